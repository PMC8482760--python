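"""An 18-weighted-layer 1D residual regressor with a two-layer head.

The backbone follows the canonical 18-layer residual design adapted to one
dimension: a long first convolution (kernel 49, stride 4) on the raw
5000-sample window, a stride-2 max pool, four stages of two basic blocks at
widths w/2w/4w/8w, global average pooling, then a two-layer perceptron head.
All normalization is group normalization, so inference is deterministic and
independent of batch composition. The head can take one extra scalar (the
pulse count) concatenated to its penultimate activation — the injection path
used by the feature-regression network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    Conv1d,
    GlobalAvgPool,
    GroupNorm,
    Linear,
    MaxPool1d,
    Module,
    Param,
    ReLU,
)

__all__ = ["BNetConfig", "BasicBlock", "ResNet1dRegressor"]


@dataclass(frozen=True)
class BNetConfig:
    """Architecture knobs shared by the two network paths."""

    window_len_samples: int = 5000
    base_width: int = 64
    stage_blocks: tuple[int, int, int, int] = (2, 2, 2, 2)
    first_kernel: int = 49
    first_stride: int = 4
    gn_groups: int = 8
    head_hidden: int = 64
    # Group normalization makes the backbone invariant to positive rescaling
    # of its input, so the head also receives log(per-window robust scale) —
    # without it the absolute blockade depth is unlearnable.
    scale_feature: bool = True

    def __post_init__(self) -> None:
        if self.base_width % self.gn_groups:
            raise ValueError("base_width must be divisible by gn_groups")


class BasicBlock(Module):
    """conv-gn-relu-conv-gn plus a (possibly projected) shortcut, then relu."""

    def __init__(self, c_in: int, c_out: int, stride: int, groups: int,
                 rng: np.random.Generator, name: str):
        self.conv1 = Conv1d(c_in, c_out, 3, stride, 1, rng, f"{name}.conv1")
        self.gn1 = GroupNorm(groups, c_out, f"{name}.gn1")
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, 3, 1, 1, rng, f"{name}.conv2")
        self.gn2 = GroupNorm(groups, c_out, f"{name}.gn2")
        self.relu_out = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj = Conv1d(c_in, c_out, 1, stride, 0, rng, f"{name}.proj")
            self.proj_gn = GroupNorm(groups, c_out, f"{name}.proj_gn")
        else:
            self.proj = None
            self.proj_gn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1.forward(self.gn1.forward(self.conv1.forward(x)))
        out = self.gn2.forward(self.conv2.forward(out))
        short = x if self.proj is None else self.proj_gn.forward(
            self.proj.forward(x))
        return self.relu_out.forward(out + short)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu_out.backward(dy)
        dshort = dy if self.proj is None else self.proj.backward(
            self.proj_gn.backward(dy))
        dmain = self.conv1.backward(self.gn1.backward(self.relu1.backward(
            self.conv2.backward(self.gn2.backward(dy)))))
        return dmain + dshort

    def params(self):
        out = self.conv1.params() + self.gn1.params() + \
            self.conv2.params() + self.gn2.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_gn.params()
        return out


class ResNet1dRegressor(Module):
    """Backbone + two-layer perceptron head with optional count injection."""

    def __init__(self, cfg: BNetConfig, out_dim: int, inject_count: bool,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.out_dim = out_dim
        self.inject_count = inject_count
        w = cfg.base_width
        pad = cfg.first_kernel // 2
        self.stem = Conv1d(1, w, cfg.first_kernel, cfg.first_stride, pad,
                           rng, "stem")
        self.stem_gn = GroupNorm(cfg.gn_groups, w, "stem_gn")
        self.stem_relu = ReLU()
        self.pool = MaxPool1d(3, 2, 1)
        self.blocks: list[BasicBlock] = []
        c_in = w
        for s, n_blocks in enumerate(cfg.stage_blocks):
            c_out = w * (2 ** s)
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                self.blocks.append(BasicBlock(c_in, c_out, stride,
                                              cfg.gn_groups, rng,
                                              f"stage{s}.block{b}"))
                c_in = c_out
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(c_in, cfg.head_hidden, rng, "head.fc1")
        self.fc1_relu = ReLU()
        self._n_extras = (1 if cfg.scale_feature else 0) + \
            (1 if inject_count else 0)
        self.fc2 = Linear(cfg.head_hidden + self._n_extras, out_dim,
                          rng, "head.fc2")

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, count: np.ndarray | None = None,
                training: bool = False) -> np.ndarray:
        """x: (N, window_len) standardized windows; count: (N,) scalars when
        this path takes the injected pulse count."""
        if x.ndim != 2 or x.shape[1] != self.cfg.window_len_samples:
            raise ValueError(
                f"expected (N, {self.cfg.window_len_samples}) input, got {x.shape}")
        if self.inject_count and count is None:
            raise ValueError("this path requires an injected count")
        x = np.asarray(x, dtype=np.float32)
        h = x[:, None, :]
        h = self.stem_relu.forward(self.stem_gn.forward(self.stem.forward(h)))
        h = self.pool.forward(h)
        for blk in self.blocks:
            h = blk.forward(h)
        h = self.gap.forward(h)
        h = self.fc1_relu.forward(self.fc1.forward(h))
        extras = []
        if self.cfg.scale_feature:
            med = np.median(x, axis=1, keepdims=True)
            mad = 1.4826 * np.median(np.abs(x - med), axis=1, keepdims=True)
            extras.append(np.log(mad + 1e-6).astype(np.float32))
        if self.inject_count:
            extras.append(np.asarray(count, dtype=np.float32).reshape(-1, 1))
        if extras:
            h = np.concatenate([h] + extras, axis=1)
        return self.fc2.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        dh = self.fc2.backward(dy.astype(np.float32))
        if self._n_extras:
            dh = dh[:, :-self._n_extras]  # auxiliary scalars take no gradient
        dh = self.fc1.backward(self.fc1_relu.backward(dh))
        dh = self.gap.backward(dh)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        dh = self.pool.backward(dh)
        self.stem.backward(self.stem_gn.backward(self.stem_relu.backward(dh)))

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = self.stem.params() + self.stem_gn.params()
        for blk in self.blocks:
            out += blk.params()
        out += self.fc1.params() + self.fc2.params()
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name}")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data[...] = state[p.name]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())
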