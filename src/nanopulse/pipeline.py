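"""End-to-end conveniences: dataset -> trained paths -> evaluated report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import AggregateReport, aggregate, records_frame
from .nn import (
    BNetConfig,
    ModelCheckpoint,
    WindowArrays,
    bnet_predict,
    schedule_for_snr,
    train_path,
    windows_to_arrays,
)

__all__ = ["train_bnet", "evaluate_bnet", "build_split_arrays"]


def build_split_arrays(traces_by_split: dict) -> dict[str, WindowArrays]:
    return {split: windows_to_arrays(traces)
            for split, traces in traces_by_split.items()}


def train_bnet(arrays: dict[str, WindowArrays], snr: float, seed: int,
               cfg: BNetConfig | None = None, n_epochs: int = 60,
               verbose: bool = False):
    """Train both paths with the published per-SNR schedules."""
    ckpt1 = train_path(1, arrays["train"], arrays["val"],
                       schedule_for_snr(snr, 1, n_epochs), seed, cfg,
                       verbose=verbose)
    ckpt2 = train_path(2, arrays["train"], arrays["val"],
                       schedule_for_snr(snr, 2, n_epochs), seed + 1, cfg,
                       verbose=verbose)
    return ckpt1, ckpt2


def evaluate_bnet(ckpt1: ModelCheckpoint, ckpt2: ModelCheckpoint,
                  test: WindowArrays) -> tuple[pd.DataFrame, AggregateReport]:
    """Gated inference over a labeled test split, per-window error records,
    and the three-stage aggregation."""
    counts, amps, durs = bnet_predict(ckpt1, ckpt2, test.x)
    truths = list(zip(test.count, test.amplitude, test.duration))
    preds = list(zip(counts, amps, durs))
    conditions = [tuple(row) for row in np.asarray(test.condition)]
    records = records_frame(conditions, truths, preds)
    return records, aggregate(records)
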