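"""Synthetic nanopore translocation traces with exact ground-truth labels.

A trace is the sum of three parts: a drifting/jumping baseline at the
open-pore current, randomly placed asymmetric-triangle blockade pulses that
subtract from it, and colored Gaussian background noise whose power is
calibrated per condition to hit a target SNR (amplitude / (6 x noise RMS)
by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .physics import (
    Electrolyte,
    NoisePSDParams,
    PoreSpec,
    SnrSpec,
    blockade_amplitude,
    noise_rms,
    open_pore_current,
    snr_noise_scale,
)

__all__ = [
    "Event",
    "EventTable",
    "SimCondition",
    "SimSettings",
    "JumpConfig",
    "DriftConfig",
    "Trace",
    "sample_events",
    "spike_waveform",
    "synth_colored_noise",
    "synth_baseline",
    "generate_trace",
    "condition_grid",
    "default_grid",
    "generate_dataset",
]

WINDOW_S = 0.5


@dataclass(frozen=True)
class Event:
    """One translocation pulse."""

    t_start_s: float
    duration_ms: float
    amplitude_nA: float
    rise_fraction: float

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_ms * 1e-3

    @property
    def t_mid_s(self) -> float:
        return self.t_start_s + 0.5 * self.duration_ms * 1e-3

    def __post_init__(self) -> None:
        if self.t_start_s < 0 or self.duration_ms <= 0 or self.amplitude_nA <= 0:
            raise ValueError("invalid event")
        if not (0.0 < self.rise_fraction < 1.0):
            raise ValueError("rise_fraction must lie in (0, 1)")


class EventTable:
    """Ordered (by start time) sequence of events."""

    def __init__(self, events=()):
        evs = list(events)
        if any(b.t_start_s < a.t_start_s for a, b in zip(evs, evs[1:])):
            evs.sort(key=lambda e: e.t_start_s)
        self.events: list[Event] = evs

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other):
        return isinstance(other, EventTable) and self.events == other.events

    def to_arrays(self):
        """Columns (t_start_s, t_end_s, duration_ms, amplitude_nA, rise_fraction)."""
        n = len(self.events)
        out = {k: np.empty(n) for k in
               ("t_start_s", "t_end_s", "duration_ms", "amplitude_nA", "rise_fraction")}
        for i, e in enumerate(self.events):
            out["t_start_s"][i] = e.t_start_s
            out["t_end_s"][i] = e.t_end_s
            out["duration_ms"][i] = e.duration_ms
            out["amplitude_nA"][i] = e.amplitude_nA
            out["rise_fraction"][i] = e.rise_fraction
        return out


@dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation grid."""

    c_np_nM: float
    d_np_nm: float
    duration_ms: float
    snr: float
    bias_V: float = 0.3
    trace_length_s: float = 20.0
    fs_Hz: float = 10_000.0

    def __post_init__(self) -> None:
        if min(self.c_np_nM, 0.0) < 0 or self.d_np_nm <= 0 or self.duration_ms <= 0:
            raise ValueError("invalid condition")
        if self.snr <= 0 or self.trace_length_s <= 0 or self.fs_Hz <= 0:
            raise ValueError("invalid condition")
        n = self.fs_Hz * self.trace_length_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs_Hz * trace_length_s must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_Hz * self.trace_length_s))


@dataclass(frozen=True)
class JumpConfig:
    """Sudden baseline steps: Bernoulli per sample, signed uniform amplitude."""

    rate_per_s: float = 0.05
    amp_frac: float = 0.02


@dataclass(frozen=True)
class DriftConfig:
    """Slow baseline wander: sum of sine and cosine terms at random low
    frequencies with random amplitudes."""

    n_terms: int = 8
    f_lo_Hz: float = 0.05
    f_hi_Hz: float = 2.0
    amp_frac_max: float = 0.005


@dataclass(frozen=True)
class SimSettings:
    """Everything about the simulator that is not part of the condition grid."""

    pore: PoreSpec = field(default_factory=PoreSpec)
    electrolyte: Electrolyte = field(default_factory=Electrolyte)
    noise: NoisePSDParams = field(default_factory=NoisePSDParams)
    jumps: JumpConfig = field(default_factory=JumpConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    k_cap_per_s_nM: float = 20.0
    p2p_factor: float = 6.0
    rise_fraction_range: tuple[float, float] = (0.2, 0.8)


@dataclass
class Trace:
    """A simulated recording plus its exact generating information."""

    noisy: np.ndarray
    clean: np.ndarray | None
    fs_Hz: float
    condition: SimCondition
    seed: int | None
    events: EventTable


def sample_events(cond: SimCondition, rng: np.random.Generator,
                  settings: SimSettings | None = None) -> EventTable:
    """Draw pulse start times as a per-sample Bernoulli process.

    The per-step probability is k_cap * C_np * dt; each accepted step starts a
    pulse with the condition's dwell time, the physics-model blockade
    amplitude, and a random apex position. Pulses that would run past the end
    of the trace are dropped so the table stays within the trace extent.
    """
    settings = settings or SimSettings()
    p = settings.k_cap_per_s_nM * cond.c_np_nM / cond.fs_Hz
    if p > 1.0:
        raise ValueError("capture probability per step exceeds 1; lower k_cap or C_np")
    if cond.c_np_nM == 0 or p == 0:
        return EventTable()
    i0 = open_pore_current(settings.pore, settings.electrolyte, cond.bias_V)
    amp = blockade_amplitude(settings.pore, cond.d_np_nm, i0)
    n = cond.n_samples
    hits = np.flatnonzero(rng.random(n) < p)
    lo, hi = settings.rise_fraction_range
    events = []
    dur_s = cond.duration_ms * 1e-3
    for idx in hits:
        t0 = idx / cond.fs_Hz
        if t0 + dur_s > cond.trace_length_s:
            continue
        events.append(Event(t0, cond.duration_ms, amp,
                            float(rng.uniform(lo, hi))))
    return EventTable(events)


def spike_waveform(ev: Event, fs_Hz: float) -> np.ndarray:
    """Sampled asymmetric triangle: linear ramp to the apex, linear fall.

    The apex sample equals the event amplitude exactly; the support is
    round(duration * fs) samples and the discrete sum approximates the
    triangle area A*W/2.
    """
    n = int(round(ev.duration_ms * 1e-3 * fs_Hz))
    if n < 2:
        raise ValueError("event shorter than 2 samples at this sampling rate")
    apex = int(round(ev.rise_fraction * (n - 1)))
    apex = min(max(apex, 0), n - 1)
    w = np.empty(n)
    i = np.arange(n)
    rise = i <= apex
    w[rise] = ev.amplitude_nA * (i[rise] + 1) / (apex + 1)
    w[~rise] = ev.amplitude_nA * (n - i[~rise]) / (n - apex)
    return w


def synth_colored_noise(params: NoisePSDParams, n_samples: int, fs_Hz: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Colored Gaussian noise whose expected one-sided periodogram equals S(f).

    White Gaussian noise is shaped in the frequency domain. With W = rfft of
    unit white noise (E|W_k|^2 = n), interior bins are scaled by
    sqrt(S(f_k) * fs / 2) and the Nyquist bin by sqrt(S * fs), so that the
    one-sided periodogram 2|Y_k|^2/(fs n) has expectation S(f_k) and the
    variance of the output equals sum_k S(f_k) df ~ integral of S over the
    band (Parseval). Bins outside [f_min, f_max] — including DC — are zeroed,
    which keeps the realized RMS consistent with the quadrature RMS of the
    PSD over its stated integration band.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_Hz)
    spectrum = np.fft.rfft(rng.standard_normal(n_samples))
    gain = np.zeros_like(freqs)
    band = (freqs >= params.f_min_Hz) & (freqs <= params.f_max_Hz)
    if band.any():
        s = np.asarray(
            np.maximum(
                0.0,
                params.a_flicker / freqs[band] ** params.beta
                + params.a_electrode / freqs[band] ** params.gamma
                + params.a_white
                + params.a_dielectric * freqs[band],
            )
        )
        gain[band] = np.sqrt(s * fs_Hz / 2.0)
    if n_samples % 2 == 0 and band[-1]:
        gain[-1] *= math.sqrt(2.0)  # real Nyquist bin carries no conjugate twin
    return np.fft.irfft(spectrum * gain, n=n_samples)


def synth_baseline(n_samples: int, fs_Hz: float, i0_nA: float,
                   jump_cfg: JumpConfig, drift_cfg: DriftConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Open-pore current plus random sudden steps and slow sinusoidal wander."""
    base = np.full(n_samples, i0_nA)
    # sudden jumps: cumulative signed steps, Bernoulli per sample
    p = jump_cfg.rate_per_s / fs_Hz
    if p > 0 and jump_cfg.amp_frac > 0:
        hits = np.flatnonzero(rng.random(n_samples) < p)
        if hits.size:
            amps = rng.uniform(-jump_cfg.amp_frac, jump_cfg.amp_frac,
                               hits.size) * i0_nA
            steps = np.zeros(n_samples)
            steps[hits] = amps
            base += np.cumsum(steps)
    # slow drift: half sine, half cosine terms
    if drift_cfg.n_terms > 0 and drift_cfg.amp_frac_max > 0:
        t = np.arange(n_samples) / fs_Hz
        n_sin = drift_cfg.n_terms // 2
        for k in range(drift_cfg.n_terms):
            f = rng.uniform(drift_cfg.f_lo_Hz, drift_cfg.f_hi_Hz)
            a = rng.uniform(0.0, drift_cfg.amp_frac_max) * i0_nA
            phase = 0.0 if k < n_sin else 0.5 * math.pi
            base += a * np.sin(2.0 * math.pi * f * t + phase)
    return base


def _band_limited(noise: NoisePSDParams, fs_Hz: float) -> NoisePSDParams:
    f_max = min(noise.f_max_Hz, fs_Hz / 2.0)
    if f_max != noise.f_max_Hz:
        noise = replace(noise, f_max_Hz=f_max)
    return noise


def generate_trace(cond: SimCondition, seed: int,
                   settings: SimSettings | None = None) -> Trace:
    """Simulate one fully labeled trace, bit-reproducible from its seed."""
    settings = settings or SimSettings()
    rng = np.random.default_rng(seed)
    i0 = open_pore_current(settings.pore, settings.electrolyte, cond.bias_V)
    amp = blockade_amplitude(settings.pore, cond.d_np_nm, i0)
    n = cond.n_samples

    events = sample_events(cond, rng, settings)
    clean = synth_baseline(n, cond.fs_Hz, i0, settings.jumps, settings.drift, rng)
    for ev in events:
        w = spike_waveform(ev, cond.fs_Hz)
        start = int(round(ev.t_start_s * cond.fs_Hz))
        stop = min(start + w.size, n)
        clean[start:stop] -= w[: stop - start]

    noise_params = _band_limited(settings.noise, cond.fs_Hz)
    base_rms = noise_rms(noise_params)
    scale = snr_noise_scale(SnrSpec(cond.snr, settings.p2p_factor), amp, base_rms)
    noise = scale * synth_colored_noise(noise_params, n, cond.fs_Hz, rng)
    return Trace(noisy=clean + noise, clean=clean, fs_Hz=cond.fs_Hz,
                 condition=cond, seed=seed, events=events)


def condition_grid(c_values, d_values, duration_values, snr, *,
                   bias_V: float = 0.3, fs_Hz: float = 10_000.0,
                   trace_length_s: float = 20.0) -> list[SimCondition]:
    """Cartesian product of concentrations, diameters and dwell times."""
    return [
        SimCondition(float(c), float(d), float(w), float(snr), bias_V=bias_V,
                     trace_length_s=trace_length_s, fs_Hz=fs_Hz)
        for c in c_values for d in d_values for w in duration_values
    ]


def default_grid(snr: float, **kwargs) -> list[SimCondition]:
    """The full 20 x 15 x 5 condition grid: C_np 0.01-1 nM (log-spaced),
    D_np 3-17 nm in 1 nm steps, dwell 0.5/1/1.5/3/5 ms."""
    c_values = np.logspace(-2, 0, 20)
    d_values = np.arange(3, 18)
    durations = [0.5, 1.0, 1.5, 3.0, 5.0]
    return condition_grid(c_values, d_values, durations, snr, **kwargs)


def generate_dataset(conditions, windows_per_split: dict[str, int], seed: int,
                     settings: SimSettings | None = None,
                     window_s: float = WINDOW_S):
    """Simulate traces over a grid so each split has the requested window count.

    Windows are distributed as evenly as possible across conditions; each
    (condition, split) pair gets its own trace, sized to exactly its share of
    windows, with a seed derived from `seed`. Returns ``{split: [Trace, ...]}``
    plus a manifest of per-trace metadata (one dict per trace).
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("empty condition grid")
    settings = settings or SimSettings()
    n_cond = len(conditions)
    out: dict[str, list[Trace]] = {}
    manifest: list[dict] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_cond * len(windows_per_split) * 2)
    k = 0
    for split, total in windows_per_split.items():
        if total < 0:
            raise ValueError("split sizes must be non-negative")
        base, extra = divmod(total, n_cond)
        traces: list[Trace] = []
        for i, cond in enumerate(conditions):
            n_win = base + (1 if i < extra else 0)
            trace_seed = int(child_seeds[k]); k += 1
            if n_win == 0:
                continue
            length = n_win * window_s
            cond_i = replace(cond, trace_length_s=length)
            tr = generate_trace(cond_i, trace_seed, settings)
            traces.append(tr)
            manifest.append({
                "split": split, "condition_index": i, "seed": trace_seed,
                "c_np_nM": cond.c_np_nM, "d_np_nm": cond.d_np_nm,
                "duration_ms": cond.duration_ms, "snr": cond.snr,
                "n_windows": n_win,
            })
        got = sum(int(t.condition.trace_length_s / window_s + 0.5) for t in traces)
        if got != total:
            raise ValueError(f"split {split!r}: requested {total} windows, got {got}")
        out[split] = traces
    return out, manifest
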