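"""Fixed-length temporal windows and their ground-truth label triples."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import EventTable, Trace, WINDOW_S

__all__ = ["WindowSample", "segment_trace", "label_window", "label_trace_windows"]


@dataclass
class WindowSample:
    """One trace segment with an optional (count, mean amp, mean dur) label.

    An event belongs to the window containing its temporal midpoint, so every
    event is counted exactly once even when it straddles a boundary.
    """

    samples: np.ndarray
    label: tuple[int, float, float] | None
    trace_id: str
    index: int


def segment_trace(trace: Trace, window_s: float = WINDOW_S,
                  trace_id: str = "") -> list[WindowSample]:
    """Consecutive non-overlapping windows; a trailing partial window is dropped."""
    n_win_samples = int(round(window_s * trace.fs_Hz))
    n = trace.noisy.size
    n_windows = n // n_win_samples
    if n_windows == 0:
        warnings.warn("trace shorter than one window; no windows produced",
                      stacklevel=2)
        return []
    return [
        WindowSample(trace.noisy[i * n_win_samples:(i + 1) * n_win_samples],
                     None, trace_id, i)
        for i in range(n_windows)
    ]


def label_window(t_lo_s: float, t_hi_s: float,
                 events: EventTable) -> tuple[int, float, float]:
    """(count, mean amplitude nA, mean duration ms) of events whose midpoints
    fall in [t_lo, t_hi); (0, 0, 0) when none do."""
    amps, durs = [], []
    for ev in events:
        if t_lo_s <= ev.t_mid_s < t_hi_s:
            amps.append(ev.amplitude_nA)
            durs.append(ev.duration_ms)
    if not amps:
        return (0, 0.0, 0.0)
    return (len(amps), float(np.mean(amps)), float(np.mean(durs)))


def label_trace_windows(trace: Trace, window_s: float = WINDOW_S,
                        trace_id: str = "") -> list[WindowSample]:
    """Segment a trace and attach ground-truth labels from its event table."""
    windows = segment_trace(trace, window_s, trace_id)
    for w in windows:
        t_lo = w.index * window_s
        w.label = label_window(t_lo, t_lo + window_s, trace.events)
    return windows
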