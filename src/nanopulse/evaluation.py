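"""Error metrics, zero-window rules, and the hierarchical error aggregation.

Per-window relative errors (with the two zero-count rules) are averaged in
three stages: per (C_np, D_np, duration) grid cell, then per duration across
cells, then a total across durations with equal weight per duration. The
standard deviation at each stage is the population SD of that stage's member
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "relative_error",
    "rpd",
    "window_errors",
    "records_frame",
    "aggregate",
    "AggregateReport",
    "compare_report",
]

FEATURES = ("count", "amplitude", "duration")


def relative_error(x: float, x0: float) -> float:
    """|x - x0| / |x0|. Not symmetric in its arguments; x0 must be nonzero
    (zero truth is handled by the zero-window rules, never by division)."""
    if x0 == 0:
        raise ZeroDivisionError("true value is zero; apply the zero-window rules")
    return abs(x - x0) / abs(x0)


def rpd(x: float, x0: float) -> float:
    """Relative percent difference 2|x - x0| / (|x| + |x0|), in [0, 2],
    symmetric, with 0/0 defined as 0."""
    denom = abs(x) + abs(x0)
    if denom == 0:
        return 0.0
    return 2.0 * abs(x - x0) / denom


def window_errors(truth: tuple, prediction: tuple) -> tuple[float, float, float]:
    """Per-feature relative errors for one window.

    ``truth`` and ``prediction`` are (count, mean amplitude, mean duration),
    with the prediction's count already rounded/gated. Rules for zero-count
    truth windows: a correctly predicted empty window scores 0 error on all
    three features; a falsely non-empty prediction scores 100% (=1.0) on all
    three. Otherwise each feature uses |x - x0|/|x0|.
    """
    t_count, t_amp, t_dur = truth
    p_count, p_amp, p_dur = prediction
    if t_count == 0:
        return (0.0, 0.0, 0.0) if p_count == 0 else (1.0, 1.0, 1.0)
    return (
        relative_error(p_count, t_count),
        relative_error(p_amp, t_amp),
        relative_error(p_dur, t_dur),
    )


def records_frame(conditions, truths, predictions) -> pd.DataFrame:
    """Tidy per-window table: condition columns plus err_count/amplitude/duration.

    ``conditions`` is an iterable of (c_np, d_np, duration_ms) triples aligned
    with the truth/prediction triples.
    """
    rows = []
    for (c, d, w), t, p in zip(conditions, truths, predictions):
        e = window_errors(t, p)
        rows.append({"c_np_nM": c, "d_np_nm": d, "duration_ms": w,
                     "err_count": e[0], "err_amplitude": e[1], "err_duration": e[2]})
    return pd.DataFrame(rows)


@dataclass
class AggregateReport:
    per_cell: pd.DataFrame       # mean/std per (c_np, d_np, duration)
    per_duration: pd.DataFrame   # mean/std per duration, across cells
    total: dict[str, tuple[float, float]]  # feature -> (mean, population SD)

    def total_percent(self) -> dict[str, float]:
        return {k: 100.0 * v[0] for k, v in self.total.items()}


def aggregate(records: pd.DataFrame) -> AggregateReport:
    """Three-stage equal-weight aggregation of per-window errors."""
    if records.empty:
        raise ValueError("no records to aggregate")
    err_cols = [f"err_{f}" for f in FEATURES]
    g = records.groupby(["duration_ms", "c_np_nM", "d_np_nm"])[err_cols]
    cell = g.mean().add_suffix("_mean").join(
        g.std(ddof=0).add_suffix("_std")).reset_index()

    mean_cols = [f"err_{f}_mean" for f in FEATURES]
    gd = cell.groupby("duration_ms")[mean_cols]
    per_dur = gd.mean().join(gd.std(ddof=0), rsuffix="_spread").reset_index()
    per_dur.columns = (["duration_ms"]
                       + [f"err_{f}_mean" for f in FEATURES]
                       + [f"err_{f}_std" for f in FEATURES])

    total = {}
    for f in FEATURES:
        vals = per_dur[f"err_{f}_mean"].to_numpy()
        total[f] = (float(vals.mean()), float(vals.std(ddof=0)))
    return AggregateReport(per_cell=cell, per_duration=per_dur, total=total)


def compare_report(bnet_records: pd.DataFrame,
                   sweep_records: pd.DataFrame) -> pd.DataFrame:
    """Long-format comparison of per-condition errors from the two methods.

    ``bnet_records`` is the per-window error frame of the network;
    ``sweep_records`` must additionally carry an ``n_threshold`` column. The
    result has one row per (condition, method, threshold) with the network
    rows carrying a missing threshold.
    """
    err_cols = [f"err_{f}" for f in FEATURES]
    cond_cols = ["c_np_nM", "d_np_nm", "duration_ms"]
    b = (bnet_records.groupby(cond_cols)[err_cols].mean().reset_index())
    b["method"] = "bnet"
    b["n_threshold"] = np.nan
    s = (sweep_records.groupby(cond_cols + ["n_threshold"])[err_cols]
         .mean().reset_index())
    s["method"] = "classic"
    out = pd.concat([b, s], ignore_index=True)
    return out[cond_cols + ["method", "n_threshold"] + err_cols]
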