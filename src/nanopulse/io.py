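"""Trace-bundle I/O, event-table files, configuration, and the fixture grid.

A trace bundle is one HDF5 file holding the noisy (and, for synthetic data,
clean) current arrays with sampling rate, seed and generating-condition
metadata, plus a sibling tab-delimited event table as the ground-truth
answer sheet. Currents are stored in nA and times in seconds; durations are
milliseconds in event tables, matching the reporting units elsewhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .physics import Electrolyte, NoisePSDParams, PoreSpec
from .simulate import (
    DriftConfig,
    EventTable,
    Event,
    JumpConfig,
    SimCondition,
    SimSettings,
    condition_grid,
    generate_dataset,
)

__all__ = [
    "FormatError",
    "write_bundle",
    "read_bundle",
    "write_event_table",
    "read_event_table",
    "load_settings",
    "make_fixture",
]

BUNDLE_VERSION = 1
EVENT_COLUMNS = ("event_id", "t_start_s", "t_end_s", "duration_ms",
                 "amplitude_nA", "rise_fraction")


class FormatError(ValueError):
    """A bundle or event-table file is malformed."""


def write_event_table(path, events: EventTable) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for i, e in enumerate(events):
            fh.write(f"{i}\t{e.t_start_s:.9f}\t{e.t_end_s:.9f}\t"
                     f"{e.duration_ms:.9f}\t{e.amplitude_nA:.9g}\t"
                     f"{e.rise_fraction:.9g}\n")


def read_event_table(path) -> EventTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EVENT_COLUMNS:
            raise FormatError(f"unexpected event-table header in {path}")
        events = []
        for line in fh:
            _, t0, t1, dur, amp, rf = line.rstrip("\n").split("\t")
            ev = Event(float(t0), float(dur), float(amp), float(rf))
            if abs(ev.t_end_s - float(t1)) > 1e-9:
                raise FormatError(f"inconsistent start/end/duration in {path}")
            events.append(ev)
    return EventTable(events)


def _events_path(bundle_path) -> Path:
    p = Path(bundle_path)
    return p.with_suffix(p.suffix + ".events.tsv")


def write_bundle(path, trace) -> None:
    """Write a trace bundle (HDF5) plus its sibling event-table TSV."""
    path = Path(path)
    cond = dataclasses.asdict(trace.condition)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = BUNDLE_VERSION
        f.attrs["fs_Hz"] = trace.fs_Hz
        f.attrs["seed"] = -1 if trace.seed is None else int(trace.seed)
        f.attrs["condition"] = json.dumps(cond)
        f.create_dataset("noisy", data=np.asarray(trace.noisy, dtype=np.float64))
        if trace.clean is not None:
            f.create_dataset("clean", data=np.asarray(trace.clean,
                                                      dtype=np.float64))
    write_event_table(_events_path(path), trace.events)


def read_bundle(path):
    """Read a trace bundle back into a Trace (clean may be absent -> None)."""
    from .simulate import Trace

    path = Path(path)
    with h5py.File(path, "r") as f:
        try:
            version = int(f.attrs["version"])
            fs = float(f.attrs["fs_Hz"])
            seed = int(f.attrs["seed"])
            cond = json.loads(f.attrs["condition"])
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(f"corrupt bundle metadata in {path}: {exc}") from exc
        if version > BUNDLE_VERSION:
            raise FormatError(f"bundle version {version} is newer than supported")
        try:
            condition = SimCondition(**cond)
        except TypeError as exc:
            raise FormatError(f"bad condition metadata in {path}: {exc}") from exc
        noisy = f["noisy"][...]
        clean = f["clean"][...] if "clean" in f else None
    events_file = _events_path(path)
    events = read_event_table(events_file) if events_file.exists() else EventTable()
    return Trace(noisy=noisy, clean=clean, fs_Hz=fs, condition=condition,
                 seed=None if seed < 0 else seed, events=events)


# -- configuration -----------------------------------------------------------

def load_settings(path_or_dict) -> SimSettings:
    """Build SimSettings from a YAML file or an equivalent nested mapping.

    Recognized keys: pore {diameter_nm, thickness_nm, surface_charge},
    electrolyte {kcl_mM, conductivity, mobility}, noise {a_flicker, beta,
    a_electrode, gamma, a_white, a_dielectric, f_min_Hz, f_max_Hz},
    snr {p2p_factor}, capture {k_cap_per_s_nM}, jumps {...}, drift {...}.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})

    def sub(key):
        return raw.get(key) or {}

    pore_cfg, elec_cfg = sub("pore"), sub("electrolyte")
    pore = PoreSpec(
        diameter_nm=pore_cfg.get("diameter_nm", 20.0),
        thickness_nm=pore_cfg.get("thickness_nm", 20.0),
        surface_charge_C_per_m2=pore_cfg.get("surface_charge", -0.02),
    )
    elec = Electrolyte(
        kcl_mM=elec_cfg.get("kcl_mM", 100.0),
        bulk_conductivity_S_per_m=elec_cfg.get("conductivity", 1.28),
        cation_mobility_m2_per_Vs=elec_cfg.get("mobility", 7.62e-8),
    )
    noise = NoisePSDParams(**{k: v for k, v in sub("noise").items()})
    jumps = JumpConfig(**sub("jumps"))
    drift = DriftConfig(**sub("drift"))
    return SimSettings(
        pore=pore, electrolyte=elec, noise=noise, jumps=jumps, drift=drift,
        k_cap_per_s_nM=sub("capture").get("k_cap_per_s_nM", 20.0),
        p2p_factor=sub("snr").get("p2p_factor", 6.0),
    )


# -- fixture -----------------------------------------------------------------

def make_fixture(seed: int, out_dir=None, snr: float = 4.0):
    """Deterministic miniature standard database: a 2 x 2 x 2 condition grid
    at SNR 4 with 120 windows (60/30/30 across splits).

    Returns (traces_by_split, manifest, checksum); when ``out_dir`` is given,
    bundles and a manifest TSV are also written there.
    """
    conditions = condition_grid([0.2, 1.0], [8.0, 14.0], [1.0, 3.0], snr)
    splits = {"train": 60, "val": 30, "test": 30}
    traces, manifest = generate_dataset(conditions, splits, seed)
    digest = hashlib.sha256()
    for split in splits:
        for tr in traces[split]:
            digest.update(np.ascontiguousarray(tr.noisy).tobytes())
    checksum = digest.hexdigest()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for split in splits:
            for i, tr in enumerate(traces[split]):
                name = f"{split}_{i:03d}.h5"
                write_bundle(out_dir / name, tr)
                rows.append((split, name, tr.seed))
        with (out_dir / "manifest.tsv").open("w") as fh:
            fh.write("split\tfile\tseed\n")
            for split, name, s in rows:
                fh.write(f"{split}\t{name}\t{s}\n")
        (out_dir / "checksum.txt").write_text(checksum + "\n")
    return traces, manifest, checksum
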