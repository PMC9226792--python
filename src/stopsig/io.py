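"""On-disk formats: EDF for continuous EEG, TSV for schedules and event
markers, CSV for behavior and measures, JSON for ground-truth parameters.

EEG interchange uses European Data Format (EDF): a 256-byte fixed header,
one 256-byte header per signal, then 16-bit little-endian samples in
record-sized chunks.  Reading goes through :func:`mne.io.read_raw_edf`;
writing is a small self-contained encoder (amplitudes are quantized to the
per-channel physical range, so a round trip is lossless to within one
16-bit quantization step).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import task_design
from .simulate import SimulatedSession

__all__ = [
    "write_edf",
    "read_edf",
    "write_events",
    "read_events",
    "write_schedule",
    "read_schedule",
    "write_behavior",
    "read_behavior",
    "write_session",
]


def _pad(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _phys_str(v: float) -> str:
    """Physical min/max as an 8-char-safe decimal string."""
    s = f"{v:.6g}"
    if len(s) > 8:
        s = f"{v:.1e}"
    return s


def write_edf(path, data_uv: np.ndarray, ch_names, sfreq: float,
              record_duration_s: float = 1.0) -> None:
    """Write a (channels x samples) microvolt array as EDF.

    The signal is zero-padded to a whole number of data records.  Each
    channel's physical range is its own min/max (so quantization error is
    at most (max-min)/65535).
    """
    data_uv = np.asarray(data_uv, dtype=float)
    n_ch, n_samp = data_uv.shape
    if len(ch_names) != n_ch:
        raise ValueError("ch_names length does not match data")
    spr = int(round(sfreq * record_duration_s))     # samples per record
    n_rec = math.ceil(n_samp / spr) if n_samp else 0
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data_uv

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    # Small margin so header-precision rounding never clips extremes.
    span = pmax - pmin
    pmin = pmin - 0.002 * span
    pmax = pmax + 0.002 * span
    dmin, dmax = -32768, 32767

    header = b"".join([
        _pad(0, 8),                      # version
        _pad("X X X X", 80),             # local patient id (anonymous)
        _pad("Startdate X X X X", 80),   # local recording id
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(256 * (1 + n_ch), 8),
        _pad("", 44),
        _pad(n_rec, 8),
        _pad(f"{record_duration_s:g}", 8),
        _pad(n_ch, 4),
    ])
    fields = [
        [_pad(ch, 16) for ch in ch_names],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(_phys_str(v), 8) for v in pmin],
        [_pad(_phys_str(v), 8) for v in pmax],
        [_pad(dmin, 8)] * n_ch,
        [_pad(dmax, 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(spr, 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    # Quantize with the header's (truncated-precision) physical range so
    # the decode mapping matches exactly.
    pmin_h = np.array([float(_phys_str(v)) for v in pmin])
    pmax_h = np.array([float(_phys_str(v)) for v in pmax])
    gain = (dmax - dmin) / (pmax_h - pmin_h)
    digital = np.rint((padded - pmin_h[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())


def read_edf(path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file -> (channels x samples microvolt array, names, sfreq)."""
    import mne
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6          # mne returns volts
    return data, list(raw.ch_names), float(raw.info["sfreq"])


EVENT_COLUMNS = ["onset_sample", "code", "event", "condition", "direction",
                 "ssd_ms", "trial_index"]


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in ("onset_sample", "code") if c not in ev.columns]
    if missing:
        raise ValueError(f"{path}: marker table lacks columns {missing}")
    if not ev["onset_sample"].is_monotonic_increasing:
        warnings.warn(f"{path}: event onsets unsorted; sorting by onset_sample")
        ev = ev.sort_values("onset_sample", kind="stable").reset_index(drop=True)
    return ev


def write_schedule(path, schedule: task_design.TaskSchedule) -> None:
    task_design.schedule_to_frame(schedule).to_csv(path, sep="\t", index=False,
                                                   na_rep="n/a")


def read_schedule(path) -> task_design.TaskSchedule:
    frame = pd.read_csv(path, sep="\t", na_values=["n/a"],
                        keep_default_na=True)
    frame["stop_direction"] = frame["stop_direction"].fillna("n/a")
    return task_design.frame_to_schedule(frame)


def write_behavior(path, behavior) -> None:
    pd.DataFrame([vars(b) for b in behavior]).to_csv(path, index=False,
                                                     na_rep="")


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_epochs(path_stem, epochs) -> tuple[Path, Path]:
    """Cache an EpochSet as ``<stem>.npy`` plus a ``<stem>.json`` sidecar
    describing shape, channels, timing and rejection flags."""
    stem = Path(path_stem)
    npy = stem.with_suffix(".npy")
    sidecar = stem.with_suffix(".json")
    np.save(npy, epochs.data)
    meta = {
        "shape": list(epochs.data.shape),
        "ch_names": list(epochs.ch_names),
        "sfreq": epochs.sfreq,
        "tmin_ms": epochs.tmin_ms,
        "baseline_ms": list(epochs.baseline_ms) if epochs.baseline_ms else None,
        "event_class": epochs.event_class,
        "rejected": epochs.rejected,
        "events": epochs.events.to_dict(orient="list"),
    }
    sidecar.write_text(json.dumps(meta, default=float))
    return npy, sidecar


def read_epochs(path_stem):
    from .erp import EpochSet
    stem = Path(path_stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(
        data=data, ch_names=tuple(meta["ch_names"]), sfreq=meta["sfreq"],
        tmin_ms=meta["tmin_ms"], events=pd.DataFrame(meta["events"]),
        rejected=meta["rejected"],
        baseline_ms=tuple(meta["baseline_ms"]) if meta["baseline_ms"] else None,
        event_class=meta["event_class"])


def write_session(out_dir, session: SimulatedSession) -> dict[str, Path]:
    """Persist one simulated session (EDF + events TSV + behavior CSV +
    truth JSON); returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = session.subject_id
    paths = {
        "edf": out / f"{sid}_eeg.edf",
        "events": out / f"{sid}_events.tsv",
        "behavior": out / f"{sid}_behavior.csv",
        "schedule": out / f"{sid}_schedule.tsv",
        "truth": out / f"{sid}_truth.json",
    }
    write_edf(paths["edf"], session.eeg_uv, session.ch_names, session.sfreq)
    write_events(paths["events"], session.events)
    write_behavior(paths["behavior"], session.behavior)
    write_schedule(paths["schedule"], session.schedule)
    truth = {
        "subject": sid, "group": session.group,
        "race_params": asdict(session.race_params),
        "erp_params": _erp_params_dict(session.erp_params),
        "blink_intervals": [list(map(int, iv)) for iv in session.blink_intervals],
        "artifact_trials": list(map(int, session.artifact_trials)),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def _erp_params_dict(p) -> dict:
    d = asdict(p)
    return d
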