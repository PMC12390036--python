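"""CSV (and optional WFDB) record input/output.

CSV dialect: UTF-8, comma-separated, header ``time_s,<label>``, floats written
at full ``repr`` precision so a write/read round-trip is bit-lossless.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import RecordBundle, Waveform

logger = logging.getLogger(__name__)

#: relative tolerance for declaring a time column uniformly sampled
_UNIFORM_RTOL = 1e-6

_CHANNEL_FILES = {"ecg": "ecg.csv", "ppg": "ppg.csv", "resp_ref": "resp.csv"}


def _fs_from_times(t: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("need at least two samples to infer a sampling rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _UNIFORM_RTOL * med:
        raise ValueError("time column is not uniformly sampled (beyond 1 ppm)")
    # the full-span estimate averages away the per-step rounding of the
    # written time stamps, unlike the median single step
    return (t.size - 1) / float(t[-1] - t[0])


def read_waveform_csv(path: Union[str, Path], column: Optional[str] = None) -> Waveform:
    """Read one channel from a ``time_s,<label>`` CSV.

    The sampling rate is inferred from the median spacing of the time column;
    non-uniform spacing beyond 1 ppm or a non-monotone time column is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: CSV must have a 'time_s' column")
    value_cols = [c for c in df.columns if c != "time_s"]
    if not value_cols:
        raise ValueError(f"{path}: no value column found")
    col = column if column is not None else value_cols[0]
    if col not in df.columns:
        raise ValueError(f"{path}: no column named {col!r}")
    t = df["time_s"].to_numpy(dtype=np.float64)
    fs = _fs_from_times(t)
    return Waveform(df[col].to_numpy(dtype=np.float64), fs=fs, t0=float(t[0]), label=col)


def write_waveform_csv(w: Waveform, path: Union[str, Path]) -> None:
    """Write ``time_s,<label>`` at full repr precision (lossless round-trip)."""
    path = Path(path)
    label = w.label or "value"
    with open(path, "w", encoding="utf-8") as f:
        f.write(f"time_s,{label}\n")
        for t, v in zip(w.times.tolist(), w.samples.tolist()):
            f.write(f"{t!r},{v!r}\n")


def read_record(path: Union[str, Path], format: str = "csv",
                subject_id: Optional[str] = None) -> RecordBundle:
    """Read a multi-channel record.

    ``csv``: *path* is either a directory holding ``ecg.csv`` / ``ppg.csv`` /
    ``resp.csv`` (any subset) or a single CSV whose value columns are named
    after channels.  ``wfdb``: *path* is a WFDB record name; requires the
    optional :mod:`wfdb` package.
    """
    path = Path(path)
    if format == "wfdb":
        return _read_wfdb(path, subject_id)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    sid = subject_id or path.stem
    channels: dict = {}
    if path.is_dir():
        for key, fname in _CHANNEL_FILES.items():
            fpath = path / fname
            if fpath.exists():
                channels[key] = read_waveform_csv(fpath)
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, float_precision="round_trip")
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: CSV must have a 'time_s' column")
        t = df["time_s"].to_numpy(dtype=np.float64)
        fs = _fs_from_times(t)
        aliases = {"ecg": "ecg", "ppg": "ppg", "resp": "resp_ref", "resp_ref": "resp_ref"}
        for col in df.columns:
            if col == "time_s":
                continue
            key = aliases.get(col.lower(), None)
            if key is None and len(df.columns) == 2:
                key = "ecg"  # single unlabelled channel: caller knows best
            if key is not None:
                channels[key] = Waveform(df[col].to_numpy(dtype=np.float64),
                                         fs=fs, t0=float(t[0]), label=col)
    if not channels:
        raise ValueError(f"{path}: no recognizable channels found")
    return RecordBundle(subject_id=sid, **channels)


def write_record(bundle: RecordBundle, outdir: Union[str, Path],
                 truth: Optional[dict] = None) -> None:
    """Write each channel of *bundle* to ``<outdir>/{ecg,ppg,resp}.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, fname in _CHANNEL_FILES.items():
        w = getattr(bundle, key)
        if w is not None:
            write_waveform_csv(w, outdir / fname)
    if truth is not None:
        with open(outdir / "truth.json", "w", encoding="utf-8") as f:
            json.dump(truth, f, indent=1)


def _read_wfdb(path: Path, subject_id: Optional[str]) -> RecordBundle:
    try:
        import wfdb  # noqa: F401
    except ImportError as exc:  # pragma: no cover - depends on extra
        raise ImportError(
            "WFDB support needs the optional 'wfdb' package "
            "(pip install cardioresp[wfdb]); CSV is the built-in format"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    channels: dict = {}
    for name, sig in zip(rec.sig_name, rec.p_signal.T):
        lname = name.lower()
        key = ("ecg" if "ecg" in lname or "ii" == lname else
               "ppg" if "ppg" in lname or "pleth" in lname else
               "resp_ref" if "resp" in lname or "co2" in lname else None)
        if key and key not in channels:
            channels[key] = Waveform(sig, fs=float(rec.fs), label=name)
    if not channels:
        raise ValueError(f"{path}: no ECG/PPG/respiration channels in record")
    return RecordBundle(subject_id=subject_id or path.name, **channels)
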