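"""End-to-end convenience wrappers: waveform in, per-window RR out."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import ecg as _ecg
from . import ppg as _ppg
from .core import BeatFeatureSeries, Waveform, WindowGrid, segment
from .respiration import DerivedRespiration, WindowRR, rr_timeseries, spline_reconstruct
from .ppg import savgol_smooth


def edr_rr(ecg: Waveform, feature: str = "r_amp", window_length_s: float = 30.0,
           fs_out: float = 4.0, grid: Optional[WindowGrid] = None,
           ) -> Tuple[DerivedRespiration, List[WindowRR]]:
    """ECG -> surrogate respiration (EDR) -> per-window RR for one feature."""
    series = _ecg.extract_feature_series(ecg, feature)
    resp = spline_reconstruct(series, fs_out=fs_out)
    grid = grid or segment(ecg.duration_s, window_length_s)
    return resp, rr_timeseries(resp, grid)


def edr_rr_multi(ecg: Waveform, features: Sequence[str] = _ecg.ECG_FEATURES,
                 window_length_s: float = 30.0, fs_out: float = 4.0,
                 grid: Optional[WindowGrid] = None,
                 ) -> Dict[str, List[WindowRR]]:
    """Per-window RR for several ECG features, sharing one QRS detection."""
    filt = _ecg.bandpass_ecg(ecg)
    r_idxs = _ecg.detect_qrs(filt)
    if r_idxs.size < 3:
        raise ValueError(f"only {r_idxs.size} beats detected; need >= 3")
    complexes = [_ecg.locate_qs(filt, int(r)) for r in r_idxs]
    times = filt.t0 + r_idxs / filt.fs
    grid = grid or segment(ecg.duration_s, window_length_s)
    out: Dict[str, List[WindowRR]] = {}
    for feature in features:
        op = _ecg._FEATURE_OPS[feature]
        values = np.array([op(filt, c) for c in complexes])
        series = BeatFeatureSeries(feature=feature, times=times, values=values)
        resp = spline_reconstruct(series, fs_out=fs_out)
        out[feature] = rr_timeseries(resp, grid)
    return out


def pdr_rr(ppg: Waveform, feature: str = "am", window_length_s: float = 30.0,
           fs_out: float = 4.0, grid: Optional[WindowGrid] = None,
           ) -> Tuple[DerivedRespiration, List[WindowRR]]:
    """PPG -> surrogate respiration (PDR) -> per-window RR (AM or FM)."""
    series = _ppg.extract_feature_series(ppg, feature)
    resp = spline_reconstruct(series, fs_out=fs_out)
    grid = grid or segment(ppg.duration_s, window_length_s)
    return resp, rr_timeseries(resp, grid)


def reference_rr(resp_ref: Waveform, window_length_s: float = 30.0,
                 grid: Optional[WindowGrid] = None,
                 smooth_window_ms: float = 250.0) -> List[WindowRR]:
    """Per-window RR from the reference respiration channel.

    The channel is Savitzky-Golay smoothed before peak counting, sharpening
    breath-peak detection on noisy reference signals.
    """
    smoothed = savgol_smooth(resp_ref, window_ms=smooth_window_ms)
    grid = grid or segment(resp_ref.duration_s, window_length_s)
    return rr_timeseries(smoothed, grid)


def rr_values(windows: List[WindowRR]) -> np.ndarray:
    """Extract the rr_bpm sequence from a list of WindowRR."""
    return np.array([w.rr_bpm for w in windows])
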