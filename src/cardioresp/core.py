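"""Core containers and windowing primitives.

A :class:`Waveform` is a uniformly sampled channel: sample ``j`` lives at time
``t0 + j/fs`` (0-based).  Analysis windows are contiguous, non-overlapping,
half-open intervals ``[k*T, (k+1)*T)``; a trailing remainder shorter than one
window is discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Waveform:
    """Uniformly sampled signal.

    Parameters
    ----------
    samples : array-like
        Signal values in arbitrary units; must be finite.
    fs : float
        Sampling frequency in Hz (> 0).
    t0 : float
        Time of the first sample in seconds.
    label : str
        Channel name (e.g. ``"ecg"``).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, label: Optional[str] = None) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       label=self.label if label is None else label)


@dataclass
class RecordBundle:
    """A multi-channel record: ECG, PPG and/or a reference respiration channel.

    Channels may have different sampling rates but share ``t0`` and duration
    (within one sample period); at least one channel must be present.
    """

    subject_id: str
    ecg: Optional[Waveform] = None
    ppg: Optional[Waveform] = None
    resp_ref: Optional[Waveform] = None

    def __post_init__(self) -> None:
        if self.ecg is None and self.ppg is None and self.resp_ref is None:
            raise ValueError("RecordBundle needs at least one channel")

    @property
    def channels(self) -> dict:
        return {k: v for k, v in
                (("ecg", self.ecg), ("ppg", self.ppg), ("resp_ref", self.resp_ref))
                if v is not None}

    @property
    def duration_s(self) -> float:
        return min(w.duration_s for w in self.channels.values())


@dataclass(frozen=True)
class WindowGrid:
    """Contiguous equal-length analysis windows ``[start, end)`` in seconds."""

    window_length_s: float
    boundaries: Tuple[Tuple[float, float], ...]

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)


@dataclass
class BeatFeatureSeries:
    """One value per beat, stamped at the beat's fiducial time.

    ``feature`` is one of ``r_amp``, ``qrs_area``, ``up_slope``, ``down_slope``
    (ECG) or ``ppg_am``, ``ppg_fm`` (PPG).  Times are strictly increasing and
    ``len(times) == len(values)``.
    """

    feature: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def segment(record_duration_s: float, window_length_s: float = 30.0) -> WindowGrid:
    """Tile ``[0, record_duration_s)`` with non-overlapping windows.

    ``n_windows = floor(duration / T)``; the trailing remainder is discarded.
    The study compared 20, 30 and 60 s windows and settled on 30 s.

    Raises
    ------
    ValueError
        If the record is shorter than one window.
    """
    if not window_length_s > 0:
        raise ValueError(f"window_length_s must be positive, got {window_length_s}")
    # a nanosecond-scale slop so a duration recovered from written time
    # stamps (last-ulp short of the nominal length) still tiles fully
    ratio = record_duration_s / window_length_s + 1e-9
    if ratio < 1:
        raise ValueError(
            f"record ({record_duration_s} s) is shorter than one window "
            f"({window_length_s} s); supply a longer record or a shorter window")
    n = int(math.floor(ratio))
    bounds = tuple((k * window_length_s, (k + 1) * window_length_s) for k in range(n))
    return WindowGrid(window_length_s=window_length_s, boundaries=bounds)


def normalize01(w: Waveform) -> Waveform:
    """Rescale to [0, 1] via (x - min)/(max - min).

    A constant signal maps to all zeros (the event is logged rather than
    raised, so batch runs survive dead channels).
    """
    x = w.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        logger.warning("normalize01: constant signal %r mapped to zeros", w.label)
        return w.with_samples(np.zeros_like(x))
    return w.with_samples((x - lo) / (hi - lo))
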