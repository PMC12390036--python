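"""ECG conditioning, QRS detection and per-beat morphological features.

The ECG-derived respiration (EDR) chain is: band-pass 5-40 Hz (removes
baseline wander, P/T energy and EMG noise while keeping the QRS), Pan-
Tompkins QRS detection, Q/S localization by local-minimum search around each
R peak, then one of four per-beat features:

* ``r_amp``      R-peak amplitude, max of x over the QRS
* ``up_slope``   max |x_j - x_{j-1}| between Q and R
* ``down_slope`` max |x_{j+1} - x_j| between R and S
* ``qrs_area``   sum of absolute trapezoidal areas of the Q, R and S waves

Respiration modulates each of these beat-to-beat; a separate surrogate
respiration signal is reconstructed downstream from each feature series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import signal as sps

from .core import BeatFeatureSeries, Waveform

logger = logging.getLogger(__name__)

ECG_FEATURES = ("r_amp", "qrs_area", "up_slope", "down_slope")


@dataclass(frozen=True)
class QrsComplex:
    """Q/R/S sample indices (into the filtered ECG) for one beat."""

    q_idx: int
    r_idx: int
    s_idx: int

    def __post_init__(self) -> None:
        if not self.q_idx <= self.r_idx <= self.s_idx:
            raise ValueError("require q_idx <= r_idx <= s_idx")


def bandpass_ecg(ecg: Waveform, low_hz: float = 5.0, high_hz: float = 40.0) -> Waveform:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward).

    The forward-backward application keeps fiducial timing intact.
    """
    if not ecg.fs > 2 * high_hz:
        raise ValueError(
            f"fs={ecg.fs} too low for a [{low_hz}, {high_hz}] Hz band "
            f"(need fs > {2 * high_hz})")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=ecg.fs, output="sos")
    return ecg.with_samples(sps.sosfiltfilt(sos, ecg.samples))


def detect_qrs(ecg_filtered: Waveform) -> np.ndarray:
    """Pan-Tompkins QRS detection on the band-passed ECG.

    Chain: derivative, squaring, 150 ms moving-window integration, adaptive
    dual thresholds with a 200 ms refractory period and searchback at half
    threshold when an expected beat is missed.  Zero-delay (centered)
    derivative and integration are used so each integrator fiducial sits on
    the QRS; the returned indices are refined to the local maximum of the
    filtered ECG within +/-50 ms.

    Returns an array of strictly increasing R sample indices (possibly empty;
    flat input yields no beats rather than an error).
    """
    x = ecg_filtered.samples
    fs = ecg_filtered.fs
    if x.size < 2 * fs:
        raise ValueError("detect_qrs needs at least 2 s of signal")

    deriv = np.gradient(x) * fs
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(0.200 * fs)))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # global-percentile initialization: the 99th percentile of the integrated
    # energy tracks QRS peaks and the median tracks the noise floor, so the
    # thresholds start sensibly even when the record opens with silence
    spki = 0.6 * float(np.percentile(mwi, 99))
    npki = 0.5 * float(np.median(mwi))
    if spki <= 0:
        return np.array([], dtype=int)

    qrs: List[int] = []
    noise_cand: List[int] = []
    rr_intervals: List[float] = []
    for i in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[i] > thr1 and (not qrs or i - qrs[-1] > refractory):
            if qrs:
                rr_intervals.append(float(i - qrs[-1]))
            qrs.append(int(i))
            spki = 0.125 * mwi[i] + 0.875 * spki
            noise_cand.clear()
            continue
        npki = 0.125 * mwi[i] + 0.875 * npki
        noise_cand.append(int(i))
        # searchback: if more than 1.66*RRavg elapsed, accept the best
        # rejected candidate above half threshold
        if qrs and rr_intervals:
            rr_avg = float(np.mean(rr_intervals[-8:]))
            if i - qrs[-1] > 1.66 * rr_avg:
                back = [j for j in noise_cand if j - qrs[-1] > refractory
                        and mwi[j] > 0.5 * thr1]
                if back:
                    best = max(back, key=lambda j: mwi[j])
                    rr_intervals.append(float(best - qrs[-1]))
                    qrs.append(best)
                    qrs.sort()
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    noise_cand.clear()

    # refine to the local max of the filtered ECG within +/-50 ms
    half = max(1, int(round(0.050 * fs)))
    refined: List[int] = []
    for i in qrs:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = sorted(set(refined))

    # enforce refractory after refinement, keeping the larger R
    out: List[int] = []
    for r in refined:
        if out and r - out[-1] <= refractory:
            if x[r] > x[out[-1]]:
                out[-1] = r
        else:
            out.append(r)
    return np.asarray(out, dtype=int)


def locate_qs(ecg_filtered: Waveform, r_idx: int, search_ms: float = 100.0) -> QrsComplex:
    """Locate Q and S as local minima before/after the R peak.

    Q is the argmin over the ``search_ms`` window before R (exclusive), S the
    argmin over the window after R (exclusive); windows are clipped at record
    edges, and an empty window collapses onto R (logged).  Ties break toward
    the earliest index.
    """
    x = ecg_filtered.samples
    if not 0 <= r_idx < x.size:
        raise ValueError(f"r_idx {r_idx} outside record")
    span = max(1, int(round(search_ms / 1000.0 * ecg_filtered.fs)))

    lo = max(0, r_idx - span)
    if lo < r_idx:
        q_idx = lo + int(np.argmin(x[lo:r_idx]))
    else:
        logger.info("locate_qs: empty Q window at r_idx=%d", r_idx)
        q_idx = r_idx

    hi = min(x.size, r_idx + span + 1)
    if r_idx + 1 < hi:
        s_idx = r_idx + 1 + int(np.argmin(x[r_idx + 1:hi]))
    else:
        logger.info("locate_qs: empty S window at r_idx=%d", r_idx)
        s_idx = r_idx
    return QrsComplex(q_idx=q_idx, r_idx=r_idx, s_idx=s_idx)


def feature_r_amplitude(x: Waveform, qrs: QrsComplex) -> float:
    """R_i = max of x over the QRS span [q_idx, s_idx]."""
    return float(np.max(x.samples[qrs.q_idx:qrs.s_idx + 1]))


def feature_up_slope(x: Waveform, qrs: QrsComplex) -> float:
    """Max |x_j - x_{j-1}| for j in (q_idx, r_idx]; units per sample.

    Degenerate q_idx == r_idx returns 0 (logged).  Multiply by fs for
    units-per-second if needed; RR extraction is invariant to that scaling.
    """
    if qrs.q_idx == qrs.r_idx:
        logger.info("feature_up_slope: degenerate q==r at %d", qrs.r_idx)
        return 0.0
    seg = x.samples[qrs.q_idx:qrs.r_idx + 1]
    return float(np.max(np.abs(np.diff(seg))))


def feature_down_slope(x: Waveform, qrs: QrsComplex) -> float:
    """Max |x_{j+1} - x_j| for j in [r_idx, s_idx); 0 when r == s."""
    if qrs.r_idx == qrs.s_idx:
        logger.info("feature_down_slope: degenerate r==s at %d", qrs.r_idx)
        return 0.0
    seg = x.samples[qrs.r_idx:qrs.s_idx + 1]
    return float(np.max(np.abs(np.diff(seg))))


def _crossing(dev: np.ndarray, lo: int, hi: int, prefer_late: bool) -> int:
    """Index in (lo, hi) splitting a sign change of *dev*, or -1 if none.

    Exact zeros are taken as crossings; for a sign change between adjacent
    samples the one closer to the baseline wins.  ``prefer_late`` picks the
    crossing nearest *hi* (used before R), else nearest *lo* (after R).
    """
    idxs: List[int] = []
    for j in range(lo + 1, hi):
        if dev[j] == 0.0:
            idxs.append(j)
        elif dev[j - 1] != 0.0 and np.sign(dev[j]) != np.sign(dev[j - 1]):
            idxs.append(j if abs(dev[j]) <= abs(dev[j - 1]) else j - 1)
    idxs = [j for j in idxs if lo < j < hi]
    if not idxs:
        return -1
    return max(idxs) if prefer_late else min(idxs)


def feature_qrs_area(x: Waveform, qrs: QrsComplex) -> float:
    """Sum of absolute trapezoidal areas of the Q, R and S waves.

    The baseline is the median of x over [q_idx, s_idx]; the span is
    partitioned at the baseline crossings nearest R on either side (falling
    back to the Q-R / R-S midpoints when no crossing exists), and each
    sub-wave's area is the trapezoidal integral of (x - baseline) in
    signal-units * seconds.
    """
    q, r, s = qrs.q_idx, qrs.r_idx, qrs.s_idx
    if q == s:
        logger.info("feature_qrs_area: degenerate q==s at %d", r)
        return 0.0
    seg = x.samples[q:s + 1]
    dev = seg - float(np.median(seg))
    rl = r - q  # R position local to the segment
    c1 = _crossing(dev, 0, rl, prefer_late=True)
    if c1 < 0:
        c1 = rl // 2
    c2 = _crossing(dev, rl, dev.size - 1, prefer_late=False)
    if c2 < 0:
        c2 = (rl + dev.size - 1) // 2
    dx = 1.0 / x.fs
    total = 0.0
    for a, b in ((0, c1), (c1, c2), (c2, dev.size - 1)):
        if b > a:
            total += abs(float(np.trapezoid(dev[a:b + 1], dx=dx)))
    return total


_FEATURE_OPS = {
    "r_amp": feature_r_amplitude,
    "qrs_area": feature_qrs_area,
    "up_slope": feature_up_slope,
    "down_slope": feature_down_slope,
}


def extract_feature_series(ecg: Waveform, feature: str, *, bandpass: bool = True,
                           search_ms: float = 100.0) -> BeatFeatureSeries:
    """Detect beats and evaluate one morphological feature per beat.

    Set ``bandpass=False`` if *ecg* has already been conditioned.  Raises if
    fewer than 3 beats are found (the spline reconstruction downstream needs
    at least 3 knots).
    """
    if feature not in _FEATURE_OPS:
        raise ValueError(f"unknown ECG feature {feature!r}; choose from {ECG_FEATURES}")
    filt = bandpass_ecg(ecg) if bandpass else ecg
    r_idxs = detect_qrs(filt)
    if r_idxs.size < 3:
        raise ValueError(f"only {r_idxs.size} beats detected; need >= 3")
    op = _FEATURE_OPS[feature]
    complexes = [locate_qs(filt, int(r), search_ms=search_ms) for r in r_idxs]
    values = np.array([op(filt, c) for c in complexes])
    times = filt.t0 + r_idxs / filt.fs
    return BeatFeatureSeries(feature=feature, times=times, values=values)
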