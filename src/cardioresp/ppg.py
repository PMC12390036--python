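"""PPG conditioning, pulse-extrema detection, and AM/FM beat series.

The PPG-derived respiration (PDR) chain smooths the pulse waveform
(8th-order Butterworth low-pass at 10 Hz, multilevel wavelet denoising,
Savitzky-Golay), detects each systolic maximum and the diastolic trough
preceding it, and reads two respiratory modulations off the pulse train:

* AM - pulse amplitude, x[peak] - x[trough], respiration-driven stroke
  volume changes;
* FM - systolic peak-to-peak interval, respiratory sinus arrhythmia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import pywt
from scipy import signal as sps

from .core import BeatFeatureSeries, Waveform

logger = logging.getLogger(__name__)

PPG_FEATURES = ("am", "fm")


@dataclass(frozen=True)
class PulseExtrema:
    """Systolic maximum and the preceding diastolic minimum of one pulse."""

    peak_idx: int
    trough_idx: int

    def __post_init__(self) -> None:
        if not self.trough_idx < self.peak_idx:
            raise ValueError("trough_idx must precede peak_idx")


def lowpass_ppg(ppg: Waveform, cutoff_hz: float = 10.0, order: int = 8) -> Waveform:
    """Zero-phase Butterworth low-pass with unit DC gain."""
    if not ppg.fs > 2 * cutoff_hz:
        raise ValueError(f"fs={ppg.fs} too low for a {cutoff_hz} Hz cutoff")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=ppg.fs, output="sos")
    return ppg.with_samples(sps.sosfiltfilt(sos, ppg.samples))


def wavelet_smooth(ppg: Waveform, levels: int = 11, wavelet: str = "db4",
                   zero_finest: int = 2) -> Waveform:
    """Multilevel wavelet denoising: zero the finest detail bands.

    A ``levels``-deep discrete wavelet decomposition is taken (reduced to the
    maximum feasible depth for short signals, logged); the ``zero_finest``
    finest detail bands are zeroed and the signal reconstructed at its
    original length.  Constants pass through untouched (they live entirely in
    the approximation band).
    """
    x = ppg.samples
    wav = pywt.Wavelet(wavelet)
    max_lvl = pywt.dwt_max_level(x.size, wav.dec_len)
    lvl = min(levels, max_lvl)
    if lvl < levels:
        logger.info("wavelet_smooth: reduced levels %d -> %d for n=%d",
                    levels, lvl, x.size)
    if lvl < 1:
        return ppg.with_samples(x.copy())
    coeffs = pywt.wavedec(x, wav, level=lvl)
    for k in range(1, min(zero_finest, lvl) + 1):
        coeffs[-k] = np.zeros_like(coeffs[-k])
    rec = pywt.waverec(coeffs, wav)
    return ppg.with_samples(rec[: x.size])


def savgol_smooth(x: Waveform, window_ms: float = 250.0, polyorder: int = 3) -> Waveform:
    """Savitzky-Golay local least-squares polynomial smoothing.

    The window is converted to samples and forced odd; it must exceed the
    polynomial order.
    """
    win = int(round(window_ms / 1000.0 * x.fs))
    if win % 2 == 0:
        win += 1
    if win <= polyorder:
        raise ValueError(
            f"Savitzky-Golay window ({win} samples) must exceed polyorder "
            f"({polyorder}); lengthen window_ms or lower the order")
    return x.with_samples(sps.savgol_filter(x.samples, win, polyorder))


def smooth_ppg(ppg: Waveform, *, cutoff_hz: float = 10.0, order: int = 8,
               levels: int = 11, window_ms: float = 250.0,
               polyorder: int = 3) -> Waveform:
    """Full conditioning chain: low-pass, wavelet denoise, Savitzky-Golay."""
    return savgol_smooth(
        wavelet_smooth(lowpass_ppg(ppg, cutoff_hz, order), levels=levels),
        window_ms=window_ms, polyorder=polyorder)


def _select_peaks(x: np.ndarray, dist: int) -> np.ndarray:
    """Local maxima at least ``dist`` samples apart: highest wins a conflict,
    the earliest wins a tie."""
    import bisect

    cand, _ = sps.find_peaks(x)
    kept: list = []
    for c in sorted(cand.tolist(), key=lambda i: (-x[i], i)):
        j = bisect.bisect_left(kept, c)
        left_ok = j == 0 or c - kept[j - 1] >= dist
        right_ok = j == len(kept) or kept[j] - c >= dist
        if left_ok and right_ok:
            kept.insert(j, c)
    return np.asarray(kept, dtype=int)


def detect_pulse_extrema(ppg_smooth: Waveform, hr_max_bpm: float = 220.0,
                         prominence_frac: float = 0.3) -> List[PulseExtrema]:
    """Detect systolic peaks and their preceding diastolic troughs.

    Peaks are local maxima at least ``60/hr_max_bpm`` s apart whose
    prominence reaches ``prominence_frac`` of the typical (median) systolic
    peak-to-trough excursion; this keeps systolic peaks while rejecting
    dicrotic bumps and ripple.  Because a distance-only candidate pass can
    contain up to one dicrotic bump per pulse, the typical excursion is
    estimated as the upper quartile of candidate prominences (the median of
    the systolic half of a bimodal candidate set).  Each trough is the
    minimum between consecutive retained peaks; the first trough is the
    minimum over the 0.5 s before the first peak.
    """
    x = ppg_smooth.samples
    fs = ppg_smooth.fs
    if x.size < 2 * fs:
        raise ValueError("detect_pulse_extrema needs at least 2 s of signal")
    dist = max(1, int(round(60.0 / hr_max_bpm * fs)))
    cand = _select_peaks(x, dist)
    if cand.size == 0:
        return []
    prominences = sps.peak_prominences(x, cand)[0]
    med_exc = float(np.percentile(prominences, 75))
    if med_exc <= 0:
        return []
    peaks = cand[prominences >= prominence_frac * med_exc]
    if peaks.size == 0:
        return []

    out: List[PulseExtrema] = []
    first_lo = max(0, peaks[0] - int(round(0.5 * fs)))
    if peaks[0] > first_lo:
        t0 = first_lo + int(np.argmin(x[first_lo:peaks[0]]))
        out.append(PulseExtrema(peak_idx=int(peaks[0]), trough_idx=t0))
    for a, b in zip(peaks[:-1], peaks[1:]):
        trough = a + int(np.argmin(x[a:b]))
        out.append(PulseExtrema(peak_idx=int(b), trough_idx=trough))
    return out


def am_series(ppg_smooth: Waveform, extrema: List[PulseExtrema]) -> BeatFeatureSeries:
    """Pulse-amplitude (AM) series: x[peak] - x[preceding trough] per pulse."""
    if len(extrema) < 3:
        raise ValueError(f"am_series needs >= 3 pulses, got {len(extrema)}")
    x = ppg_smooth.samples
    values = np.array([x[e.peak_idx] - x[e.trough_idx] for e in extrema])
    times = ppg_smooth.t0 + np.array([e.peak_idx for e in extrema]) / ppg_smooth.fs
    return BeatFeatureSeries(feature="ppg_am", times=times, values=values)


def fm_series(extrema: List[PulseExtrema], fs: float, t0: float = 0.0) -> BeatFeatureSeries:
    """Peak-to-peak interval (FM) series, stamped at interval midpoints.

    RSA makes these intervals oscillate at the respiratory rate; the midpoint
    stamp centers each spline knot on the interval it measures.
    """
    if len(extrema) < 4:
        raise ValueError(f"fm_series needs >= 4 pulses, got {len(extrema)}")
    peaks = np.array([e.peak_idx for e in extrema], dtype=float)
    values = np.diff(peaks) / fs
    times = t0 + (peaks[:-1] + peaks[1:]) / 2.0 / fs
    return BeatFeatureSeries(feature="ppg_fm", times=times, values=values)


def extract_feature_series(ppg: Waveform, feature: str, *, smooth: bool = True,
                           **smooth_kwargs) -> BeatFeatureSeries:
    """Condition the PPG (optional) and extract the AM or FM beat series."""
    if feature not in PPG_FEATURES:
        raise ValueError(f"unknown PPG feature {feature!r}; choose from {PPG_FEATURES}")
    cond = smooth_ppg(ppg, **smooth_kwargs) if smooth else ppg
    extrema = detect_pulse_extrema(cond)
    if feature == "am":
        return am_series(cond, extrema)
    return fm_series(extrema, cond.fs, t0=cond.t0)
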