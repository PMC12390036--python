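"""Synthetic cardiorespiratory signal generator.

Respiration modulates cardiovascular waveforms in three ways: amplitude
modulation (AM) of the beat envelope, baseline wander (BW), and frequency
modulation (FM) of the beat-to-beat period via respiratory sinus arrhythmia.
This module builds ECG and PPG records in which all three modulations are
driven by a *known* respiration signal, so the downstream surrogate-
respiration pipeline can be tested against ground truth.

ECG beats are sums of five Gaussian bumps (P, Q, R, S, T) at fixed offsets
from the beat time; PPG pulses are a systolic Gaussian plus a dicrotic bump.
Beat k is scaled by ``1 + am_depth * r(t_k)``; the instantaneous beat period
is ``(60/hr_bpm) * (1 - fm_depth * r(t_k))``; the baseline ``bw_amp * r(t)``
and seeded white Gaussian noise are added.  Identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import Waveform

logger = logging.getLogger(__name__)

# (offset_s, amplitude, gaussian sd_s) relative to the beat (R-apex) time
ECG_WAVES: Tuple[Tuple[float, float, float], ...] = (
    (-0.200, 0.12, 0.025),   # P
    (-0.025, -0.16, 0.010),  # Q
    (0.000, 1.00, 0.012),    # R
    (0.025, -0.25, 0.010),   # S
    (0.250, 0.35, 0.060),    # T
)
#: end of the QRS support relative to the beat time; a final beat whose QRS
#: would extend past the record end is dropped (and logged), not half-drawn.
_QRS_END_S = 0.025 + 3 * 0.010

# PPG template, relative to the instantaneous period p: systolic Gaussian at
# the beat time, dicrotic bump at 0.45*p.  Widths scale with p so pulses stay
# separable across heart rates.
_PPG_SYS_AMP = 1.0
_PPG_DIC_AMP = 0.25


@dataclass(frozen=True)
class ModulationSpec:
    """Study conditions for one synthetic record.

    Depth parameters are fractional: ``am_depth=0.2`` swings beat amplitudes
    by ±20 %, ``fm_depth=0.1`` swings the heart period by ±10 % (RSA).
    ``bw_amp`` and ``noise_sd`` are in signal units (templates peak at 1.0).
    ``rr_bpm_end``, when set, ramps the respiratory rate linearly from
    ``rr_bpm`` to ``rr_bpm_end`` over the record (emulating an exercise
    acceleration phase).
    """

    duration_s: float = 480.0
    fs: float = 300.0
    hr_bpm: float = 70.0
    rr_bpm: float = 15.0
    am_depth: float = 0.2
    bw_amp: float = 0.1
    fm_depth: float = 0.1
    noise_sd: float = 0.01
    seed: int = 0
    rr_bpm_end: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs < 100:
            raise ValueError(f"fs must be >= 100 Hz, got {self.fs}")
        if not 20 <= self.hr_bpm <= 220:
            raise ValueError(f"hr_bpm must be in [20, 220], got {self.hr_bpm}")
        for name, val in (("rr_bpm", self.rr_bpm), ("rr_bpm_end", self.rr_bpm_end)):
            if val is None:
                continue
            if not 4 <= val <= 60:
                raise ValueError(f"{name} must be in [4, 60], got {val}")
            if not val * 1.5 < self.hr_bpm:
                raise ValueError(
                    f"{name}={val} too fast for hr_bpm={self.hr_bpm}: need "
                    "rr_bpm*1.5 < hr_bpm so beats resolve the modulation")
        if not 0 <= self.am_depth < 1:
            raise ValueError(f"am_depth must be in [0, 1), got {self.am_depth}")
        if not 0 <= self.fm_depth < 1:
            raise ValueError(f"fm_depth must be in [0, 1), got {self.fm_depth}")
        if self.bw_amp < 0:
            raise ValueError(f"bw_amp must be >= 0, got {self.bw_amp}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class SyntheticRecord:
    """A generated record plus its ground truth."""

    resp_ref: Waveform
    beat_times_true: List[float]
    rr_true_bpm: float
    ecg: Optional[Waveform] = None
    ppg: Optional[Waveform] = None


def _resp_phase(spec: ModulationSpec, t: np.ndarray) -> np.ndarray:
    """Respiratory phase in cycles at time(s) t."""
    f0 = spec.rr_bpm / 60.0
    if spec.rr_bpm_end is None:
        return f0 * t
    slope = (spec.rr_bpm_end - spec.rr_bpm) / 60.0 / spec.duration_s
    return f0 * t + 0.5 * slope * t ** 2


def resp_value(spec: ModulationSpec, t) -> np.ndarray:
    """The normalized respiration signal r(t) = sin(2*pi*phase(t))."""
    return np.sin(2 * np.pi * _resp_phase(spec, np.asarray(t, dtype=np.float64)))


def resp_peak_times(spec: ModulationSpec) -> np.ndarray:
    """Analytic times of the respiration maxima within [0, duration_s).

    Maxima occur where the phase equals k + 1/4 cycles; for a rate ramp the
    quadratic phase is inverted in closed form.
    """
    f0 = spec.rr_bpm / 60.0
    total = float(_resp_phase(spec, np.asarray(spec.duration_s)))
    ks = np.arange(0, math.ceil(total) + 1) + 0.25
    if spec.rr_bpm_end is None:
        times = ks / f0
    else:
        slope = (spec.rr_bpm_end - spec.rr_bpm) / 60.0 / spec.duration_s
        if slope == 0:
            times = ks / f0
        else:
            times = (-f0 + np.sqrt(f0 ** 2 + 2 * slope * ks)) / slope
    return times[(times >= 0) & (times < spec.duration_s)]


def generate_respiration(spec: ModulationSpec) -> Waveform:
    """Reference respiration: unit sinusoid at rr_bpm (or the rr ramp)."""
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    return Waveform(resp_value(spec, t), fs=spec.fs, label="resp")


def generate_beat_times(spec: ModulationSpec) -> List[float]:
    """FM-modulated beat times: cumulative sums of the instantaneous period.

    ``p_k = (60/hr_bpm) * (1 - fm_depth * r(t_k))`` starting at t = 0;
    strictly increasing by construction since fm_depth < 1.
    """
    base = 60.0 / spec.hr_bpm
    times: List[float] = []
    t = 0.0
    while t < spec.duration_s:
        times.append(t)
        t += base * (1.0 - spec.fm_depth * float(resp_value(spec, t)))
    return times


def _add_gaussian(y: np.ndarray, fs: float, center_s: float,
                  amp: float, sd_s: float) -> None:
    lo = max(0, int(math.floor((center_s - 4 * sd_s) * fs)))
    hi = min(y.size, int(math.ceil((center_s + 4 * sd_s) * fs)) + 1)
    if hi <= lo:
        return
    tt = np.arange(lo, hi) / fs
    y[lo:hi] += amp * np.exp(-0.5 * ((tt - center_s) / sd_s) ** 2)


def _finalize(spec: ModulationSpec, y: np.ndarray, stream: int) -> np.ndarray:
    n = y.size
    t = np.arange(n) / spec.fs
    y = y + spec.bw_amp * resp_value(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, stream])
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    return y


def generate_ecg(spec: ModulationSpec) -> SyntheticRecord:
    """Synthesize the ECG channel (plus reference respiration and truth).

    Each beat's five-Gaussian template is snapped so the R apex falls exactly
    on a sample; the whole template is scaled by ``1 + am_depth * r(t_k)``.
    """
    n = int(round(spec.duration_s * spec.fs))
    y = np.zeros(n)
    kept: List[float] = []
    for tk in generate_beat_times(spec):
        tk_s = round(tk * spec.fs) / spec.fs
        if tk_s + _QRS_END_S > spec.duration_s:
            logger.info("generate_ecg: dropped final partial beat at %.3f s", tk)
            continue
        scale = 1.0 + spec.am_depth * float(resp_value(spec, tk_s))
        for off, amp, sd in ECG_WAVES:
            _add_gaussian(y, spec.fs, tk_s + off, scale * amp, sd)
        kept.append(tk_s)
    ecg = Waveform(_finalize(spec, y, stream=101), fs=spec.fs, label="ecg")
    return SyntheticRecord(ecg=ecg, resp_ref=generate_respiration(spec),
                           beat_times_true=kept, rr_true_bpm=spec.rr_bpm)


def generate_ppg(spec: ModulationSpec) -> SyntheticRecord:
    """Synthesize the PPG channel: systolic Gaussian + dicrotic bump per beat.

    Systolic maxima and the diastolic troughs preceding them remain
    recoverable across heart rates because template widths scale with the
    instantaneous period.
    """
    n = int(round(spec.duration_s * spec.fs))
    y = np.zeros(n)
    beats = generate_beat_times(spec)
    base = 60.0 / spec.hr_bpm
    kept: List[float] = []
    for i, tk in enumerate(beats):
        p = (beats[i + 1] - tk) if i + 1 < len(beats) else base
        tk_s = round(tk * spec.fs) / spec.fs
        if tk_s + 0.12 * p > spec.duration_s:
            logger.info("generate_ppg: dropped final partial pulse at %.3f s", tk)
            continue
        scale = 1.0 + spec.am_depth * float(resp_value(spec, tk_s))
        _add_gaussian(y, spec.fs, tk_s, scale * _PPG_SYS_AMP, 0.12 * p)
        _add_gaussian(y, spec.fs, tk_s + 0.45 * p, scale * _PPG_DIC_AMP, 0.14 * p)
        kept.append(tk_s)
    ppg = Waveform(_finalize(spec, y, stream=202), fs=spec.fs, label="ppg")
    return SyntheticRecord(ppg=ppg, resp_ref=generate_respiration(spec),
                           beat_times_true=kept, rr_true_bpm=spec.rr_bpm)


def generate_record(spec: ModulationSpec) -> SyntheticRecord:
    """ECG + PPG + reference respiration with shared beat times and truth."""
    e = generate_ecg(spec)
    p = generate_ppg(spec)
    return SyntheticRecord(ecg=e.ecg, ppg=p.ppg, resp_ref=e.resp_ref,
                           beat_times_true=e.beat_times_true,
                           rr_true_bpm=spec.rr_bpm)
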