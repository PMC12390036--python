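# Methods

This note documents the models, parameter choices and numerical conventions
behind `cardioresp`, and what the synthetic experiments do and do not show.

## Signal model and generator

The generator treats respiration as the driver of three modulations of the
cardiac waveform train:

- **AM** — beat *k*'s template is scaled by `1 + am_depth · r(t_k)`, where
  `r(t) = sin(2π ∫ f_R(τ) dτ)` is the unit respiration signal;
- **BW** — `bw_amp · r(t)` is added to the whole record;
- **FM (RSA)** — the instantaneous beat period is
  `p_k = (60/hr_bpm) · (1 − fm_depth · r(t_k))`, and beat times are the
  cumulative sums of `p_k` from `t = 0`.

ECG beats are sums of five Gaussians (P, Q, R, S, T) at fixed offsets
(−200, −25, 0, +25, +250 ms) and widths (25, 10, 12, 10, 60 ms), amplitudes
(0.12, −0.16, 1.0, −0.25, 0.35); PPG pulses are a systolic Gaussian at the
beat time plus a dicrotic bump at 45 % of the instantaneous period, widths
scaling with the period so pulses stay separable from 50 to 120 bpm. These
are conventional synthetic-morphology choices: the pipeline contract only
requires that the fiducials (R peaks, systolic peaks/troughs) be
recoverable, not that the shapes be physiologically detailed. The R apex of
each beat is snapped to the nearest sample so ground-truth beat indices are
exact. Noise is white Gaussian only; all randomness flows from the single
`seed` through per-channel `numpy` generator streams, so an identical spec
reproduces a record bit for bit.

Default conditions (480 s, 300 Hz, 70 bpm heart rate, AM depth 0.2, BW
0.1, FM 0.1, noise sd 0.01–0.02 against a unit R amplitude) represent a
resting adult with clearly expressed but not extreme respiratory coupling;
rates between 4 and 60 breaths/min are accepted provided there are at
least ~1.5 beats per breath, below which a beat-sampled modulation is not
resolvable. A linear rate ramp (`rr_bpm → rr_bpm_end`) emulates an exercise
acceleration phase; its analytic phase integral gives closed-form
ground-truth breath-peak times.

What the generator does **not** emulate: motion and powerline artifact,
ectopy and arrhythmia, pulse-morphology changes other than uniform scaling,
apnea, and sensor-specific transfer functions. Passing tests therefore
demonstrate algorithmic correctness and noise robustness of the stated
kind, not field performance on clinical recordings.

## ECG chain

- Band-pass 5–40 Hz, 4th-order Butterworth applied forward–backward:
  zero-phase filtering preserves fiducial timing; the band removes baseline
  wander and P/T energy while keeping QRS content.
- Pan–Tompkins detection: derivative → squaring → 150 ms moving-window
  integration → adaptive dual thresholds with a 200 ms refractory period
  and searchback at half threshold after 1.66 × the running RR average.
  The derivative and integrator are realized with centered (zero-delay)
  kernels so the ±50 ms refinement to the filtered-ECG maximum needs no
  group-delay bookkeeping. Thresholds initialize from global percentiles of
  the integrated energy (99th for signal, median for noise), which behaves
  sensibly when a record opens with silence.
- Q and S are the argmin over 100 ms windows before/after R (exclusive of
  R; clipped at record edges, ties to the earliest index). 100 ms bounds
  the QRS at physiological widths.
- QRS area: baseline = median over [Q, S]; the span is partitioned at the
  baseline crossings nearest R on each side (midpoint fallback when a wave
  does not cross), and the three sub-wave trapezoidal areas are summed in
  absolute value, in signal-units·seconds. The partition rule is this
  package's construction; only the sum-of-absolute-areas form is inherited.
- Slopes are per-sample first differences; rate extraction is invariant to
  the per-sample vs per-second scaling, so no fs factor is applied.

## PPG chain

- 8th-order Butterworth low-pass at 10 Hz (zero-phase, unit DC gain), then
  an 11-level Daubechies-4 decomposition with the two finest detail bands
  zeroed (depth reduced and logged on short signals), then Savitzky–Golay
  smoothing (250 ms window forced odd, order 3).
- Systolic peaks: local maxima at least 60/220 s apart (220 bpm ceiling)
  with prominence ≥ 0.3 of the typical pulse excursion. The typical
  excursion is estimated as the *upper quartile* of candidate prominences:
  a distance-only candidate pass can contain one dicrotic bump per pulse,
  which makes the candidate prominence distribution bimodal and the plain
  median unstable. Conflicting peaks resolve highest-first, earliest on a
  tie. Each trough is the minimum between consecutive retained peaks (the
  first: minimum over the 0.5 s before the first peak).
- AM = peak minus preceding trough (baseline-robust, unlike raw peak
  height); FM = systolic peak-to-peak interval, stamped at the interval
  midpoint so each spline knot is centered on what it measures.
  Peak-to-peak (rather than trough-to-trough) intervals are this package's
  documented choice.

## Surrogate respiration and rate

A natural cubic spline through the beat-feature knots is evaluated on a
uniform 4 Hz grid over the knot span only — extrapolated cubics oscillate
and fabricate peaks — and normalized to [0, 1]. 4 Hz is Nyquist-safe for
rates up to 60 breaths/min, and peak counts are insensitive to the
evaluation rate above that. Respiratory peaks are local maxima at least
60/60 s apart with prominence ≥ 0.1 (normalized units); the same detector
serves derived surrogates and the (Savitzky–Golay-smoothed) reference
channel. Windows are contiguous, non-overlapping, half-open `[kT, (k+1)T)`
with the trailing remainder discarded; `RR = N_peaks · 60 / T` holds
exactly per window, so rates are quantized to 60/T breaths/min (2 at
T = 30 s, 1 at T = 60 s). A nanosecond-scale slop in the window count
guards against durations recovered from written time stamps falling one
ulp short.

## Evaluation

Differences are oriented derived − reference (negative bias =
underestimation). Bland–Altman uses the sample (n−1) standard deviation
and 1.96 limits. Pearson ρ uses the t-transform p-value with n−2 df and
bands at 0.3/0.7 on |ρ| (boundaries → moderate). The Wilcoxon signed-rank
test drops zero differences, mid-ranks ties, and uses an exact null — the
rank-sum distribution built by convolution over doubled (integerized)
mid-ranks, equivalent to enumerating all 2^m sign assignments — for
m ≤ 15, switching to a tie-corrected normal approximation with continuity
correction beyond. α = 0.05 two-sided throughout, with no multiple-testing
correction. Overall metrics average the metric values computed on
per-subject mean pairs and on per-window mean pairs; ρ p-values are
averaged by the same convention (a reporting convention, not a combined
test). Intra-subject Bland–Altman is emitted both pooled over all windows
and on per-subject means, since either aggregation is defensible.

## Experiment sizes and checks

The verification experiments use 8-minute records at 300 Hz (and 4-minute
records for detector scoring and trend corpora) — long enough for 8–16
analysis windows per record while keeping the whole suite fast. Recovery is
scored as the mean per-window |rr_est − rr_true| pooled over rates
{10, 15, 20, 25} breaths/min: at T = 30 s, rates whose period does not
divide the window (15, 25) alternate between adjacent counts and contribute
an irreducible 1 breath/min per window even for a perfect counter, which
the pooled mean reflects. The rate-ramp tracking check (19 → 22 breaths/min
over 8 min) is evaluated on 60 s windows, whose 1 breath/min quantization
can express a 3 breaths/min ramp; at 30 s the 2 breaths/min steps tie most
windows and cap the rank correlation near 0.7 *for the ground truth
itself* (the estimator reproduces the true window counts exactly in both
cases).

## Known limitations

- Beats at the record edges are half-observed; their features deviate and
  the first/last analysis window can lose a boundary breath.
- The AM/FM surrogates assume one systolic peak per beat; severe dicrotic
  accentuation beyond the prominence gate's reach, or heart rates above
  220 bpm, break the extrema contract.
- The evaluation table requires a complete subject × window grid; records
  of unequal usable length must be trimmed by the caller.
- WFDB input is an optional code path requiring the `wfdb` package; CSV is
  the built-in format. EDF/BDF are not supported.
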