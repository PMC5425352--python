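# Methods

`ecgcreativity` studies whether the autonomic state visible in a single-lead
ECG changes when a person moves from rest into figural creativity tasks, and
whether those changes separate recording conditions and high- vs
low-creativity individuals.  Because no recordings ship with the package,
every stage is exercised against a synthetic cohort whose statistical
structure is controlled and known; this note documents the models, the
defaults and their rationale, and what the synthetic results do and do not
show.

## Synthetic cohort

**RR tachogram.**  Beat times are generated by a modulated-interval model:
the instantaneous interval (ms) is

    I(t) = 60000 / HR  +  m_LF(t) + m_HF(t) + e,

where `m_LF` and `m_HF` are mixtures of 24 random-phase sinusoids confined
to the LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) HRV bands and `e` is white
per-beat jitter carrying 5 % of the variance.  Band variances are set in
the ratio of the target LF/HF and the total is scaled to the target SDNN,
so the band-power ratio is controlled analytically rather than emergently.
An integral-pulse-frequency-modulation model would be more physiological
but does not give this closed-form control.  The empirical LF/HF estimated
back through the spectral module converges to the target within ~15 % for
600 s records (verified per seed in the tests).

**Waveform.**  One fixed P-QRS-T template — five Gaussian bumps in time
relative to the R peak, R amplitude 1 mV — is superposed at each beat time.
Tails of adjacent templates simply add; an inter-beat interval below 0.3 s
(where QRS cores would merge) is an error.  Noise terms: a 50 Hz powerline
sinusoid, three slow (<0.5 Hz) drift sinusoids for baseline wander, and
white broadband noise, all with configurable mV amplitudes.  The first beat
is placed 0.4 s into the record so the first template is complete.  The
simulator makes no attempt at clinical fidelity (no ectopy, respiration
coupling or multi-lead morphology); the features under test depend on beat
timing and broad morphology only.

**Condition presets** (synthetic choices, not measured values): rest
HR 65 bpm / SDNN 40 ms / LF-HF 1.5; task1 75 / 55 / 3.0; task2 72 / 50 /
2.2; task3 70 / 48 / 2.0.  They encode the qualitative pattern the analysis
is meant to detect — heart rate and sympathovagal balance rise sharply into
the first task and relax through the later ones — with magnitudes chosen as
plausible for young adults under mild cognitive load.  Each subject gets
small random effects (±1.5 bpm HR, ~8 % lognormal on SDNN and LF/HF).

**Creativity coupling.**  Each subject draws a 0–100 creativity score; the
default distribution is an equal mixture of N(20, 8) and N(80, 8) so both
the high (>70) and low (<30) groups are populated.  During task conditions
a subject with score `s` receives `6 · (s − 50)/50` bpm of extra heart rate
and a `1 + 0.4 · (s − 50)/50` multiplier on LF/HF.  This is the injected
ground truth that group classification must recover; rest recordings are
uncoupled, so group separation must come from task physiology.

## Preprocessing

50 Hz second-order IIR notch (Q = 30) followed by an order-4 Chebyshev II
band-pass with stopband edges 0.3 and 250 Hz and 40 dB attenuation (a
conventional value giving a well-conditioned design; at 1000 Hz sampling
the 250 Hz edge is valid, just below Nyquist).  Both filters run
forward-backward, so phase is zero and R-peak timing is undistorted, at the
cost of doubling the effective attenuation.  Frequency-response tests
discard 2 s of filter transient at the record edges; the pipeline itself
relies on the protocol's own 0.6 s head trim.  After filtering, the first
0.6 s is dropped, the next 120 s form the analysis segment, and the segment
is cut into non-overlapping 5 s windows (trailing partial window dropped).
Filtering precedes windowing, the standard order.

## Beat detection and NN series

A Pan-Tompkins-style detector (5–15 Hz band-pass, derivative, squaring,
150 ms moving integration, peak picking with a 200 ms refractory period)
with the threshold set as a fraction of a high quantile of the detection
function, making it invariant to amplitude rescaling.  Detections are
refined to the raw-signal argmax within ±50 ms, giving ≤1-sample timing
error on noise-free synthetic beats.  Successive beat-time differences form
the NN series; intervals outside 250–3000 ms are flagged abnormal and
excluded from all NN statistics (the protocol itself specifies no artifact
policy, so a physiologic gate guards SDNN/RMSSD against detector errors).

## Features (the 19-column panel)

*Time domain* (per 5 s window, from the intervals ending inside the
window): mean NN, SDNN (sample SD, `ddof=1`, configurable), RMSSD, NN50
(strict |ΔNN| > 50 ms), pNN50 = 100·NN50/(N−1), min/max/median NN.  "RMSD"
is implemented as RMSSD, the standard short-term HRV statistic; an RMS
deviation from the mean would duplicate SDNN.  An amplitude-statistics
variant (mean/min/max/median/RMS of raw mV samples) is available for the
alternative reading in which these statistics are taken on the waveform
itself; the NN-based panel is the default.

*Frequency domain* (per 120 s segment, broadcast to its windows): the NN
tachogram is cubic-interpolated to 4 Hz, mean-detrended, and Welch-estimated
(Hann, 150 s segments or the whole record, 50 % overlap).  Band powers are
trapezoid integrals over ULF (<0.003), VLF (0.003–0.04), LF (0.04–0.15) and
HF (0.15–0.4 Hz) on a grid augmented with the exact band edges, so the four
bands partition total power to machine precision.  LF/HF is computed last
and reported as NaN when HF power is zero.  A 5 s window cannot resolve any
of these bands (HF alone needs ≥ ~13 s), hence the per-segment estimation —
a deviation forced by physics, not a tuning choice.  Bands whose slowest
estimable frequency exceeds one cycle per record span (ULF and VLF on
2-minute segments) are still integrated but flagged `unresolved`.

*Nonlinear* (per 5 s window, on raw samples): Katz fractal dimension,
Renyi entropy, and Shannon / log-energy / norm wavelet entropies.  Katz
embeds the window as points `(i·dt, x_i)` with `dt` = the sampling interval
in seconds, so the time and mV axes have comparable scale (with `dt = 1`
sample the mV axis is negligible and D degenerates to 1).  The dimension is
`D = log10(n) / (log10(n) + log10(d/L))` with curve length L, diameter d
from the first point, and n = L/a for average step a; a straight line gives
exactly 1.  Renyi entropy uses a 100-bin equal-width amplitude histogram
and order α = 2 (the order is configurable; α → 1 recovers Shannon, which
the tests verify numerically).  Wavelet entropies pool the coefficients of
a level-5 Daubechies-4 decomposition with periodized boundaries (orthogonal,
energy-conserving) and evaluate, in nats with 0·log 0 := 0:
shannon = −Σ s²ln s², log-energy = Σ ln s² (zero coefficients skipped), and
norm = Σ|s|^1.1 (the common toolbox default exponent).  Higuchi fractal
dimension and sample/approximate entropies are out of scope.

## Statistics

For every feature and each of the six condition pairs, a two-sided Wilcoxon
rank-sum test on pooled window-level values — unpaired, because window
counts differ across conditions; a signed-rank switch on subject means is
available.  The exact null is enumerated when both samples have n ≤ 10 and
no cross-sample ties; otherwise the normal approximation with continuity
and tie correction is used, and the tests verify the exact path against
full enumeration.  Significance is starred strictly at p < 0.05 with no
multiple-testing correction by default (a Holm option exists), matching the
presentation style of uncorrected pairwise tables.

## Classification

Rows are split 70/30 with stratification, repeated 20 times with
deterministic per-run sub-seeds; all reported metrics are means over runs.
Features are z-scored with training-split statistics only — necessary for
an RBF kernel over mixed units (ms, ms², nats) — and a mutation test
verifies no test-set leakage into the scaler.  The SVM uses C = 1 and
`gamma = 1/(n_features · var)`, the conventional scaled default.

The ANFIS is a from-scratch first-order Sugeno system: rules are seeded by
Chiu's subtractive clustering (radius 0.5 in normalized coordinates, with
an option to force exactly six rules by taking the strongest centers),
premises are per-feature Gaussians with widths `radius·range/√8`, and
training alternates a least-squares solve for the consequents with a
normalized-gradient step on the premise parameters (step accepted only if
the RMSE does not increase; the learning rate adapts up 5 % on acceptance,
down 30 % on rejection, so the error trace is non-increasing).  The product
T-norm is used for rule firing — the standard differentiable choice for
hybrid learning — rather than the minimum.  Classification codes the
classes {0, 1} and thresholds the continuous center-of-gravity output at
0.5.  On the classic sinc benchmark (121 points, 300 epochs) the trainer
reaches RMSE < 1e-3.

Metrics per run: accuracy, sensitivity, specificity (percent),
LR+ = sens/(100−spec), LR− = (100−sens)/spec, error rate = 100 − accuracy.
When specificity is 100 % LR+ is unbounded and is rendered as the marker
`">100"`.  Splits are at window level by default (a subject's windows can
fall in both train and test, which inflates accuracy relative to
subject-level splitting); a subject-level split can be emulated by
aggregating the table before classification.

## Creativity scores and groups

Raw totals are z-transformed across subjects and the z-scores min-max
mapped onto [0, 100] (the affine reading of "normalize then 0–100"; it is
order-preserving and pins the extremes to 0 and 100).  Groups are strict:
high > 70, low < 30, otherwise excluded from group classification but kept
for condition classification.  If either group ends up with fewer than two
windows the group stage reports "insufficient groups" instead of running.

## Problem sizes and determinism

The default study simulates 20 subjects × 4 conditions × ~126 s at
1000 Hz — about 1 900 analysis windows — which gives stable Wilcoxon tables
and classifier means while keeping a full run in the order of a minute on
one core; inside `run_study` the ANFIS trains 30 epochs per pair (its
standalone default is 300).  A single master seed fans out to per-stage
sub-seeds, so identical configurations produce identical feature tables and
reports; every random draw in the package goes through a seeded generator.

## What passing tests show — and what they do not

The suite demonstrates that each implemented operator matches its defining
formula (against independently coded oracles), that the pipeline recovers
effects it injects (direction of HR/LF-HF shifts, group separability), and
that the metric arithmetic reproduces published operating points.  It does
not show that real creativity tasks produce these effect sizes: the
synthetic generator realizes the assumed structure by construction, window-
level splitting is optimistic, and real recordings add artifact classes
(motion, ectopy, electrode noise) the simulator deliberately omits.
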