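# Methods

## Problem and pipeline

The package estimates sleep stages (AASM five-stage: W, R, S1, S2, S3) and
sleep efficiency from a wrist device's 24 Hz record — tri-axial
acceleration, PPG green/IR counts, and a sparse RR channel carrying the
interval in ms at beat samples and zero elsewhere — with PSG epoch labels
as ground truth. Every quantity is computed per 30-s epoch, with epoch i
covering [i·30, (i+1)·30) seconds (half-open, so a beat at exactly t = 30 s
belongs to epoch 1).

## RR cleaning

Applied in fixed order: (1) drop zero samples of the sparse channel;
(2) exclude intervals ≤ 700 ms (inclusive) as outliers — the threshold is
deliberately aggressive (it removes all beats faster than ~86 bpm) and is a
configuration knob; no upper cutoff is applied; (3) fill interior excluded
positions by linear interpolation in beat index between the nearest
retained neighbours, flagged `interpolated`; leading/trailing exclusions
are dropped rather than extrapolated; (4) Malik ectopic deletion: interval
i is removed when it differs from the previous **accepted** interval by
more than 20% (the standard Malik criterion; comparing against the raw
predecessor would let one ectopic beat cascade), then refilled by the same
interpolation so the beat-time bookkeeping stays gap-free for spectral
analysis. One pass is applied; on realistic series the operator reaches a
fixed point within a few passes (asserted ≤ 5 in tests). A centered 10-beat
moving average is exposed for QC; edges are truncated, not padded.

## HRV features

All standard deviations are population (ddof = 0) — the convention is
stated because both appear in the literature and the difference is visible
at epoch length (n ≈ 30 beats). Time-domain, geometric and non-linear
features are computed on the epoch's own beats; an epoch with fewer than
10 beats is flagged and gets no features. Spectral features use a trailing
5-min window ending at the epoch's end (standard short-term HRV): the NN
series is linearly resampled to 4 Hz, mean-removed, and analysed with a
Welch periodogram (Hann, segments ≤ 256 samples, 50% overlap); band powers
are trapezoidal integrals over VLF (0.003–0.04 Hz), LF (0.04–0.15 Hz) and
HF (0.15–0.40 Hz). A band is reported missing (NaN), never zero, when the
window is shorter than two periods of its lower edge — hence VLF is always
missing at the default 5-min window (it needs ~11 min) and is excluded
from modelling automatically. The triangular index uses 7.8125 ms
(1/128 s) bins aligned at multiples of the bin width. Poincaré statistics
use SD1² = var(ΔNN)/2 and SD2² = 2·var(NN) − var(ΔNN)/2, which satisfy
SD1² + SD2² = 2·var(NN) exactly; CSI = SD2/SD1, CVI = log₁₀(16·SD1·SD2)
(the Toichi L·T form with L = 4·SD2, T = 4·SD1), modified CSI = L²/T.
The full set is 30 named variables.

## Activity counts

Per axis: linear-interpolation resampling from 24 Hz onto a 30 Hz grid
spanning the same time range (output length ⌊duration·30⌋); a 3rd-order
Butterworth band-pass 0.29–1.63 Hz (the published actigraph emulation's
pass-band; the exact legacy filter coefficients are not public in the
sources used here, and only the qualitative pass/stop behaviour matters
downstream — DC is blocked entirely, 10 Hz content is attenuated by far
more than 20 dB); then rectification, clipping at 2.13 g, 8-bit
quantization over [0, 2.13] g, a 0.068 g deadband applied to the quantized
magnitude, decimation to 10 Hz (every 3rd sample), and summation of the
quantized levels per epoch into integer counts. Two numerical choices:
the filter state is initialized to the DC steady state of the record's
first sample, so a record that begins mid-wear does not register its own
onset as movement (this also makes counts exactly zero for any constant
orientation of gravity); and the first 2 s of filtered output are excluded
from accumulation as a residual-transient guard. A vector magnitude
vm = round(√(cx² + cy² + cz²)) is emitted alongside the per-axis counts and
all four are offered to the model, since which of them the original
analysis used is not determinable.

## Models

The pooled epoch table (one row per subject × epoch; HRV features, counts,
per-epoch mean green/IR as raw summaries, stage label) feeds a random
forest with 500 trees, entropy criterion, √p features per split and a
fixed seed; feature importances are the entropy-based impurity
importances, which sum to 1. Four feature configurations — {HRV,
acceleration counts} × {with, without raw PPG summaries} — define the
model family; binary mode relabels W → 0 and any sleep stage → 1. The
default train/validation split is an 80/20 label-stratified random split
over epochs: epochs from all subjects are pooled as exchangeable rows,
which reproduces the intended evaluation design but is optimistic about
generalisation to unseen subjects because within-subject epochs are
strongly dependent. A whole-subject hold-out split is provided as the
methodologically stricter alternative. A deterministic comparison harness
covers extra trees, gradient boosting, decision tree, k-NN, LDA, logistic
regression and naive Bayes with the metric schema Accuracy / AUC
(one-vs-rest macro) / Recall / Prec. / F1 / Kappa / MCC; it replaces any
automated model search, which is out of scope.

## Evaluation

Confusion matrices use rows = true, columns = predicted, label order
[R, W, S1, S2, S3]. Accuracy = trace/total; per-class precision/recall use
the 0-convention for empty denominators; macro averages are unweighted;
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products (undefined,
NaN, when p_e = 1); MCC uses the multiclass covariance form (0 when a
marginal term degenerates). Sleep efficiency equates time-in-bed with the
scored record span, so SE is the sleep-epoch fraction × 100; consequently
SE + 100·(wake fraction) = 100 exactly. The SE-estimation accuracy formula
carries an absolute value on the difference — without it an overestimate
would score above 100%. The cohort report gives mean ± SD (population) of
both SE lists, the mean paired difference, the mean per-subject accuracy
and a paired two-sided t-test; a constant non-zero paired difference is
reported as t = ±∞, p = 0 rather than tripping the t-test's zero-variance
division.

## Synthetic cohorts

The generator encodes the structure the features rely on, not waveform
realism. Hypnograms are first-order Markov chains over the five stages at
30-s resolution; the default transition matrix gives dwell times of a few
minutes and was chosen as a convention (no published transition statistics
exist for the target cohort). Default record length is 8 h (960 epochs),
default cohort 30 subjects. Per stage, NN intervals are
Normal(mean_nn, sdnn) truncated at 300 ms with mean NN rising and SDNN
falling with depth (W: 780 ± 55 ms → S3: 1070 ± 16 ms), plus a per-beat
ectopic probability that produces >20% jumps for Malik cleaning to catch;
movement bursts are Poisson per epoch (W: 4/epoch → S3: 0.1/epoch), each a
0.5–2 s damped 1–3 Hz oscillation on a random axis over a constant 1 g
gravity on z plus 0.003 g sensor noise; PPG baselines are stage-dependent
(wake clearly elevated, sleep stages within ~120 counts of each other)
under a slow shared AR(1) drift whose stationary SD (~130 counts) is
comparable to the between-sleep-stage gaps, plus white sample noise. The
drift terms (PPG, and a 9 ms/epoch AR(1) on the NN baseline) exist so that
raw PPG summaries separate wake from sleep but not sleep stages from each
other, and so stage means are informative but not trivially separable —
giving the qualitative model ranking HRV-based ≥ acceleration-based that
the pipeline is expected to reproduce. What passing tests on this cohort
shows is that the pipeline recovers stage structure of exactly this kind;
it says nothing about PPG waveform morphology, respiratory or apnea
effects, device artifacts, or between-subject physiological heterogeneity,
none of which are modelled.

## Problem sizes

Unit tests run on cohorts of ≤ 6 subjects × ≤ 240 epochs. The
parameter-recovery check and the acceptance script use 10 subjects ×
960 epochs (9,600 epochs, ~27 M accelerometer samples), which the package
processes end to end in about a minute on one CPU — large enough for
stable validation κ estimates while staying convenient to re-run.

## Known limitations

The 700 ms cutoff biases wake epochs' NN statistics upward (fast beats are
excluded and interpolated); the epoch-stratified split inflates validation
κ relative to subject hold-out; the Butterworth band-pass matches the
legacy actigraph filter's pass/stop behaviour, not its exact coefficients,
so absolute count magnitudes are not comparable across implementations;
and binary-mode SE estimation inherits whatever wake/sleep confusion the
classifier has, so its accuracy on real data will be lower than on the
well-separated synthetic default profile.
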