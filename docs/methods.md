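# Methods

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions that were genuinely open.

## Silent-synapse estimation from minimal stimulation

**Model.** A stimulated afferent contacts the recorded neuron through N
synapses (default 5, the typical single-axon contact number for
cortical pyramidal neurons); a fraction s of them are AMPA-silent
(NMDA receptors only). Each synapse releases a vesicle independently
per stimulus with probability p. At −60 mV only the Nₐ = N − round(N·s)
AMPA-functional synapses produce current, so the failure probability is
F₋₆₀ = (1−p)^Nₐ; at +40 mV the Mg²⁺ block of NMDA receptors is relieved
and all N synapses respond, giving F₊₄₀ = (1−p)^N. The estimator
s = 1 − ln(F₋₆₀)/ln(F₊₄₀) eliminates p exactly. The generator stores
round(N·s) as its ground truth, so recovery studies compare estimates
against the silent fraction that is actually representable at integer
synapse counts.

**Assumptions.** Silent and active synapses share one NMDA quantal
amplitude (equal detectability at +40 mV), release is independent and
stationary across trials, and no synapse lacks NMDA receptors. Sampling
noise in the two failure rates propagates through the log ratio, so
per-cell estimates can fall below 0 or above 1; they are reported
unclipped and enter cohort means unclipped, and cells whose sampled
failure rate is exactly 0 or 1 carry no estimator value (they keep
potency and success-rate summaries and are flagged, not dropped
silently). Note the estimator is strictly increasing in F₋₆₀ at fixed
F₊₄₀ — more AMPA failures mean more silent synapses.

**Quantal amplitudes** are gamma distributed (mean / CV
parameterization; default 10 pA, CV 0.3). The gamma was chosen for its
positive support and its additivity (a k-quantum trial is a single
gamma draw), not from a fitted empirical distribution.

**Success/failure classification.** Trials are scored automatically as
a surrogate for by-eye scoring at the rig: a trial is a success when
the response peak within a holding-potential-specific window (1–20 ms
post-stimulus at −60 mV for the fast AMPA component; 5–60 ms at +40 mV
for the slow composite response) exceeds k·RMS of the pre-stimulus
baseline, k = 3 by default. The peak is searched on a 2 ms boxcar-smoothed
trace while the RMS is quoted on the raw baseline. This asymmetry is
deliberate: the maximum over a response window of smoothed noise alone
exceeds 3 smoothed-noise SDs with double-digit probability, whereas
3 raw-noise SDs sit far above that ceiling and still an order of
magnitude below a quantal response at realistic noise levels
(classification matches generator ground truth at > 99% for noise SD
≤ ~1 pA against 10 pA quanta). With peak-only tables (no traces) the
tabulated magnitude is compared against k times the tabulated baseline
RMS directly. Both windows and k are configurable.

**QC.** Cells are retained only with series resistance strictly below
30 MΩ and series/input resistance drift strictly below 20%; exclusions
are logged with the violated rule.

**NMDA potency** averages all +40 mV success traces and all failure
traces and reports the success-average peak minus the failure average
at the same sample, cancelling stimulus artefacts common to both. The
AMPA/NMDA ratio divides the −60 mV peak by the +40 mV amplitude 50 ms
after that trace's own peak, where the fast component has decayed;
denominators below a caller-supplied noise floor raise an explicit
"unreliable" signal.

## Event analyses

**Detection** is a two-stage threshold-crossing surrogate (the original
workflow's detector is not specified): the polarity-corrected,
median-subtracted signal is smoothed heavily (5 ms) for detection and
lightly (1 ms) for amplitude measurement; peaks must exceed 3.5× a
robust (MAD) noise estimate in both height and prominence and be
separated by a 5 ms refractory period (closer candidates merge to the
larger peak). The prominence requirement removes noise ripples riding
on decay tails; the two smoothing scales decouple detection reliability
from amplitude fidelity. At SNR 5 this yields sensitivity and precision
above 0.95 against generator ground truth. All four constants are
parameters.

**Cumulative distributions.** Per cell, exactly the first 400 events in
recording order are used (determinism; cells with fewer are excluded
and logged), the chosen variable is sorted and averaged within 20 rank
bins (20 events each for amplitudes), and bins are averaged across
cells. Rank (quantile) bins rather than equal-width bins follow from
the sort-then-bin procedure; equal-width binning is available as an
option. For inter-event intervals 400 events yield 399 intervals, which
are split as evenly as possible; exact 20-per-bin equality (and the
bin-mean/grand-mean conservation identity) holds for the amplitude
case.

**Paired-pulse ratio.** The decay of the first response between its
peak and the second stimulus is fitted with a double exponential and
extrapolated beneath the second response; the second amplitude is the
peak of the residual. Tail fitting rather than paired-average blank
subtraction keeps the measure applicable to single traces; recovery on
noiseless synthetic pairs is within 1% at 50–200 ms intervals, and the
ratio is invariant to uniform gain.

**MK-801 decay.** Open-channel block means a synapse's NMDA response is
lost the first time it releases, so the expected peak at sweep k scales
as (1−p)^(k−1). Series are normalized to sweep 1, averaged, and fitted
with a·r^(k−1) by least squares. The free amplitude a matters: dividing
by a stochastic first sweep inflates the curve by roughly
1 + CV²(first sweep) uniformly, and a pure r^(k−1) fit absorbs that
into r (≈ 0.715 instead of 0.700 at p = 0.3, 100 synapses); with a
free, the fitted survival recovers 1−p within ±0.03 at 100 cells /
50 sweeps. Flat series (survival > 0.995) are flagged degenerate rather
than interpreted, covering the p = 0 case where nothing releases and
nothing decays. This assay is simulated with many synapses (default
100), reflecting the stronger, non-minimal stimulation used for it.

**Sr²⁺ quantal analysis** applies the same rank-binning machinery to
evoked asynchronous events restricted to the post-stimulus window
(default 400 ms) and reports mean quantal amplitude and within-window
inter-event intervals. The generator draws latencies uniformly in the
window; real asynchronous release decays over the window, which only
matters for IEI summaries, not amplitudes.

## Fourier maps and ocular dominance

Per pixel, the (optionally linearly detrended — slow hemodynamic-like
drift would otherwise leak into the projection) time series is
projected onto cos/sin at the stimulus frequency; amplitude is 2/T
times the modulus (a pure cosine of amplitude A returns A), phase is
wrapped to [0, 2π) and reported in radians (conversion to visual-field
degrees requires stimulus geometry and is out of scope). 30 Hz
acquisitions are temporally binned to 7.5 Hz by non-overlapping 4-frame
means with trailing remainders dropped and logged.

The OD score per responsive pixel is (C−I)/(C+I); the ODI is the mean
score over the responsive mask, spanning −1 (ipsilateral) to +1
(contralateral). The default responsive rule — amplitude above 30% of
the 99th percentile of the contra map in either eye — is scale free and
robust to hot pixels, but is referenced to the contra map; a symmetric
variant referenced to the pixelwise max of both maps ("either-p99") is
provided and is the right choice when exact eye-swap antisymmetry is
required. Pixels with C+I = 0 are removed from the mask. Animal ODIs
are means of block ODIs (consecutive blocks of 4 runs); animals with
fewer than 3 block ODIs are excluded — an outcome, not an error.

**Map scatter** is a stated surrogate for the map-quality metric of the
underlying imaging literature (whose exact formula is not public): the
mean absolute circular difference between each masked pixel's phase and
the circular mean direction of its 5×5 neighbourhood (centre excluded).
A locally planar retinotopic ramp scores ≈ 0; i.i.d. uniform phases
score ≈ π/2.

The movie generator renders A·cos(2πft − φ) per pixel plus Gaussian
frame noise; an optional pink (1/f) temporal component is off by
default since the analyzer uses only the stimulus-frequency component.
Hemodynamic filtering, vessel artefacts and cross-session registration
are not modelled, so recovery tests validate the extraction arithmetic,
not robustness to those real-data features.

## Puncta and blots

Segmentation thresholds by intensity (Otsu by default, as a surrogate
for interactive thresholding; absolute thresholds available), labels
connected components, and discards objects below 200 px² (≈ 7,200 nm²
at the 6 nm pixels of the semi-thin-section protocol; 0.5 µm section
thickness). An optional watershed split on the distance transform
replaces the original manual separation of fused puncta. Colocalization
matches puncta whose mask intersection exceeds 5% of the smaller
punctum's area — the denominator is not specified upstream, and the
smaller-area convention makes the rule symmetric (alternatives are
configurable); each punctum matches at most one partner, greedily by
overlap fraction with ties broken by label order. Synapse density is
matched-pair count / (image area × section thickness). Border-touching
puncta are retained. Blot intensities are divided by the mean
control-group intensity for the same protein on the same blot, making
values comparable across blots with different detection gains; rows on
blots lacking a control are flagged and returned, never silently
dropped.

The puncta generator places disk puncta on a jittered coarse grid so
distinct plan entries never touch, and realises a requested pairwise
overlap fraction by solving the equal-disk circle-intersection equation
for the centre offset. Real puncta are neither disk-shaped nor
isolated; the generator validates the counting/overlap arithmetic, not
the segmentation of crowded tissue.

## Visual water task

The observer is a stationary Bernoulli process on a logistic
psychometric function bounded by the two-alternative guess rate (0.5)
and 1 − lapse; difficulty increases with spatial frequency (acuity) or
with decreasing angular difference (orientation). Thresholds are read
from pooled per-level accuracy: the highest frequency, or smallest
angle, with accuracy ≥ 0.70 (inclusive); the learning criterion is the
first training block at ≥ 0.90. Thresholds are therefore always members
of the tested level set: 0.086 cycles/degree then 0.05 c/d steps for
acuity, 90° down in 5° steps for orientation. Non-monotone
pass/fail/pass sequences are logged and resolved by the extreme passing
level, per the threshold definitions.

The default session tests each level with 3 blocks of 10 trials,
pooled. Block size for threshold testing is not specified upstream;
30 trials per level emulates the repeated testing an animal receives at
each difficulty step and keeps the probability that chance performance
(0.5) passes the 70% criterion at ≈ 2% per level, which a single
10-trial block (≈ 17%) would not. Testing stops at the first failing
level, as on the rig.

## Determinism and problem sizes

All generators accept explicit seeds or generators; the pipeline
derives one independent stream per stage from a master seed via a
name-keyed `SeedSequence`, so stages rerun independently and full runs
are byte-identical. Default problem sizes are desk scale — 30-cell
minimal-stimulation cohorts at 50 trials per potential, 64×64 movies of
600 frames (10 stimulus cycles), 120 s mEPSC recordings, 1688² puncta
images — chosen so a full pipeline completes in seconds while keeping
Monte-Carlo error comfortably inside the recovery tolerances used in
the tests (e.g. cohort silent-fraction recovery within ±0.02 at 300
cells × 200 trials).

## Known limitations

- The estimator's exactness requires equal release probability across
  synapses and equal NMDA detectability of silent and active synapses;
  violations bias s in ways the generator does not currently model.
- The mEPSC detector is threshold-based; heavily overlapping events at
  high rates merge (no deconvolution), and amplitudes measured at local
  maxima carry a small positive noise bias.
- Imaging analysis assumes co-registered maps and models no vascular or
  movement artefacts.
- Group-level inferential statistics (ANOVA, survival comparisons) are
  deliberately left to standard libraries; this package produces the
  per-cell / per-animal quantities they consume.
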