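# Methods

This note documents the models, parameter choices and numerical decisions
behind `megbody`, and what the synthetic validation does and does not
establish about real data.

## Forward model

The head is a homogeneous spherical conductor. The magnetic field of a
current dipole **q** (A·m) at **r₀** observed at an external point **r**
is the Sarvas closed form

    F   = a (r a + r² − r₀·r),          a = |r − r₀|, r = |r|
    ∇F  = (a²/r + a·r/a + 2a + 2r) r − (a + 2r + a·r/a) r₀
    B   = μ₀ / (4πF²) [ F (q × r₀) − ((q × r₀)·r) ∇F ]

Sensors are radial magnetometers on a helmet shell 2 cm outside the
scalp; the lead field collects `B·n̂` for a unit dipole along each source
orientation. Two consequences are exact and are used as physics tests:
a dipole parallel to its position vector produces no external field, and
the radial field component outside the sphere equals the Biot–Savart
field of the bare primary dipole (volume currents contribute nothing
radially), which provides an independent numerical oracle.

Sources sit on a shell at 0.85 of the head radius. Their orientations
are deterministic *tangential* unit vectors rather than shell normals: a
radial dipole is magnetically silent in a spherical conductor, and the
tangential component is the part of an oblique cortical normal that MEG
sees. Choosing tangential orientations keeps every simulated source
visible and makes inverse recovery testable.

## Synthetic experiment

The stimulus design is fixed: 14 images (4 feet, 4 hands, 4 mouths, 2
objects), 40 repetitions each by default, uniformly shuffled order.
Each body-part trial activates

* a **shared** vertex set (default 12 vertices) in the
  occipitotemporal body patch — the category-independent body-sensitive
  response;
* a **category-unique** set (default 6 vertices per category, disjoint
  across categories) in the same patch, scaled by `category_effect`
  (0 removes all category information) — with the default half/half
  amplitude split the response is ~50% shared, ~50% unique;
* object trials activate an early-visual patch instead.

The temporal kernel is a unimodal pulse (sin² rise from 120 ms to the
190-ms peak, cos² fall to 300 ms; zero outside), so evoked peaks land in
the empirically expected 140–240 ms window. The mouth category's unique
response is boosted ×1.3, making contrasts that include mouth the most
F-variant — the qualitative asymmetry body-category studies report. A
side effect is that peak *amplitudes* can differ detectably across
categories in large synthetic cohorts even when latencies do not; real
studies reported null results for both, so the amplitude ANOVA should be
read as a property of this generator, not a target.

Noise has three parts: white sensor noise (default SD 100 fT per raw
sample, the ballpark of a magnetometer's in-band noise integrated over a
500-Hz bandwidth), 30 background dipoles per trial at random vertices
with 1/f-shaped spectra (3 nA·m SD), and a per-subject multiplicative
channel gain jitter (SD 5%) standing in for helmet/head alignment
differences. A fixed per-image gain factor (SD 10%) gives each image an
identity signature without category structure — this is exactly what the
random-class decoding null can exploit, so random-class accuracy sits
slightly above chance, as it should.

Calibration of the source strength was the one genuinely free constant
(no single-trial SNR is published for this paradigm). The default
0.8 nA·m per template vertex was chosen so that a study-scale subject
(160 channels, 40 repetitions) shows a ≈100 fT evoked peak at the best
channel and a peak categorical decoding accuracy near 50% — above chance
and below ceiling. Scaled-down test configurations use 2.0 nA·m to keep
the effect detectable with 4× fewer repetitions and ~5× fewer retained
channels.

One head model (geometry, lead field, template) is shared by all
subjects of a cohort, as in analyses on a spatially normalized brain;
between-subject variability enters through gain jitter, per-image gains,
trial order and noise draws. This is what makes vertex-wise F-map
averaging across subjects meaningful.

## Preprocessing

Order: notch (IIR, Q=30) → band-pass → baseline → frontal-channel
exclusion (geometric tag, anterior quarter of the helmet) → peak-to-peak
rejection (3 pT default; generous for clean synthetic data, it exists to
catch constructed artifacts). Filters run per trial and channel on
reflection-padded (200 ms) epochs.

Phase handling is deliberate. A zero-phase (forward–backward) 1 Hz
high-pass redistributes part of a monophasic evoked deflection *backwards*
in time: the filter output must integrate to ~zero and filtfilt splits
the compensating lobe symmetrically around the pulse, which measurably
smears category information into the pre-stimulus baseline (~20–25% of
the peak with a 4th-order design). The default `phase="hybrid"` therefore
applies the high-pass causally as a first-order DC blocker (passband
group delay ≲2 ms, peak latency shift ~5 ms) while the 30 Hz low-pass
and the notch — the stages that dominate waveform timing — remain
zero-phase. `phase="zero"` (everything forward–backward, exactly zero
lag) and `phase="causal"` are available; the temporal-specificity
property (pre-stimulus windows decode at chance) holds under the hybrid
default and necessarily fails under `phase="zero"` for pulses with
nonzero area.

## Evoked peaks

"Maximum negative component" is the most negative signed value (not the
largest magnitude) across retained channels within 140–240 ms, ties
broken by earliest time then lowest channel index. The peak channel is
chosen once per subject from the grand average over body categories and
held fixed across categories, so the cross-category ANOVA compares like
with like; a flag switches to per-category channels. Under a
null generator (equal category amplitudes), the peak ANOVA's rejection
rate stays at its nominal level — verified over 100 simulated cohorts.

## Inverse and F-maps

The inverse is L2 minimum-norm: `W = Gᵀ(GGᵀ + λ_eff C)⁻¹` with the
shrunk (10% toward diagonal) baseline covariance `C`. The user-level `λ`
is dimensionless: it is scaled by `tr(GGᵀ)/tr(C)` so `λ=1` balances the
two terms, and, when training data are supplied, additionally by the
ratio of baseline power to signal power in the 140–240 ms training
window — a discrepancy-principle flavour that lets one `λ` (default 0.1)
work across SNR regimes. `λ→0` reduces to the pseudo-inverse, `λ→∞`
shrinks estimates to zero; both limits are tested.

Currents are averaged in consecutive non-overlapping 20-ms windows
(half-open `[start, start+20)`, labelled by centre). F-maps are one-way
ANOVAs across trial groups on *signed* window-averaged currents (a flag
switches to magnitudes) at the 180–200 ms window by default, and are
averaged vertex-wise across subjects before interpretation — top-decile
vertices of the averaged 3-category map overlap the simulated
category-unique set (Jaccard ≈ 0.36 at scaled size; per-seed values
scatter around 0.33 under inverse blur, which is why the aggregate map,
not each seed, carries the claim).

## Decoding

Features are 20-ms window means per retained channel (59 windows over
−100…500 ms at the default grid), z-scored per window with training-fold
statistics only. The classifier is a one-vs-rest linear SVM — per-class
weight vector plus bias, argmax decision — via scikit-learn's `LinearSVC`
in the primal squared-hinge formulation (penalty C=1): the dual hinge
solver fails to converge on information-free windows, and the primal
problem is deterministic and ~10× faster with an identical decision rule
on separable data. Folds are stratified 10-fold with a fixed seed; trials
of the same image can appear in train and test folds, which mirrors the
within-image generalization the original design implies (decoders are
asked about categories, not left-out images). Object trials are excluded;
random-class accuracy is averaged over independent seeded partitions
(20 by default, fewer in scaled tests), each partition constrained so no
class is category-pure.

Significance: per window, correct counts pooled over subjects (and
partitions) feed a two-sided exact binomial test against 1/3;
categorical-vs-random is a two-sided paired t-test on per-subject
accuracies; CIs are t-based across subjects.

## What the validation shows — and does not

The Monte-Carlo suite establishes that the pipeline is *calibrated* (with
the category effect off, decoding averages to 33.3% within Monte-Carlo
error — the pipeline manufactures no category information), *sensitive*
(with the default effect, categorical decoding beats the random-class
null in 20/20 simulated cohorts with paired p ≪ 0.01 at the response
peak), *temporally specific* (pre-stimulus windows decode at chance), and
*spatially meaningful* (F-maps localize the simulated category-unique
sources through inverse blur). It does not establish anything about real
MEG data: the simulator omits eye/cardiac artifacts, correlated sensor
noise, cortical folding (and hence realistic lead-field structure),
inter-subject anatomical variability, and attention or adaptation
effects. Passing here means the analysis logic is sound, not that a real
experiment would reach the same accuracies.

## Scaled problem sizes

Tests and the acceptance script use reduced sizes chosen once: null
calibration uses 8-channel/16-vertex subjects with 10 repetitions at
250 Hz (50 seeds); cohort separation uses 9-subject cohorts with a
32-channel helmet, 200 vertices, 10 repetitions, 3 random partitions and
a 0–300 ms decoding range (20 cohorts); parameter recovery uses the same
geometry (20 seeds). The trial *structure* — 14 images, 4/4/4/2 category
split, balanced repetitions, 10-fold stratified CV — is never scaled.
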