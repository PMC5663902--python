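# Methods

`modparc` re-implements, as a tested and reusable pipeline, a
graph-theoretic parcellation of a small brain region of interest (ROI)
from resting-state fMRI: signed-weighted Louvain community detection with
an iterated maximum-Q restart protocol and border fine-tuning, followed by
seed-based partial-correlation connectivity mapping, test-retest and group
statistics, and a block-design task GLM whose ROI activation is related to
connectivity strength.  Because the real acquisitions such an analysis
targets (hundreds of multi-run whole-brain sessions) cannot ship with a
software package, every stage is exercised on synthetic phantoms with
known ground truth; this note records the model, the defaults, and what
the phantom does and does not emulate.

## Signed modularity and its optimization

The parcellation operates on the fully connected, undirected, signed
weighted graph `M` whose nodes are ROI voxels and whose edge weights are
Pearson correlations averaged (as raw r) across subjects and runs, with
the diagonal removed.  The objective is the asymmetric signed modularity

    Q* = (1/v+) Σ_ij (w+_ij − s+_i s+_j / v+) δ(c_i, c_j)
       − (1/(v+ + v−)) Σ_ij (w−_ij − s−_i s−_j / v−) δ(c_i, c_j)

with `w± = max(±w, 0)` the positive/negative layers, `s±` their node
strengths and `v±` their totals.  Positive within-community weight is
rewarded at full scale while negative within-community weight is penalized
with the reduced prefactor `1/(v+ + v−)`; when `v− = 0` the expression is
exactly Newman–Girvan weighted modularity (verified against networkx to
1e−10 in the tests).

Internally every optimization phase operates on the generalized
modularity matrix `B = B+/v+ − B−/(v+ + v−)`, for which
`Q* = Σ_ij B_ij δ(c_i, c_j)`.  `B` aggregates linearly
(`B_agg = Hᵀ B H`), so the Louvain local-moving and aggregation phases,
the protocol, and the fine-tuning stage all see one consistent objective;
aggregated graphs additionally carry their positive and negative layers
explicitly so that Q* is exactly invariant under aggregation even when
mixed-sign inter-community sums would cancel in the net weights.

Numerical choices:

* **Candidate moves.** The graph is fully connected, so "neighboring
  communities" means all currently non-empty communities; gains are read
  from a community-strength table `S[i, c] = Σ_{j∈c} B_ij` that is updated
  in O(n) per accepted move.
* **Tie-breaking.** A node stays in its community on ties; among other
  tied communities the lowest index wins.  Moves must improve Q* by more
  than 1e−12, which both enforces strict ascent and guarantees
  termination in floating point.
* **Restart protocol.** Louvain is stochastic, so it is restarted in
  blocks of 100 independent runs.  Each block's maximum Q is rounded to 4
  decimals (half-even); the partition with the strictly higher rounded Q
  is kept across blocks and the protocol stops when two consecutive
  blocks agree on the rounded maximum.  A hard cap of 50 blocks aborts
  with a diagnostic; in practice two to three blocks suffice.  The
  module count is expected to be constant across registered maxima and a
  warning is recorded in the protocol trace if it is not.
* **Fine-tuning.** Starting from the winning affiliation vector, nodes
  are re-offered (in seeded random order) to existing communities only,
  under the same blocked rounded-max stopping rule; the refined Q is never
  below the input Q and no new communities can appear.
* **Hierarchy.** Only the top level of the Louvain hierarchy is reported;
  sub-module exploration exists behind a flag but is off by default
  because lower levels of small ROI graphs typically dissolve into single
  voxels.
* **RNG.** One master seed; each run in a block draws an independent
  child stream (`numpy` SeedSequence spawning), all recorded in the
  protocol trace, making every partition bit-reproducible.

On graphs small enough for exhaustive enumeration (n ≤ 9, all set
partitions), the protocol attains the global optimum in ≥ 95% of random
signed instances and never exceeds it — this, rather than any fixed Q
value, is the correctness surface for the optimizer.

## Preprocessing

Per run, in fixed order: drop 4 initial volumes (signal equilibrium);
zero-phase second-order Butterworth band-pass 0.01–0.10 Hz (mean
removed); multiple regression on intercept, 6 realignment parameters, and
the first 3 principal components each of the white-matter and CSF voxel
signals (separate PCAs; collinear columns dropped with a warning); spatial
Gaussian smoothing, FWHM 4 mm, reflect boundary (conserves the local mean
on small grids); censoring of frames with FD > 0.5 mm *or* DVARS > 0.5%
(strict inequalities).  FD is the Power convention — sum of absolute
backward differences with rotations converted on a 50 mm sphere — and
DVARS is the RMS frame-to-frame change as a percent of the whole-mask
temporal mean signal.  Both are computed on the unfiltered post-drop
data, since censoring targets raw motion artifacts.  Runs with more than
30% (rest) or 20% (task) of frames censored discard the subject.
Censored frames are excluded from every downstream statistic and each
correlation's degrees of freedom are decremented accordingly.

## Connectivity mapping and group statistics

Each parcellation module is a seed; its mean retained-frame signal is
correlated with every brain voxel after regressing the mean signals of
the *other* modules out of both sides (textbook partial correlation; with
no covariates this is numerically identical to plain Pearson
correlation).  Maps are Fisher r-to-z transformed and then averaged
across runs (transform-then-average, asserted by test); the effective
degrees of freedom (retained frames − covariates − 2) accumulate across
runs.  For test-retest analyses the retained frames are split into four
contiguous equal subseries ("sessions"), splitting after censoring.

Group inference: voxelwise one-sample t (df = n−1); seed contrasts as
within-subject differences (one-vs-rest or pairwise) followed by a
one-sample t; a balanced two-way repeated-measures ANOVA
(session × seed, subject as random blocking factor, each effect tested
against its own subject-interaction mean square — the classic balanced
decomposition, cross-checked against statsmodels' AnovaRM); and ICC(3,1)
reliability, `(BMS − EMS) / (BMS + (k−1) EMS)` (cross-checked against
pingouin's consistency single-measures ICC).  A linear mixed-effects
implementation was deliberately not used: the phantom designs are
complete and balanced, where the classic F-tests coincide under compound
symmetry; divergence is possible under sphericity violations, which this
package does not model.

Multiple comparisons use Monte-Carlo cluster-extent correction: white
Gaussian noise fields over the analysis mask, smoothed to an assumed
(conservative, fixed) 10 mm FWHM, standardized, thresholded two-sided at
a voxelwise p (default 0.001, configurable — corrected levels of 0.05 and
0.01 are both supported), clusters formed under 6-face adjacency
(configurable to 18/26), and the maximum cluster size recorded per
iteration.  The minimum surviving size is the ceiling of the (1−α)
quantile of the null maxima plus a one-voxel safeguard, so an observed
cluster survives only when strictly larger than the null quantile.
Smoothness is not estimated from residuals by default (a residual-based
mode exists) because the phantom's smoothness is known.

## Task analysis

A two-condition (face/shape) block design modeled with a canonical
double-gamma HRF (response peak 6 s, undershoot 16 s, ratio 1/6, unit
peak).  The default design has 6 alternating blocks (3 face, 3 shape),
each a 3 s cue followed by six 2 s trials with 1 s inter-trial intervals,
in a 176-frame run at TR 0.72 s; the trailing fixation is not modeled.
Runs are scaled voxelwise to 100·signal/mean so betas are percent signal
change; frames whose 6-parameter motion derivative has Euclidean norm
(rotations at 50 mm) above 0.3 mm are censored; the two runs are combined
in a fixed-effects OLS with run-specific intercept and drift columns and
the reported contrast is β_face − β_shape.

The activation–connectivity link: per subject, the FC map summary is the
mean of Fisher-z values that are positive *and* individually significant
at p < 0.05 under the subject-level r-to-t test at the map's own df
(subject-level rather than group-level significance; an alternative mode
exists).  This scalar is Pearson-correlated with the subject's ROI mean
beta across subjects.  Subjects with no qualifying voxels contribute 0
and are flagged; constant inputs yield r = 0 with a degenerate flag.

## The synthetic phantom

The phantom emulates the statistical structure the pipeline consumes,
not MR physics.  On a 24×24×18 grid of 2 mm voxels (configurable), K = 3
planted communities of 60/70/70 voxels form the ROI; each community
shares a band-limited (0.01–0.10 Hz) unit-variance latent signal, and
voxels follow the factor model

    x_v = sqrt(ρ_w)·g_k + sqrt(1 − ρ_w)·σ·ε_v + drift + nuisance-leak

with ρ_w = 0.6 within-community and latent equicorrelation
ρ_g = ρ_b/ρ_w chosen so the between-community correlation is ρ_b = 0.1
(the implied K×K latent correlation must be positive definite or the spec
is rejected).  At σ = 1 the pairwise within-correlation is ρ_w up to a
small dilution from the drift (sd 0.2) and nuisance-leak (sd 0.15,
random ± sign per voxel so pairwise targets are unbiased) terms — about
0.565 empirically, within the 0.05 calibration band.  Latents are kept
inside the analysis passband deliberately, so that band-pass filtering
preserves the planted structure and preprocessing + detection are jointly
testable.  Correlation targets are achieved by this factor construction
rather than a Cholesky factor of the full voxel covariance, which keeps
generation O(voxels × frames) and analytically calibrated.

Three 48-voxel target regions outside the ROI each carry one community's
latent at effect correlation 0.3; white-matter and CSF blocks carry three
shared nuisance latents each (mixed per voxel), which also leak into
grey-matter voxels; all brain voxels sit on a baseline of 1000 signal
units (so percent-scaled quantities like DVARS are well defined).  Motion
traces are smooth low-amplitude baselines (FD ≪ 0.5 mm) plus single-frame
1 mm x-translation spikes with alternating sign at Bernoulli(0.02)
frames; spike frames are recorded as ground truth.  Task runs modulate
ROI voxels as baseline·(1 + β·x(t)/100) with the demeaned unit-peak
HRF-convolved face regressor, module amplitudes {0.2, 0.5, 0.8}% and
white noise at 0.5% of baseline.  An optional per-subject coupling
factor ~ max(0.1, N(1, sd)) scales both the seed circuitry's connectivity
strength (community coherence and target correlation) and the task
amplitude, planting the across-subject activation–connectivity
association; its default is 0 (subjects exchangeable).

Everything planted — labels, target signs and effects, true betas, spike
frames — is recorded in a `GroundTruth` object, enabling exact recovery
scoring (adjusted Rand index, target detection, beta RMSE).

What the phantom does *not* emulate: scanner drift beyond slow
polynomials, physiological (cardiac/respiratory) waveforms, spatial
autocorrelation of the noise floor (voxel noise is white in space, so
passing tests say nothing about smoothness-estimation accuracy on real
data), registration/distortion artifacts, or anatomical variability of
the ROI across subjects.  Consequently, green tests demonstrate
correctness of the estimators and error control under the stated model,
not robustness to the full artifact spectrum of real acquisitions.

## Problem sizes and defaults

Desk-scale defaults were chosen so the complete test-bed runs in minutes
on one CPU: 30 subjects × 2 runs × 304 frames (300 analysed) for
partition-recovery studies, graph-level studies via an ROI-only fast path
that skips whole-brain volume assembly, 12 subjects for the FC-map
specificity study, 40-subject smoothed-noise families (200 repetitions)
for the family-wise-error check with a 1000-iteration cluster null, and
30 subjects for the activation–connectivity coupling study.  The demo
pipeline (`modparc run-all`) uses 6 subjects.  All sizes are parameters;
nothing in the code depends on them.

## Known limitations

* Raw-r averaging of correlation matrices (the default, matching the
  method being reproduced) slightly biases the group matrix toward zero
  relative to Fisher-z averaging; a z-averaging mode exists.
* The restart protocol keeps the higher rounded Q when consecutive block
  maxima differ (monotone ascent).  A literal "keep the latest block"
  reading could retain a lower-Q partition; the monotone interpretation
  is implemented and the trace records every block's maximum so the
  alternative can be audited.
* The cluster null assumes fixed 10 mm smoothness rather than estimating
  it; on data whose true smoothness differs, FWE is mis-calibrated (the
  FWE acceptance check generates data at the assumed smoothness).
* ICC on phantoms with exchangeable subjects is near zero by
  construction (no true between-subject variance); reliability studies
  require the subject coupling factor or real data.
* `qc_subject` discards subjects, it does not impute; heavily censored
  datasets therefore shrink n.
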