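# Methods

## Overview

`roamind` analyzes longitudinal locomotion of individually housed *C.
elegans* across development. The pipeline has two halves:

1. **Trajectory processing** — from a frame-level centroid trajectory
   (3 frames/s by default) to a stage-segmented, age-normalized profile of
   roaming behavior.
2. **Individuality analysis** — from a cohort's roaming profiles to
   "individuality dimensions": temporal patterns of consistent deviation
   from the population, extracted by a rank/bias transform and weighted
   PCA, with shuffle-null significance testing and permutation tests on
   inter-individual variance.

A synthetic-data generator provides cohorts and trajectories with known
ground truth, so every stage of the pipeline is testable without any
recordings.

## Trajectory processing

**Rolling kinematics.** Instantaneous speed is the frame-to-frame centroid
displacement times the frame rate (µm/s); heading is the direction of the
displacement vector, and angular velocity the absolute heading change per
frame interval, wrapped to ≤ 180°, times the frame rate (deg/s). Both are
averaged over a centered rolling window of `round(10 s × fps)` frames
(30 frames at 3 fps). Edge frames use truncated windows and are flagged.
Frames with zero displacement carry the previous heading, so a stationary
animal has angular velocity 0. Sampling must be uniform at 1/fps; gaps
raise an error listing the offending frames rather than being filled.

**Stage segmentation.** Worms stop moving during lethargus (the molt
between stages). The rolling speed is further smoothed over 300 frames;
spans below the 5th percentile of the individual's own smoothed-speed
distribution lasting at least `min_quiescence_min` (default 20 min,
scaled down for short synthetic recordings) are candidate lethargus
periods. The four longest are taken as the molts, and the midpoint frame
of each is a stage boundary, giving L1 | L2 | L3 | L4 | Adult. Recordings
with fewer than four qualifying spans raise a segmentation error (the
individual is excluded). The quantile and minimum duration are defaults of
this implementation, exposed in configuration; only the 300-frame
smoothing is fixed by the source analysis.

**Roaming/dwelling classification.** Roaming (fast, straight runs) and
dwelling (slow movement with frequent reorientation) are separated by a
diagonal through the joint distribution of 10 s speed and angular
velocity, discretized on a 50 × 50 histogram with bin widths 7.59 µm/s and
3.6 deg/s. Because the diagonal is linear, the per-bin rule reduces to a
per-frame inequality: a frame in stage *s* is roaming iff

    speed / 7.59  >  slope_s × (angular_velocity / 3.6)

with stage slopes (5, 2.5, 2.3, 2, 1.5) for (L1, L2, L3, L4, Adult) — a
larger slope is a stricter roaming criterion. Two conventions had to be
fixed here: frames exactly on the diagonal are dwelling, and frames whose
speed falls in the lowest histogram bin (< 7.59 µm/s) are dwelling.
Angular velocity is computed from displacement headings, not body
orientation. Lethargus frames are labelled quiescent and excluded from
both the numerator and denominator of roaming fractions.

**Age normalization.** Individuals develop at different speeds, so each
stage's frame span is divided into a fixed number of equal-duration time
bins: 75 per stage (375 total) for fine-grained profiles, 10 per stage
(50 total) for the ranking analysis. The two binnings are computed
independently from the frame-level labels (75/10 is not an integer ratio).
Per bin: roaming fraction = roaming frames / (roaming + dwelling frames),
and roaming speed = mean rolling speed over roaming frames; bins with no
scorable frames are flagged missing.

## Individuality analysis

**Ranks and biases.** Within each experiment, individuals are ranked per
time bin by roaming fraction, ascending, with fractional ranks for ties
(values 0.1, 0.3, 0.3, 0.9 rank as 1, 2.5, 2.5, 4). Ranks are rescaled to
biases

    b_{i,k} = (2 / n_i) (r_{i,k} − 1/2) − 1

with `n_i` the size of individual *i*'s experiment: bias 0 is the
experiment median, the extremes are ±(1 − 1/n). Per experiment and bin
the mean bias is exactly zero, ties included.

**Weighted PCA.** The bias matrix is decomposed by eigendecomposition of
the weighted second-moment matrix `M = Σ w_i b_i b_iᵀ / Σ w_i`, where
`w_i = 1 / (number of individuals in i's condition)` so that every
condition (strain × treatment) carries equal total weight regardless of
its size. No mean is subtracted — per-bin mean bias is zero by
construction — though a centering toggle exists for sensitivity checks.
Components are ordered by descending eigenvalue; each component's sign is
fixed so its largest-magnitude entry is positive, and correlations with
component scores are reported as absolute values. Ranking is
within-experiment while PCA weighting is within-condition; the data model
carries both labels because the two groupings differ.

**Shuffle nulls.** Null datasets preserve everything but temporal
consistency: ranks are permuted independently within each time bin
(within experiment by default, pooled optionally), keeping every bin's
rank multiset. For each of `n_reps` (default 500) replicates the variance
attributed to each PC is measured two ways: *own space* refits PCA on the
shuffled data and takes the same-numbered eigenvalue; *original space*
projects the shuffled biases onto the real components. A PC's exceedance
rate is the fraction of replicates at or above its observed eigenvalue.

A caveat worth stating plainly: only the own-space mode is a calibrated
false-positive-rate test. Under a structure-free null it flags a PC at
rate ≈ α (verified by simulation: 9/200 at α = 0.05). The original-space
mode compares the data's *maximum-variance direction* against
fixed-direction projections of shuffles and therefore fires almost always
even on pure noise; it answers "is the observed spread along this fixed
dimension larger than shuffled data's spread along it", which is the
relevant comparison when the dimension is taken as given (e.g. comparing
conditions within an established PCA space), not a test of whether the
dimension itself exceeds chance.

**Variance comparisons.** Inter-individual variance of a population's PC
scores is its dispersal along that individuality dimension. Differences
between conditions are tested by permutation: individuals of the two
conditions are pooled and reassigned to groups of the original sizes,
the statistic is |var_A − var_B| (two-sided; the source text does not
state its statistic), and p = (1 + #{perm ≥ observed}) / (1 + n_perm)
over 1000 reassignments by default, so p is never zero and never below
1/(n_perm + 1). The same procedure is exposed under the name
`bootstrap_variance_test`, the term some figure legends use for it.
Multiple testing across PCs or condition pairs uses Benjamini–Hochberg.

**Consistency index.** A pre-defined measure of homogeneous consistency:
`log2(A/B)` with A the number of time bins the individual is above the
per-bin within-experiment median and B the number below. Bins tied with
the median count toward neither (this preserves the index's antisymmetry
under reflection about the median); a zero count is replaced by 0.5,
bounding the index at ±log2(100) for 50 bins. On cohorts with a strong
planted consistency dimension, the index correlates with PC1 scores at
|r| ≈ 0.99 while PCs 2–6 stay below 0.01 — the unsupervised first
dimension rediscovers the pre-defined measure.

## Population statistics

Stage-level summaries average each individual's defined bins within a
stage (bin averaging, not frame pooling — consistent with equal-weight
age normalization), then report condition means ± SEM. Treatment effects
are expressed as per-stage ratios of condition means relative to a control
population. Group differences per bin or per stage use two-sided Wilcoxon
rank-sum tests with BH-FDR correction, reported as −log10(adjusted p)
(base 10 by convention). Size-matched comparisons re-run the test inside
20 running windows whose centers span the pooled size range, each of width
10% of the range; windows with fewer than two members per group are
flagged rather than tested.

## Worm size

Each cropped 151 × 151 frame is normalized against a background estimate
(pixel-wise mean of 8 equally spaced frames) as `(f − b + 100)/256`, so a
background pixel maps to ≈ 0.391 and a worm pixel (darker) below the fixed
threshold 0.34. Iso-contours are traced at 0.34; exactly one closed
contour is required, and the pixels whose centers fall inside it are
counted (interior-inclusive — whether boundary pixels count was an open
convention). Zero or multiple closed contours yield a missing value. A
centered 301-frame running median (10 min at 3 fps) smooths the area
series, skipping missing frames; edges use truncated windows. The
per-video background bookkeeping of the original rig (each video
normalized against the background of the 8th-next video) is simplified to
an explicit background argument: this package processes frames, not the
rig's video chunking.

## Synthetic data generator

**Matrix level.** Each individual draws a coefficient
`c_{i,d} ~ Normal(0, strength_d)` per archetype — built-in archetypes are
*homogeneous* (constant sign), *single-switch* (sign flip at the L3
midpoint) and *double-switch* (flips at L1/L2 and L4/Adult, so L1 and
adulthood share a bias), Gram–Schmidt orthonormalized in that order — and
its roaming fraction in bin k is

    p_{i,k} = stress_{s(k)} × logistic(base_{s(k)} + Σ_d c_{i,d} u_d[k] + ε_{i,k})

with `ε ~ Normal(0, noise_sd)` iid. The loadings `u_d` are the archetype
directions at unit per-bin RMS (direction × √K), so a strength is the
per-bin signal-to-noise ratio of its dimension: at strength 1 and noise 1,
half of each bin's logit variance is consistent individuality. Default
stage baselines (−1.1, −0.6, −0.2, 0.2, 0.4 logits) make roaming rise with
age. Stress factors multiply the roaming propensity on the fraction scale,
so downstream relative-effect ratios recover them directly. The logistic
link is a modeling choice for keeping fractions in [0, 1]; the source
analysis implies no generative model, and any monotone link would serve.
A single root seed spawns per-individual substreams, so cohorts are
reproducible under reordering. Planted coefficients are returned so
recovery can be tested (coefficient–PC1 score correlation 0.98 at
strength 1, n = 456).

**Trajectory level.** Roam/dwell state sequences are alternating
exponential episodes (defaults: 60 s roam, 120 s dwell — within the
seconds-to-minutes episode range; the stationary roaming fraction is the
ratio of means). Speeds are drawn per frame from state- and stage-specific
normals (roam means 60–150 µm/s rising with stage, dwell 4–6 µm/s);
heading is a random walk with step SD 1.5 deg/frame while roaming (straight
runs) and 60 deg/frame while dwelling. Lethargus spans between stages
(default 30 min, ~3% of the recording) move at |Normal(0, 0.2)| µm/s,
giving the detector unambiguous targets. These kinematic distributions are
fixtures, not estimates: no episode-duration or speed distributions were
available to fit, so the defaults were chosen once as plausible values
that produce well-separated states under the published classifier
geometry. Tests and examples run stage durations scaled to 20% of the
realistic values (≈ 138 000 frames per individual, ≈ 15 h of recording)
with the minimum quiescence duration scaled to 3 min accordingly.

**What the generator does not emulate.** Posture, pirouettes and omega
turns; tracking noise and dropped frames; gradual within-stage kinematic
drift; correlated (non-iid) per-bin noise; hatching-time variability. A
passing round-trip therefore shows the pipeline is self-consistent under
the stated two-state model, not that the classifier's slopes are optimal
for real recordings.

## Numerical choices and degenerate inputs

- Fractional (mean-of-positions) ranking everywhere; with all values tied
  the rank is (n+1)/2 and all biases are exactly 0.
- Eigendecomposition via symmetric `eigh`; eigenvalues clipped at 0;
  rank-deficient inputs are allowed (trailing zero eigenvalues).
- Reconstruction `b_i = Σ_k t_{i,k} w_k` holds to < 1e−10 on any input
  (full orthonormal basis).
- Constant pooled values in a rank-sum test give p = 1; empty
  subpopulations, overlapping permutation groups, even median windows and
  mismatched shapes raise errors rather than guessing.
- `extreme_individuals` takes ⌈fraction × n⌉ from each end with ties
  broken by stable original order.

## Sizes used in the test suite

Cohort-level checks use n = 456 (the reference cohort size) and n = 1000;
null calibration uses 200 cohorts of n = 40 with 100 shuffle replicates
each; trajectory checks use one five-stage recording at 20% duration
scale. The full suite runs in well under a minute of CPU apart from the
calibration simulation (~10 s).
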