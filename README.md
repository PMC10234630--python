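# roamind

Longitudinal behavioral individuality analysis for *C. elegans*
development: from frame-level locomotion trajectories to roaming/dwelling
profiles, and from cohort profiles to **individuality dimensions** —
temporal patterns of consistent inter-individual bias — with shuffle-null
and permutation inference.

Genetically identical worms raised in identical environments still differ
consistently in how much they roam. This package implements the analysis
machinery for quantifying that individuality across the five developmental
stages (L1–L4 and adulthood), for researchers doing long-term single-animal
behavioral tracking.

## The analysis

Starting from a centroid trajectory sampled at a fixed frame rate:

1. **Kinematics** — speed (µm/s) and absolute angular velocity (deg/s),
   averaged over a 10 s rolling window.
2. **Stage segmentation** — lethargus (molt) periods are detected as long
   quiescent spans of the smoothed speed; their midpoints split the
   recording into L1 | L2 | L3 | L4 | Adult.
3. **Roaming/dwelling classification** — a frame in stage *s* is roaming
   iff `speed/7.59 > slope_s · angvel/3.6`, the diagonal of the 50×50
   speed × turning histogram, with stage slopes (5, 2.5, 2.3, 2, 1.5).
4. **Age normalization** — each stage is divided into a fixed number of
   equal-duration bins (75/stage fine, 10/stage for ranking); per bin, the
   roaming fraction and mean roaming speed.
5. **Rank → bias** — within each experiment and time bin, individuals are
   ranked by roaming fraction (fractional ranks for ties) and rescaled to
   biases `b = (2/n)(r − ½) − 1 ∈ (−1, 1)`, zero at the experiment median.
6. **Weighted PCA** — eigendecomposition of `M = Σ wᵢ bᵢ bᵢᵀ / Σ wᵢ` with
   `wᵢ = 1/|condition(i)|` (no mean term; per-bin mean bias is zero by
   construction). Each individual's bias profile decomposes as
   `bᵢ = Σₖ tᵢₖ wₖ` — the components `wₖ` are the individuality
   dimensions, the scores `tᵢₖ` each individual's position along them.
7. **Inference** — shuffle nulls (ranks permuted independently per bin,
   500 reps) for PC significance; permutation tests (1000 reassignments)
   for differences in inter-individual score variance between conditions;
   Wilcoxon rank-sum with BH-FDR for group effects; a pre-defined
   consistency index `log2(#bins above median / #bins below)` as a
   supervised cross-check on PC1.

A synthetic-data generator produces cohorts with planted individuality
dimensions and trajectories with known roam/dwell ground truth, so the
entire pipeline is testable end to end. A worm-size module (background
normalization `(f − b + 100)/256`, 0.34-threshold contour area, 301-frame
running median) supports size-matched comparisons.

## Worked example

```python
import numpy as np
import roamind as rm

# a cohort of 456 individuals with three planted individuality dimensions
spec = rm.PopulationSpec(n_individuals=456, seed=1)
structure = rm.IndividualityStructure(
    archetypes=["homogeneous", "single_switch", "double_switch"],
    strengths=(1.5, 1.0, 0.7), noise_sd=1.0,
)
matrix, labels, coeffs = rm.generate_roaming_matrix(spec, structure)

exps = labels["experiment_id"].to_numpy()
biases = rm.bias(rm.rank_individuals(matrix, exps), exps)
model = rm.weighted_pca(biases)          # a fitted sklearn-style transformer
scores = model.transform(biases)

print(np.round(model.explained_variance_ratio_[:5], 3))
# [0.456 0.212 0.118 0.008 0.008]

sig = rm.pc_significance(matrix, exps, n_reps=100, seed=0, n_components=5)
print(sig[["pc", "exceedance_own_space", "significant_own_space"]].head(4))
#  pc  exceedance_own_space  significant_own_space
#   1                   0.0                   True
#   2                   0.0                   True
#   3                   0.0                   True
#   4                   1.0                  False

idx = rm.consistency_index(matrix, exps)
print(round(rm.consistency_pc1_correlation(idx, scores[:, 0]), 3))
# 0.963
```

The first three PCs soak up 45.6%, 21.2% and 11.8% of the weighted
variance — far above the ≈ 1/50 a structureless cohort would give each
bin — and the shuffle test (ranks permuted within each time bin) flags
exactly those three as significant. Their components recover the planted
archetypes with |cosine| ≥ 0.996, in strength order. The pre-defined
consistency index agrees with the unsupervised PC1 scores at |r| = 0.963:
the first individuality dimension *is* cross-development consistency.

`WeightedPCA` and `BiasTransform` follow scikit-learn's estimator API
(`fit`/`transform`, `components_`, `explained_variance_`), so they compose
with sklearn pipelines.

The same analysis is scriptable from the shell:

```bash
roamind simulate matrix --seed 1 --out sim/
roamind pca --matrix sim/roaming_matrix.csv --labels sim/labels.csv \
        --reps 500 --seed 0 --out pca/
roamind run-all --seed 5 --out run/     # simulate → rank → PCA → compare
```

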