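# Methods

## Problem and data model

The package analyses along-tract ("tractometry") profiles of
diffusion-tensor metrics. Each subject contributes, for each of eight
language-related tracts (left and right arcuate, inferior
fronto-occipital, inferior longitudinal and superior longitudinal
fasciculi), a profile of FA, MD, RD and AD sampled at 100 equidistant
nodes along the tract core — the long-format export of an AFQ-style
pipeline. Demographics carry group (TD / ASD), age, sex and behaviour
scores (ABC, GDS developmental quotients, ADOS severity for the ASD
group).

A (subject, tract) profile is either complete on the node grid or
missing as a whole; ragged profiles are rejected at load time, and
missing profiles are excluded listwise from any analysis touching that
tract. Node identifiers are echoed verbatim from the input (default
grid 0–99), so reported intervals use the file's own labelling.
Validation is strict: FA must lie in [0, 1], diffusivities must be
positive, and RD ≤ AD (the tensor eigenvalue ordering).

## Statistical models

**Lateralization.** For each tract pair and metric the lateralization
index is LI = (R − L)/(R + L), computed on tract-wise means (average
over the node grid per hemisphere first). Positive LI means the right
hemisphere carries the larger value. Analyses: (1) one-sample t-tests
of mean LI against zero per group; (2) group comparison
LI ~ group + age + sex; (3) LI ~ score + age + sex within group and
LI ~ group × score + age + sex for the interaction. For FA a
significantly positive t is labelled rightward lateralization; for the
diffusivities the label is reversed (lower diffusivity ≈ greater
integrity), matching how asymmetry of integrity is conventionally
read.

**Group comparisons.** metric ~ group + age + sex (group coded TD = 0,
ASD = 1; sex M = 0, F = 1), fitted by OLS at the tract-wise level
(tract means) and point-wise per node. Standard errors use the
unbiased residual-variance estimator; all tests are two-sided.

**Permutation inference.** The default scheme for covariate-adjusted
models is Freedman–Lane residual permutation: the response is reduced
to fitted values plus residuals of the model without the tested term,
residuals are permuted, the full model refit and the term's t
recorded. Plain label permutation is available as an option and is
used where no covariates are present. One-sample LI tests use random
sign flips, exact under a null symmetric about zero. Permutation
p-values use the add-one estimator (1 + #{|t*| ≥ |t|})/(B + 1), which
is a valid p-value for any B; defaults are B = 5000.

**Family-wise error.** Correction is by the max-statistic method:
every test in a family shares the permutation sequence, and corrected
p compares observed |t| with the null distribution of the family-wise
maximum |t|. Default families follow reporting granularity: the 4
tract pairs within a metric for LI tests; the 8 tracts within a metric
for tract-wise tests and tract-level associations; the 100 nodes
within a (tract, metric) for point-wise tests; the discovered clusters
within a (metric, scope) for cluster-level associations. The family
assignment is configurable.

**Cluster rule.** Point-wise findings require more than three
consecutive corrected-significant nodes, i.e. a maximal run of length
≥ 4 with corrected p < α at every node. Correction precedes cluster
formation and no further correction is applied afterwards. Cluster
boundaries are reported inclusively in input node labels.

**Associations.** metric ~ score + age + sex within group (language
quotient in both groups; ADOS total in the ASD group only), plus the
group × score interaction model; responses are tract means or, at
cluster level, segment means over node intervals — typically the
clusters surviving the group comparison. Because those intervals are
selected on a group contrast in the same sample, cluster-level
association outputs carry a `selection_dependent` flag. Effect sizes
are squared partial correlations of score and response given age and
sex (residualise both on the covariates with intercept, square the
Pearson correlation of the residuals).

## Synthetic data generator

The generator treats the axial (λ1 = AD) and radial (λ2 = λ3 = RD)
eigenvalue fields as primary and derives MD = (AD + 2 RD)/3 and the
prolate-tensor FA = (AD − RD)/√(AD² + 2 RD²), so the cross-metric
invariants hold by construction. Each field is a smooth node baseline
(≈1.15×10⁻³ and 0.55×10⁻³ mm²/s with mild sinusoidal shape, per-pair
size factors) times multiplicative layers:

- pair-common subject size factor (SD 0.05) — shared by hemispheres
  and fields, so it cancels in both the LI and FA;
- pair-common per-field factor (SD 0.015) — cancels in the LI, drives
  between-subject FA variance;
- hemisphere-specific per-field factor (SD 0.010) — drives LI
  variance;
- covariate trends: −2 %/yr (axial) and −3 %/yr (radial) around the
  mean age, so diffusivities fall and FA rises with age, +0.5 % for
  female sex;
- a Gaussian-process node field (SD 0.03) with squared-exponential
  correlation, length 10 nodes — real tract profiles are smooth, and
  white node noise would make the cluster criterion unrealistically
  conservative.

These defaults put the between-subject node SDs, tract-mean SDs and LI
SDs in the ranges of the cohort's printed summary tables.

Hemispheric asymmetry targets are applied as ±μ scalings: AD targets
on λ1, RD targets on λ2; the MD asymmetry is thereby implied (with the
default AD/RD targets it lands on the printed MD LI means), and FA
targets are applied as a residual factor on top of what the eigenvalue
scalings already imply, so the expected FA LI equals the target.
Default asymmetry means are the cohort's printed group-specific LI
values.

Group effects are additive on a node window (full strength on the
stated interval, half at one node beyond each edge) on the relevant
field: AD → λ1, RD → λ2, MD → both (shifting MD by the stated
amplitude), FA → the derived FA, with a C¹ smooth clamp keeping FA
inside (0, 1) (identity on [0.02, 0.98]). Amplitudes may be given in
metric units or as a standardized d, converted using the pre-effect
between-subject node SD of the generated sample itself, so d is exact
for the realized nuisance structure. Behaviour links add
slope × (score − group mean) to every node of a tract. Behaviour
scores are truncated normals with the cohort's printed group means,
SDs and ranges; ADOS total is SA + RRB by construction. Ages are
truncated normals on the printed ranges; sex counts reproduce the
printed 17/5 and 24/4 splits. Everything derives from one seed and is
bit-reproducible; a truth record stores every injected parameter.

What the generator does **not** emulate: spatial correlation between
tracts, non-stationary node variance, floor/ceiling effects in
behaviour scores beyond truncation, measurement error correlated with
age or motion, and any nonlinear metric–behaviour relation. Passing
calibration/recovery suites therefore demonstrates correctness of the
inference machinery under a realistic smooth-profile model, not
robustness to arbitrary real-data pathologies.

## Numerical choices

- OLS via explicit normal equations with (XᵀX)⁻¹; designs are checked
  for full column rank (tolerance 10⁻⁸·n) and rank-deficient designs
  name the collinear terms. Exact fits (zero residual variance) give
  infinite t and parametric p = 0.
- Permutations for a family share one permutation sequence (required
  by max-statistic correction); the Freedman–Lane path is vectorised
  over responses and chunked so intermediate arrays stay near 4×10⁶
  elements.
- Fisher's exact test delegates to scipy's hypergeometric
  implementation; tests pin it against explicit enumeration.
- The smooth FA clamp is m²/(2m − x) below m = 0.02 (mirrored above
  1 − m): C¹, monotone, identity inside the margin.
- Eigenvalue safety: RD is capped at 0.995·AD after every additive
  layer; with default noise scales the cap is essentially never
  active.
- Ties in permutation counts use ≥, which is conservative.

## Calibration and recovery suites

`tractstats.calibration` re-runs the full analysis paths on replicated
synthetic datasets at the default study-scale conditions (22 TD /
28 ASD, 100 nodes): false-cluster rate and LI family-wise error under
the global null, uniformity of null association p-values, and recovery
of injected clusters (standardized amplitude 1.5 on nodes 38–42), LI
offsets and behaviour slopes. The shipped suites use 200 replicates ×
1000 permutations and run the point-wise calibration on a 2-tract ×
2-metric subset; these sizes keep Monte-Carlo error near 0.015 on a
rate while the whole suite completes in a few minutes on one CPU.

## Known limitations

- Cluster-level associations inherit the selection bias of testing
  intervals chosen by a group contrast in the same sample; the flag
  makes this visible but does not remove it.
- The permutation engine assumes exchangeable subjects; no nested or
  longitudinal structure.
- Point-wise node p-values are corrected within (tract, metric) only;
  no correction spans tracts or metrics at node level (configurable
  family, but the default mirrors per-tract reporting).
- The generator's FA is derived from a prolate tensor; crossing-fibre
  geometries that depress FA nonlinearly are out of scope.
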