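# Methods

`tractwise` implements the statistical chain used in along-tract ("tractometry")
studies of white matter and behavior: a tract is reduced to N equidistant nodes
along its core, each node carries a fractional-anisotropy (FA) summary per
subject, and brain–behavior structure is probed node by node with covariate
control, cluster-level multiple-comparison correction, follow-up correlations,
and behavioral regressions. Because no subject-level data ship with the
package, a seeded synthetic-cohort generator supplies inputs with the
statistical structure the analysis assumes; every stage is exercised end to end
on generated data.

## Tract profiles

FA is computed from the diffusion-tensor eigenvalues as the normalized standard
deviation, FA = sqrt(3/2)·‖λ − mean(λ)‖/‖λ‖, which is scale-invariant and lies
in [0, 1]. The quantification path accepts bundles of streamlines and produces
a per-node profile by (1) iterative outlier cleaning, (2) equal-arc-length
resampling to the tract's node count (100 for the direct and anterior arcuate
segments, 30 for the shorter posterior segment), and (3) a weighted average of
per-point FA samples at each node.

Cleaning removes streamlines whose mean Euclidean distance to the bundle core
(the pointwise mean of the node-resampled streamlines) exceeds 5 SD of the
distance distribution, or whose length exceeds 4 SD above the mean length,
iterating until nothing is removed. The mean and SD are computed
*leave-one-out*: a gross outlier inflates the plain sample SD enough to mask
itself in small bundles — in a 20-streamline bundle the largest attainable
plain z-score is (n−1)/√n ≈ 4.36, so a 5 SD rule with plain statistics could
never fire. Leave-one-out statistics restore the intended behavior while
leaving clean bundles untouched (zero-variance bundles flag nothing).
Bundles reduced below 3 streamlines produce a warning, never an error.

Node averaging defaults to Gaussian weights in each streamline's per-node
distance from the core, with the local bundle spread as bandwidth; uniform
weighting is available. Which anatomical end of a tract is node 1 is a
convention the package does not fix: bundles are oriented so node 1 is the
endpoint nearest a configurable anchor point.

## Node-wise statistics

The core statistic is the partial correlation between FA at one node and a
behavioral outcome after linearly regressing both on covariates (with
intercept): age and sex for the shared analyses, plus the other language's
reading score for language-unique analyses. Two-tailed p-values use the t
transform with df = n − 2 − k. Missing data are removed listwise at the subject
level over {outcome} ∪ covariates before the node loop, so n is constant
across a tract's nodes. The conjunction of two maps is the set of nodes
significant in both at the node-level alpha *with the same sign of r*; the
sign requirement prevents a node from counting as "common" when the two
outcomes relate to FA in opposite directions.

## Cluster inference

Adjacent nodes are strongly correlated, so per-node correction is far too
conservative. Clusters are maximal runs of adjacent nodes with p < 0.05
(two-tailed) and constant sign. Family-wise error is controlled by the
max-statistic permutation method: the outcome is shuffled across subjects
(covariates stay with their subjects), the full node-wise map is recomputed,
and the maximum cluster size recorded, 1,000 times by default. The critical
size c* is the smallest integer whose exceedance proportion in the null is at
most alpha; an observed cluster of size ≥ c* is *stringent*-significant. A
*lenient* descriptive threshold (≥ 9 adjacent nodes on 100-node tracts, ≥ 3 on
30-node tracts) is reported alongside. A Freedman–Lane variant (permuting
covariate-residuals of the outcome) is available behind a flag; plain outcome
shuffling is the default as the simplest scheme.

Degenerate cases are resolved reproducibly: a permutation with no
suprathreshold cluster records a maximum of 0; c* is computed on the raw
empirical distribution without smoothing; when no size satisfies the tail
bound, c* is n_nodes + 1 (nothing can be stringent). Because cluster sizes
are integers, the realized exceedance at c* is typically below alpha, making
the procedure mildly conservative (measured family-wise false-positive
proportion ≈ 0.035–0.055 at alpha = 0.05 over 200 simulated null cohorts).

When the full pipeline runs many maps (six tracts × two language-unique
analyses), per-analysis correction alone would let the run-level error rate
grow to ~35–45%. `run_pipeline` therefore pools the per-permutation maxima
across all analyses sharing a node count and derives one critical size per
family (one for 100-node tracts, one for 30-node tracts), keeping the
run-level rate near alpha (measured 8% of 25 null runs with some stringent
cluster). Per-analysis correction remains available
(`family_correction="per-analysis"`), and the standalone `permutation_fwe`
is always per-analysis.

## Cluster follow-up

For clusters passing at least the lenient threshold, the per-subject
unweighted mean FA over the cluster's nodes is correlated with candidate
cognitive measures (phonological awareness, visual-spatial ability, tone
discrimination) partialling age and sex. 95% confidence intervals come from a
percentile bootstrap (1,000 resamples of the residualized pairs; a resample
with zero variance in either coordinate is redrawn). Correlations are compared
with Fisher's r-to-z test for independent samples,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), with no degrees-of-freedom
adjustment for the partialled covariates — the convention that reproduces all
five published worked-example z statistics (0.91, 2.07, 2.42, 2.11, 1.5) from
their printed (r, n) pairs to two decimals. The compared correlations share
the FA variable and are not strictly independent; a Steiger-style dependent
test is provided for completeness but is not the default.

## Stepwise regression

Behavioral contributions to reading skill are assessed by forward stepwise
selection with backward removal over {age, sex, phonological awareness,
visual-spatial ability}: entry at probability-of-F 0.05, removal at 0.10 (the
conventional defaults of the statistics package named for this procedure;
configurable). Variables are z-scored on the complete cases (n−1 SDs), so a
lone predictor's standardized beta equals its Pearson correlation with the
outcome. Each step reports beta and t per retained predictor, R², ΔR², and
F = (R²/k)/((1−R²)/(n−k−1)); for one added predictor the ΔR² F equals that
predictor's t². Listwise deletion fixes one analysis sample before selection.
Near-collinear candidate sets (condition number > 1e8) are rejected by name;
zero entries is a valid outcome, not an error.

## Synthetic cohort generator

The generator emulates a ~40-child bilingual reading cohort:

- **Behavioral scores.** A multivariate normal on standardized scales with a
  configurable correlation matrix, mapped affinely to target means/SDs and
  clipped to the published score ranges. Clipping biases moments, so the
  pre-clipping mean/SD are calibrated by root-finding on the closed-form
  clipped-normal moments; the *post*-clipping moments then hit the targets
  (verified to 2 SE over 200 replicates). Scores are kept continuous; real
  test scores are integers, a feature the generator does not emulate.
- **Correlation defaults.** Only two entries are anchored by published
  step-1 standardized betas (age→Chinese reading 0.633, age→English reading
  0.426, which for a lone predictor equal zero-order correlations). The rest
  are plausible defaults chosen once to mirror the regression tables
  qualitatively (both PAs related to their language's reading, visual-spatial
  related to Chinese reading, sex independent of everything); they are
  configuration, not estimates of the study's unknown matrix.
- **Missingness.** Exact counts with overlap constraints, assigned to random
  subjects (no mechanism is published): 4 subjects miss the visual-spatial
  score and the 1 subject missing Chinese PA is among them, so the Chinese
  regression variable set has exactly 36 complete cases of 40.
- **Sex.** Exact 25/15 split, independent of scores.
- **Profiles.** Per tract, FA(subject, node) = mean profile + Gaussian-process
  noise with squared-exponential kernel corr(i,j) = exp(−(i−j)²/2ℓ²)
  (default ℓ = 5 nodes, node SD 0.05, a typical along-tract scale) + effects,
  clipped to [0,1]. Availability is Bernoulli per subject at the published
  per-tract rates (35/37, 30/37, 36/37, 30/37, 37/37, 37/37).
- **Effects.** A rectangular node window gains beta·u per subject, where u is
  the subject's standardized behavioral residual after the effect's stated
  covariates and beta = noise_sd·ρ/√(1−ρ²), so the realized partial
  correlation converges to the target ρ as n grows (median realized r within
  0.15 of a 0.55 target at n = 35 over 50 replicates). No smooth taper; with
  zero noise the embedding degenerates to zero (profiles equal the mean).

One global seed expands into fixed per-stage child seeds (behavior, profiles,
permutation, bootstrap, availability, missingness) via `SeedSequence`, so any
stage reruns identically in isolation.

What passing tests on generated data do *not* show: robustness to real FA
profile shapes (non-stationary variance, subject-level profile offsets,
registration error), to non-Gaussian score distributions, or to missingness
that depends on ability. The generator is a calibration instrument for the
statistics, not a forward model of the imaging process.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their Monte-Carlo error small
relative to the tested bands: 200 null cohorts × 500 permutations for the
family-wise error rate, 50 seeds for recovery rates, 1,000 simulations for
bootstrap coverage, 20 seeds per autocorrelation length for critical-size
monotonicity, 1,000 random fixtures for oracle-equivalence checks. Report
floats are serialized at 6 decimals with a 17-significant-digit sidecar for
byte-level reproducibility. The forward-selection loop is capped at twice the
candidate count to preclude entry/removal cycling.

## Known limitations

- The published data-dependent results (specific node ranges, critical sizes
  16/15/24/7, follow-up r values) depend on unavailable subject-level data and
  are not reproduced; the package reproduces the printed *worked examples*
  (Fisher z, regression F algebra) and the statistical properties of the
  procedures.
- The permutation scheme underlying the published analysis (outcome vs.
  residual shuffling) is not documented there; both are implemented.
- Whether the published conjunction required sign agreement is unknown; the
  sign rule here is a deliberate design choice.
- The stepwise "hierarchical" mode is pure forward-with-removal over all
  candidates; a forced-entry first block is not implemented.
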