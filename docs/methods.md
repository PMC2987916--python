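# Methods

This note documents the models, numerical conventions and design choices
behind `covnet`, and what the synthetic-data studies do and do not
demonstrate about real morphometric data.

## The analysis model

A structural covariance network treats the across-subject correlation of
regional gray-matter volumes as an (indirect) index of anatomical
connectivity. The unit of analysis is the *group*, not the subject: one
90 × 90 Pearson matrix per diagnostic group, estimated from that group's
subjects after nuisance regression.

**Confound regression.** Each region is regressed on intercept, age (years),
sex (0 = female, 1 = male) and total gray-matter volume with ordinary least
squares; the residuals carry forward. The design is shared across regions.
Constant covariates (e.g. a single-sex cohort) are dropped with a logged
warning and the retained regressor count is reported as `design_rank`;
fitting is refused when subjects < regressors + 2. No shrinkage or robust
variants are offered: the model is deliberately the plain linear correction
standard in this literature. Total gray-matter volume is defined as the row
sum of the 90 regional volumes — the simplest internally consistent choice,
since the measure is otherwise underdetermined by a volumes table.

**Correlation and thresholding.** Pearson (not partial) correlation is used:
with ~100 subjects and 90 regions the residual matrix is too close to rank
deficiency for a stable inverse-covariance estimate, and plain correlation
is what the field's group-level covariance studies report. The matrix is
binarized at a target sparsity `S`: `K = round(S · N(N−1)/2)` edges
(half-up rounding gives the closest achievable sparsity), taking the `K`
pairs with the largest |r|. Ranking by magnitude rather than signed r is
the default because gray-matter covariance matrices contain genuine negative
correlations and nothing in the analysis requires discarding them; a
`rank="positive"` switch selects by signed r instead. Ties at the cutoff are
broken by (i, j) lexicographic order, which makes edge sets nested across
sparsities and every run reproducible. Note that an edge-level significance
filter would be redundant here: fixing the edge count *is* the thresholding
rule, and it is what makes topology comparable across groups.

**Graph metrics.** Clustering uses `C_i = 2 e_i / (k_i (k_i − 1))` with
`C_i = 0` for degree < 2 (the common convention; such nodes stay in the
mean). Path length uses unweighted breadth-first distances;
`L_i = Σ_{j≠i} d(i,j)/(N−1)` and `Lp` is the node mean. Disconnected
networks raise an error carrying the component sizes rather than returning
an infinite or harmonic-mean value — the analysis is defined on the sparsity
range where networks are fully connected. Betweenness follows the
Freeman/Brandes definition with fractional credit across tied shortest
paths (computed via networkx); normalized betweenness divides by the network
mean, with an all-zero betweenness vector (complete graphs) mapped to zeros
and a warning. Hubs are nodes with `b_i > 2`.

**Null networks.** Surrogates preserve the degree sequence exactly via
double-edge swaps — pick edges (a,b), (c,d), replace with (a,d), (c,b) —
rejecting self-loops and duplicate edges, and preserving connectedness so
`Lp_rand` stays finite. Connectivity is enforced with the standard windowed
strategy: swaps are accepted in batches and a batch is rolled back (and the
window shrunk) when a connectivity check fails. Each surrogate performs
10·K accepted swaps, enough to decorrelate a 90-node network from its
starting topology; `n_random` defaults to 100 and is configurable (the
bundled studies use 20, which already gives sub-1% Monte-Carlo noise on
Cp_rand at these sizes). A retry budget bounds rigid cases (e.g. a
triangle), which return the input with a warning and the accepted-swap
count.

**Edge-wise comparison.** Fisher's z with variance 1/(n−3) per group and a
two-tailed normal reference; all 4005 pairs are tested regardless of which
edges survive thresholding, since the correlation difference is meaningful
for every pair. Multiplicity is handled by Benjamini–Hochberg at q = 0.01
(default); Benjamini–Yekutieli is available (`method="by"`) for worst-case
dependence, at a substantial power cost.

**Permutation test.** The observed ΔCp and ΔLp come from the real group
split; the null pools both cohorts and redraws group labels at the original
sizes, re-running the *entire* pipeline — including confound regression
within each pseudo-group — per relabeling. Decisions use the empirical
2.5th/97.5th percentiles of the null with the non-interpolating
order-statistic convention (`lower`/`higher`), the standard conservative
choice that keeps the two-tailed level at or below 5% under the
discreteness of a finite permutation set; an exact-style p-value with the
+1 correction is reported alongside. Relabelings that produce a
disconnected pseudo-network at the working sparsity are redrawn and
counted; the identity split itself must be connected or the test refuses to
run. The same machinery drives a per-node variant with normalized
betweenness as the statistic; because 90 node-level tests run at once, its
table reports both uncorrected two-tailed 5% decisions and BH-corrected
ones, clearly labeled — the corrected column is the defensible one.

**Bootstrap.** Subjects are resampled with replacement and the full pipeline
(with a reduced surrogate count, default 10) is re-run per resample; the SD
of the bootstrap distribution is the reported standard error and the
2.5/97.5 percentiles the interval. Resamples yielding a zero-variance
region or a disconnected network are redrawn and logged.

## The synthetic cohort generator

The generator produces the study conditions the pipeline assumes, with
exact ground truth. Latent region scores are multivariate normal with a
three-level correlation matrix: `homotopic_corr` for left/right mirror
pairs, `within_block_corr` inside a community block, `between_block_corr`
elsewhere (PSD-checked at construction; violations raise with the offending
eigenvalue). Volumes are affine transforms of the scores:

    vol = baseline · (1 − atrophy) · (1 + global_cv · g)
          + noise_sd · z + β_age · (age − 73) + β_sex · sex

with `g ~ N(0,1)` a per-subject brain-size factor. Because Pearson
correlation is affine-invariant, the confound-free correlation of the
volumes equals the latent matrix exactly. The brain-size factor inflates
every raw inter-regional correlation — exactly the global effect that
total-gray-matter regression is designed to remove — so residualization
recovers the latent structure better than raw correlation whenever
confounds are active (a tested invariant). Defaults: `noise_sd = 0.5`
against baselines of 4–6.7 arbitrary units, `global_cv = 0.1` (≈10%
brain-size CV), `β_age = −0.01` units/year (mild age atrophy across a
56–90-year span), `β_sex = 0.15` (males slightly larger). Ages are uniform
over each group's observed range and sex is Bernoulli at each group's
male fraction, so the nuisance-regression path is genuinely exercised.

**Community blocks.** The default partition uses 12 lobe-like, hemisphere-
mirrored blocks (sensorimotor, dorsolateral and orbital/medial frontal,
insula–cingulate, medial temporal, medial and lateral occipital, parietal,
subcortical, lateral temporal, temporal pole). Sub-lobar granularity is a
structural requirement, not cosmetic: with a handful of large lobes the
within-block pair pool exceeds the edge budget at 10% sparsity, so
thresholded networks lose their between-block shortcuts, fragment, and show
inflated λ. With 12 blocks the within pool (~307 pairs) sits below K at
S = 0.10 (401 edges), guaranteeing long-range edges at every working
sparsity. Verified over 30 generator seeds: no disconnected network in 450
group-by-sparsity combinations.

**Three-group preset.** NC is the baseline (within 0.40 / between 0.24,
homotopic 0.8); MCI strengthens local and weakens long-range covariance
(0.45 / 0.215), AD more so (0.50 / 0.19), with mean atrophy fractions 0.03
and 0.08 that shift means without touching correlations. The magnitudes are
calibration choices — no published effect sizes exist for these covariance
differences — selected so the designed qualitative behavior is realized
robustly: all groups small-world (γ > 1, λ ∈ [0.9, 1.3]) across S =
0.10–0.30, and Cp(AD) > Cp(MCI) > Cp(NC), Lp(AD) > Lp(MCI) > Lp(NC) at
S = 0.15 on the large majority of seeds (28/30 and 27/30 in the
calibration sweep). The preset's group differences are diffuse: spread
over thousands of pairs they move Cp and Lp decisively (the permutation
test rejects NC-vs-AD) while individual edges rarely survive FDR at
q = 0.01 — so an edge-map run on the preset legitimately reports few or
zero significant pairs.

**What the generator does not emulate.** Image-level artifacts (smoothing,
segmentation error, registration bias), non-Gaussian volume distributions,
site/scanner effects, spatially heterogeneous confound slopes, and
correlated atrophy (atrophy here shifts means only). Passing tests
demonstrate that the *pipeline* is correct and calibrated under its stated
model, not that real gray-matter covariance satisfies that model.

## Numerical and testing conventions

- Graph metrics are validated against exhaustive oracles (all-simple-path
  enumeration in exact rational arithmetic) on hundreds of random connected
  graphs of ≤ 7 nodes, and betweenness additionally against an independent
  library implementation.
- All stochastic procedures (generation, rewiring, permutation, bootstrap)
  are bit-reproducible under a seed; independent consumers draw from
  separate `SeedSequence` streams.
- Simulation studies in the test suite are sized to keep the whole suite
  around a minute — e.g. 100 replicates × 200 relabelings for type-I-error
  calibration on a 10-region reduced atlas, 200 replicates for FDR control
  with planted homotopic differences — sizes at which the binomial /
  Monte-Carlo error bands quoted in the tests are meaningful.
- File I/O is plain UTF-8 CSV with a `#` provenance comment line; floats
  round-trip exactly (`float_precision="round_trip"` on read).

## Known limitations

- The hub threshold (b > 2), sparsity grid and q-values are conventions of
  this analysis style, not optimized quantities.
- The permutation and bootstrap loops re-run the full pipeline per draw;
  at 90 regions and 1000 draws this is seconds-to-minutes, but nodal
  permutation with betweenness is the slowest path (Brandes per draw).
- The 10-region reduced atlas used in calibration studies has coarse,
  discrete graph metrics; power there is intentionally not representative.
- Partial-correlation or sparse-precision network estimation is explicitly
  out of scope.
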