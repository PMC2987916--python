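# covnet — structural covariance cortical networks

`covnet` builds and compares group-level *structural covariance networks*
from regional gray-matter volumes. In this kind of study each diagnostic
group (e.g. healthy elderly controls, mild cognitive impairment, Alzheimer's
disease) contributes a subjects × regions table of mean gray-matter volumes
over the 90-region AAL parcellation (45 bilateral structures, cerebellum
excluded); the across-subject Pearson correlation between every pair of
regions — after regressing out age, sex and total gray-matter volume —
defines a 90 × 90 connectivity matrix whose graph-theoretic organization can
be compared between groups. The package is aimed at researchers analyzing
morphometric covariance (or teaching/simulating such analyses) who want the
whole chain — cohort tables to publication-style statistics — as tested,
scriptable Python.

## The pipeline

For each group with *n* subjects and regional volumes `y_ij`:

1. **Confound regression.** Per region *j*, fit
   `y_ij = β0 + β1·age_i + β2·sex_i + β3·TGV_i + ε_ij` by OLS and keep the
   residuals (TGV = total gray-matter volume, the row sum).
2. **Correlation matrix.** `R[j,k]` = Pearson correlation of the residuals
   across subjects; 90·89/2 = 4005 distinct region pairs.
3. **Sparsity thresholding.** Keep the `K = round(S · 4005)` strongest
   pairs (by |r|) as the edges of a binary graph, so every group network has
   identical node and edge counts at a given sparsity `S` (working range
   10–30%, fixed comparisons at `S = 0.15`).
4. **Small-world metrics.** Mean clustering coefficient
   `Cp = mean_i [2 e_i / (k_i (k_i − 1))]` and characteristic path length
   `Lp = mean_i mean_{j≠i} d(i,j)`, referenced to degree-matched rewired
   surrogates: `γ = Cp / Cp_rand`, `λ = Lp / Lp_rand`. A small-world network
   has `γ > 1` with `λ ≈ 1`.
5. **Hubs.** Betweenness centrality `B_i` (fractional credit over tied
   shortest paths), normalized as `b_i = B_i / ⟨B⟩`; regions with `b_i > 2`
   are hubs.
6. **Between-group inference.**
   - *Edges:* Fisher's `z = atanh(r)` per group, test statistic
     `Z = (z_A − z_B) / √(1/(n_A−3) + 1/(n_B−3))`, Benjamini–Hochberg FDR at
     `q = 0.01` over the 4005 pairs.
   - *Topology:* label-permutation test — pool the groups, relabel at the
     original sizes, re-run the entire pipeline per pseudo-group, and
     compare the observed ΔCp / ΔLp with the 2.5–97.5 percentile band of
     1000 relabelings (two-tailed 5%).
   - *Uncertainty:* bootstrap over subjects for Cp, Lp, γ, λ error bars.

A synthetic-cohort generator (`covnet.synthetic`) emulates the statistical
structure such data exhibit — strong homotopic (left/right mirror-pair)
correlation, lobe-like community blocks, age/sex/brain-size confounds, and
group presets that strengthen local and weaken long-range covariance along
the NC → MCI → AD progression — so the full pipeline is testable end to end
without access to restricted imaging data.

## Worked example

```python
import covnet

spec = covnet.default_three_group_spec(seed=7)      # NC/MCI/AD, 98/113/91
cohort = covnet.generate_cohort(spec, "NC")
model = covnet.StructuralCovarianceNetwork.from_cohort(cohort)
res = model.fit(sparsity=0.15, n_random=20, seed=42)
print(res.summary())
```

```
Structural Covariance Network Results
=====================================================
Group:                NC
Subjects:             98
Regions:              90
Confound design rank: 4
Sparsity:             0.150  (K = 601 edges)
Surrogates:           20 (degree-matched rewired)
-----------------------------------------------------
Cp     (clustering):        0.2858
Lp     (path length):       2.0414
gamma  (Cp / Cp_rand):      1.7345
lambda (Lp / Lp_rand):      1.0336
-----------------------------------------------------
Hub regions (normalized betweenness > 2):
  SupraMarginal_R          b = 4.524
  Frontal_Mid_R            b = 2.958
  Precuneus_R              b = 2.462
  Frontal_Sup_Orb_L        b = 2.284
  Paracentral_Lobule_R     b = 2.117
  SupraMarginal_L          b = 2.032
  Cingulum_Post_L          b = 2.019
```

Reading the numbers: at 15% sparsity the NC network keeps its 601 strongest
correlations; its clustering is 1.73× that of degree-matched random graphs
while its path length is only 1.03× — the small-world signature. Seven
regions route more than twice the average number of shortest paths and are
flagged as hubs. Group comparisons hang off the results object:

```python
ad = covnet.StructuralCovarianceNetwork.from_cohort(
    covnet.generate_cohort(spec, "AD")).fit(sparsity=0.15, n_random=20, seed=43)
edges = res.compare_edges(ad, q=0.01)        # Fisher-z + FDR edge map
perm = res.permutation_test(ad, n_perm=1000, seed=44)  # ΔCp / ΔLp test
ci = res.bootstrap_ci(n_boot=200, seed=45)   # error bars for Cp, Lp, γ, λ
```

The same stages are scriptable from a shell (`covnet simulate`, `covnet
correlate`, `covnet metrics`, `covnet compare-edges`, `covnet permtest`,
`covnet summary`); all files are plain CSV/JSON/YAML.

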