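# Methods

## The model

The analysis treats DNA methylation of a CpG probe as a quantitative trait
(beta value in [0, 1], the methylated fraction reported by Illumina
arrays) and asks which differentially methylated regions (DMRs) are
*co-methylated* — which regions' CpGs rise and fall together across
samples. The machinery is weighted-network analysis applied to methylation:

- **Adjacency.** `a_ij = |PCC_ij|^β`, an unsigned weighted network on
  probes. The power β suppresses weak correlations smoothly instead of
  hard-thresholding them.
- **Soft-threshold selection.** For each candidate power (integer grid
  1–20), node connectivities `k_i = Σ_{j≠i} a_ij` are binned into 10
  equal-width bins; the fraction of nodes per bin `p(k)` against the bin's
  mean connectivity is fit by ordinary least squares on log10–log10 axes.
  The selected β is the smallest candidate with squared correlation
  `R² > 0.70` and negative slope — the smallest power at which the network
  looks scale-free. The full diagnostic table over the grid is always
  returned; failure to qualify is an error that carries the table, so a
  caller can inspect it and force a power deliberately.
- **Topological overlap.** `TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 −
  a_ij)` with `L_ij = Σ_{u≠i,j} a_iu a_uj`: the unsigned Zhang–Horvath
  variant with the `min(k)+1−a` denominator. TOM rewards probe pairs whose
  neighbourhoods overlap, which denoises individual correlations. It is
  computed with matrix products and verified in tests against the literal
  triple-loop definition to 1e−10.
- **DMR aggregation.** The DMR-level weight between regions d1 and d2 is
  the arithmetic mean of `TOM_pq` over all |d1|·|d2| cross pairs. Within-
  region pairs and the diagonal are excluded by default: including them
  would inflate apparent between-region connectedness asymmetrically for
  CpG-rich regions. Because the aggregation wording could also be read as
  a mean over the union submatrix, that variant is available as
  `include_within_dmr=True` rather than silently guessed.
- **Extraction and hubs.** DMR pairs with average TOM at or above a cutoff
  become edges; all regions stay in the node set so isolated DMRs remain
  visible; connected components are numbered by descending size. Hub
  tables report degree and `100 × degree / total edges` — percentages are
  relative to the whole network, so a top-10 listing does not sum to 100.
- **Cutoff choice.** In the published analyses of this kind the cutoff is
  picked per dataset by the analyst (values 0.15–0.35 are typical).
  For unsupervised use, `choose_cutoff` scans a grid (0.01–0.95, step
  0.01) and picks the smallest cutoff whose connected-component partition
  maximises unweighted modularity on the thresholded graph. This is a
  reportable convention, not a claim that any published cutoff was chosen
  this way.

## Group testing

A DMR's methylation state is the vector of its member-CpG beta values, so
group comparison is multivariate: Hotelling's T². Two-sample form
`T² = (n1 n2/(n1+n2)) d̄ᵀ S_pooled⁻¹ d̄` with
`F = (n1+n2−p−1)/(p(n1+n2−2)) · T²` against `F(p, n1+n2−p−1)`; the paired
form is the one-sample T² on within-pair differences against `F(p, n−p)`.
For p = 1 both reduce to the familiar squared t statistics (asserted in
tests, 1e−10).

Regions can carry more CpGs than there are error degrees of freedom in
small cohorts. The default then shrinks the covariance toward its diagonal
with a Ledoit–Wolf-style intensity estimated from the centered data
(floored at 1e−3), keeps the F reference approximately (df2 floored at 1),
and flags the row `regularized=True`. Disabling regularization turns these
cases into hard errors. Samples with any missing CpG in the tested region
are dropped for that region (complete-case); imputation would invent data.
Untestable regions are flagged, never dropped, so result tables always
have one row per DMR. Multiple-testing correction defaults to "none" to
match per-comparison reporting conventions; Bonferroni and
Benjamini–Hochberg are available.

Beta values are analysed as-is, without an M-value transform, matching how
methylation levels are distributed in public array matrices. The F
reference is exact under normality; on bounded beta values it is an
approximation, which is why the test suite checks the empirical type-I
error of the whole pipeline (it stays within [0.02, 0.08] at nominal
α = 0.05 over 200 null replicates).

## The synthetic-data generator

Simulation happens on the M-value scale (logit2 of beta), where Gaussian
factor models are natural, and maps to beta values by the logistic
transform, so emitted values are strictly inside (0, 1):

    M_p(s) = μ_p + λ z_m(s) + γ u_d(s) + δ·1[case, affected] + ε

with one latent factor z per co-methylation module, one factor u per DMR,
fixed probe offsets μ_p ~ N(0,1), and noise ε ~ N(0, σ²). Defaults
λ = 1.0, γ = 0.5, σ = 0.5 give within-DMR probe correlation ≈ 0.83 and
cross-DMR within-module correlation ≈ 0.67 — the regime where array CpGs a
few hundred bases apart correlate strongly and regions in one
co-methylation network correlate clearly but imperfectly. The group
effect δ defaults to 2 M-value units on all DMRs of module 1, mirroring a
disease network shifting as a whole; δ is chosen for test power, as no
effect-size estimates exist to emulate. Each randomness source (layout,
probe offsets, module factors, DMR factors, noise, missingness) draws from
its own stream derived from one seed, so changing the missing rate never
perturbs the signal values — ablations stay comparable.

Named fixtures pin the test conditions: `tiny` (6 DMRs / 2 modules / 12
probes / 20 samples), `blocks` (40 / 4 / ~160 / 60) for module recovery,
and `paper_shape` (610 DMRs, ~3680 CpGs, 60 samples, with two planted
networks of 30 and 25 regions among background) for the real problem size.
Problem sizes in the tests and the acceptance script are those fixtures;
the largest runs the full network stage in well under a minute.

What the generator does *not* emulate: Infinium I/II probe-type effects,
batch effects, cell-composition mixtures, genomic waves, or realistic
bimodal beta distributions near 0/1. Passing tests therefore demonstrate
the correctness of the network and testing machinery on data with the
assumed correlation structure, not robustness to array artefacts.

## Numerical choices

- Correlation uses pairwise-complete observations; pairs sharing fewer
  than `min_overlap = 10` samples are an error by default (or zeroed and
  counted with `on_low_overlap="flag"`). Zero-variance probes get
  correlation 0, not NaN, with a warning counter, so downstream matrices
  stay finite. Matrices are symmetrised and clipped to [−1, 1] after
  computation to absorb floating-point drift.
- TOM and DMR matrices are symmetrised ((X + Xᵀ)/2) and clipped to [0, 1];
  the diagonal is stored as 1 by convention and never thresholded.
- The scale-free fit needs at least two non-empty bins and raises on a
  degenerate (all-equal) connectivity sequence. Two non-empty bins fit
  exactly (R² = 1), which the tests document as the reason `n_bins` must
  exceed 2 for the index to mean anything.
- Hub ranking breaks degree ties lexicographically by gene label, then
  DMR id; edges are stored once in sorted canonical order, so every
  output file is byte-stable and reruns are diffable (verified by checksum
  in the pipeline manifest).
- Heatmap ordering uses average-linkage hierarchical clustering of
  1 − averageTOM of a designated reference dataset; the same leaf order is
  applied to every dataset so heatmaps are row-by-row comparable. Average
  linkage is a convention chosen here; published heatmap orders are
  typically unstated.
- "Network X is observed in dataset Y" is operationalised as the fraction
  of the reference component's nodes that are connected (degree ≥ 1) in
  Y's network, with a reportable default threshold of 0.5 — explicitly a
  convention standing in for a visual judgement.

## Limitations

- The scale-free criterion can qualify pure-noise data at high powers
  (sparse spurious tails fit a line well); β selection is a modelling
  convention, not a test of signal.
- The shrinkage path's F reference is approximate; permutation p-values
  are out of scope.
- Probe-to-region maps must be disjoint; overlapping region definitions
  need to be resolved upstream.
- No IDAT/preprocessing, normalization, probe QC or annotation parsing:
  the package starts from a beta matrix and a region table.
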