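# Methods

This note documents the models and procedures `mbstage` implements, the
defaults and why, the synthetic benchmark's scope, and the numerical
choices made where the design was genuinely open.

## Normalization

Counts are scaled per entity (cell or spot) to a fixed total
(`scale_factor = 10,000`) and log1p-transformed. Entities with zero total
are kept as all-zero rows with a logged warning: the parser and normalizer
never make analytical decisions; quality filtering is a separate, explicit
step. All downstream expression operations (module scores, HVG selection,
PC1 pseudotime, bin profiles, pseudobulk, path smoothing) consume this
`lognorm` layer; pseudobulk accepts any per-cell value layer and logs which
one was used, since batch-corrected values are a common alternative input.

## Spatial niche similarity and temporal alignment

Spots are labeled by the argmax of externally deconvolved cell-type
abundances. Ties are broken by declared type order and flagged; all-zero
spots are labeled `unassigned` and every adjacency edge touching one is
excluded from both the numerator and denominator of the pair profile.
Lattice adjacency connects spots whose center distance is at most
`scale_tolerance` (default 1.05) times the minimum pairwise center
distance; on a regular hexagonal lattice this yields the six standard
neighbors and tolerates small coordinate jitter.

Open choices and how they were fixed (all configurable):

* **Normalization of pair counts**: division by the number of retained
  edges, making the profile a composition — required for comparing samples
  of different sizes (tissue sections vs organoid discs).
* **Diagonal (same-type) pairs are counted**: homotypic niches
  (e.g. a progenitor core) are informative; excluding them would be the
  surprising choice.
* **Distance → similarity**: S = 1 − D/max(D) over the compared set, so
  the most dissimilar pair scores exactly 0 and S is monotone in −D. The
  scaling constant is a property of the compared set, not of a pair.
* **Replicates are averaged at the similarity level** (not the profile
  level) before alignment, treating replicates as repeated measurements of
  one timepoint.

Temporal alignment weights each tissue timepoint by the query's mean
similarity to that timepoint's replicates, normalized to sum one; the
estimate is the weighted mean timepoint, hence always inside the observed
timepoint range. All-zero similarities raise an explicit error rather than
silently returning a uniform average. Because weights never fully
concentrate on one timepoint, estimates compress toward the middle of the
range at extreme mixing weights; the recovery benchmark therefore asserts
monotonicity of the mean estimate over seeds and the midpoint value at
α = 0.5, not endpoint equality.

## Maturation-path trends

A drawn polyline plus an assignment radius is converted to an ordered spot
list by arc length of orthogonal projection (ties: distance to the line,
then spot id). The running average uses a centered window (default 50
spots) truncated at the path ends — truncation, not padding, to avoid
fabricating data at the ends; position *i* averages indices
max(0, i−⌊w/2⌋)…min(n−1, i+⌊w/2⌋). The window mean is unweighted, with the
window parameterization kept as the single smoothing knob; a kernel-weight
hook would slot in at the same place. The trend statistic is the Spearman
correlation of expression with path rank, calibrated by permuting
positions (exhaustive over all n! orderings for n ≤ 7, Monte Carlo with
the +1-corrected estimator otherwise). It is a deliberately transparent
substitute for cell-type-decomposed differential expression along the
path, which requires the deconvolution model itself and is out of scope;
outputs are labeled accordingly.

## Moran's I

Binary neighbor weights without row standardization — the simplest
defensible convention, switchable in config. Significance is a two-sided
permutation test centered at E[I] = −1/(n−1) under random relabeling of
values over spots; n ≤ 7 triggers exhaustive enumeration (p = count/n!,
never 0). Constant fields are an error, not a p-value. The neighbor
ligand–receptor score — ligand(s) × mean receptor over s's neighbors,
isolated spots 0 — is a per-spot signaling proxy whose spatial structure
can be ranked by Moran's I with BH correction across pairs; no equivalence
to optimal-transport signaling inference is claimed.

## Module scores and group comparisons

Activation score = mean lognorm over a module's retained genes (absent
genes dropped with a warning). The group comparison is a two-sided one-way
permutation test with statistic |mean_a − mean_b| (the canonical two-sample
choice; the test family fixes only the calibration, not the statistic),
10,000 label permutations by default and the +1-corrected p, exhaustive
enumeration of all label splits when the pooled size is ≤ 10. Unequal
groups are handled by resampling the larger group without replacement to
the smaller one's size (100 rounds by default) and reporting the mean p
across rounds; equal sizes skip resampling. Benjamini–Hochberg correction
across modules yields the significance tiers (pAdj < 0.001/0.01/0.05).

Calibration, measured here: the permutation p itself is exact/uniform, so
equal-size comparisons reject at the nominal rate; the *mean of p over
resamplings* is conservative under the null (~0.02 at nominal 0.05 in 500
simulations) because resample p-values are positively correlated and their
mean concentrates away from the tail. This conservativeness is inherent to
mean-p reporting; detection claims made with it are, if anything,
understated. Implementation guarantees: results are bit-reproducible given
the seed, and symmetric in which group is called "a" (combined values are
sorted before permutation and the resampled group is always the larger
one, so the random stream is label-invariant).

Per-timepoint summaries report mean ± sd per (dataset, timepoint) group
with Gaussian KDEs (Silverman bandwidth) on one shared evaluation grid;
densities integrate to 1 within 1e−3 (zero-variance groups get a narrow
Gaussian bump, single-cell groups sd = 0 with a warning). The rank-sum
comparison of pseudotime distributions is exact for the smaller sample
≤ 8 without ties, otherwise the normal approximation with tie correction
and no continuity correction (so identical samples give exactly p = 1).

## Lineage, HVG scheme, pseudotime, bin profiles

The cell graph is a union-of-kNN graph (k = 10) on Euclidean distances
with a deterministic tie-break by cell index. Cluster connectivity is
w(A,B) = inter-cluster edges / min(total degree of A, total degree of B),
clipped to [0, 1] — a transparent, oracle-testable abstraction statistic,
monotone in inter-cluster connectivity; it is *not* the PAGA statistic and
no numeric equivalence is claimed. Edges with w < 0.05 are pruned; w =
0.05 is kept (strict inequality). The lineage is the hop-count shortest
path, ties resolved by maximizing the path's minimum edge weight and then
lexicographic cluster ids; a waypoint splits the search into two legs with
duplicate-cluster collapse. Disconnection raises an error naming the
components. Root, endpoint and waypoint are user parameters: cluster
numbering is dataset-specific.

HVG selection ranks genes per replicate by dispersion (variance/mean of
lognorm values) z-scored within 20 gene-mean bins, takes the top n
(default 2000; tie-break by gene id), intersects across the replicates of
each timepoint, and unions across timepoints — so a gene must be
reproducibly variable at some timepoint to enter the final set.

Pseudotime is the first principal component of standardized lognorm over
the HVG set, sign-oriented so the designated root cluster has the minimal
mean score, min–max rescaled to [0, 1]; the adjusted R² of the PC1 score
on cell-type indicators is returned as a sanity check that the axis tracks
the annotated progression. PC1 is a proxy with known failure modes
(curved manifolds can put the leading axis on the "arch"); diffusion-map
pseudotime is out of scope.

Bin profiles trim cells outside the 1st–99th pseudotime percentiles, split
the remaining *range* into five equal-width bins ("evenly spaced" read as
equal width; equal-count binning would be the alternative), and report
per-bin mean expression (empty bins as missing, logged). The start-vs-end
call uses the difference of last- and first-bin mean log expression as a
logFC with a two-sided permutation p over first/last-bin membership,
thresholds p < 0.001 and |logFC| > 2; it replaces GAM-based start-vs-end
testing, and output rows carry the substitute test's name.

## Pseudobulk

Group (dataset × timepoint) mean expression over the HVG set, pairwise
Pearson correlations, constant profiles dropped with a warning.
Average-linkage leaf ordering is provided only as a presentation helper.

## Synthetic data: what it emulates and what it does not

Tissue sections are hexagonal discs (1 + 3r(r+1) spots at ring radius r,
default r = 5) in Visium doubled-column array coordinates. A maturation
coordinate m ∈ [0, 1] runs from a ventricular-zone-like pole to a mature
pole (radially, core → periphery, in organoids). Per-spot type mixtures
are Dirichlet draws (concentration 2 per type, K = 5 types) around
p_k(m) ∝ α_k · exp(s_k · [g·(m−½) + g_t·(t̂−½)]) where s_k ∈ [−1, 1] is
the type's maturity score, g = 3 the spatial gradient strength, g_t = 3
the timepoint shift, and t̂ the timepoint normalized over the reference
range (defaults 7/11/17 PCW). Counts are negative-binomial
(variance = μ + μ²/θ, θ = 2, ~200 genes with gamma base means around 5 and
8× type-marker boosts). Organoids draw mixtures from the Dirichlet
centered at (1−α)·p_A(m) + α·p_B(m) at matched maturation coordinate, so
their expected niche composition interpolates the references exactly and
the implied timepoint is (1−α)·t_A + α·t_B.

Single-cell datasets place cells on a latent pseudotime; cell-type labels
switch discretely (root → intermediate → mature) but marker *expression*
switches smoothly (Gaussian bumps of width 0.3 in pseudotime) — abrupt
marker switches would disconnect the kNN graph at type boundaries and put
PC1 on the horseshoe axis, which no continuous differentiation process
exhibits. Module genes are excluded from the marker pool and carry only
their stated log-scale effect exp(effect·(pt−½)); expected per-cell depth
is held constant so a zero-effect module is null after normalization. A
small residual coupling through realized library size remains (|r| ≈ 0.05
with pseudotime) — exactly as in real count data, where compositional
normalization never fully decouples genes.

Not emulated: sequencing reads, spatial image data, gene–gene covariance
beyond modules and markers, deconvolution error (abundances are the true
mixtures), batch effects, or doublets. Passing the benchmark therefore
shows the *computations* are correct and the procedures recover known
structure under their own assumptions; it does not validate the upstream
deconvolution, nor the biological fidelity of any particular staging.

## Problem sizes and determinism

Every stochastic step flows from one seed. The test suite and
`scripts/acceptance.py` use reduced problem sizes chosen as the package's
own benchmark conditions: grids of radius 3–5 (37–91 spots), 60–120 genes,
600–1000 cells, 199 Monte Carlo permutations where exactness is separately
established by exhaustive enumeration, 10–20 seeds for recovery curves,
and 400–500 simulations for calibration rates. Defaults in the API remain
the full-scale values (2000 HVGs, 10,000 permutations, 100 resamplings,
window 50).

## Known limitations

* The similarity scale S depends on the compared set (max-distance
  normalization); similarities are comparable within one matrix, not
  across analyses.
* Temporal alignment cannot extrapolate beyond the reference timepoint
  range and compresses near its ends.
* The cluster-connectivity statistic and the trend/start-vs-end tests are
  documented substitutes, not re-implementations, of graph-abstraction,
  GAM and deconvolution-decomposed methods.
* Mean-p over resamplings is conservative under the null (measured above).
* PC1 pseudotime assumes the maturation axis dominates variance.
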