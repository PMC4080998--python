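# Methods

## Model and assumptions

The package addresses single-source foodborne-outbreak traceback: given
a product × region matrix of retail sales and the postal-code locations
of reported illness cases, score every product by how well its sales
geography explains the case pattern.

Assumptions, all deliberate simplifications:

* **Consumption equals sale.** Each product's consumption distribution
  f_c(n, ·) is its row-normalized sales vector. People who buy in one
  postal zone and fall ill in another are not modelled (no
  gravity-model smoothing), and case locations carry no noise. A
  consequence used by the likelihood method is hard exclusion: one case
  in a region where a product is never sold drives its likelihood to
  exactly zero.
* **Single contaminated product.** The parameter vector over products
  has exactly one nonzero entry; multi-product or shared-ingredient
  contamination is out of scope.
* **Independent products, independent cases.** Case locations are
  i.i.d. draws from the guilty product's f_c; there is no limit on
  cases per location.
* **Regions are opaque labels.** No geography, distance or adjacency is
  used anywhere.

## Classifiers

**Likelihood.** P_k(m) = Π_i f_c(k, r_i), computed as Σ_i counts(r) ·
log f_c(k, r) with the maximum subtracted before exponentiation.
Likelihood ratios P̂_k = P_k / max_l P_l are therefore exact even at
m = 100, where the raw products underflow double precision (the `raw`
field underflows to 0 in that regime by design; all downstream
statistics use `normalized`). Scores depend on the cases only through
per-region counts. The ML estimate is the argmax; two products within
relative 1e-12 of the maximum are reported as an explicit tie, never
silently broken, and a tie counts as a failure in the success-rate
statistic. If every product is excluded the score vector is flagged
degenerate rather than raising.

**Spearman.** Each product's sales vector is rank-correlated (average
ranks for ties — the shared structural zeros make ties ubiquitous) with
the per-region case-count vector. The correlation vector is mapped onto
[0, 1] by shifting by its minimum and dividing by the shifted maximum,
so the same threshold grid applies to both classifiers. This
normalization is a documented package convention. Products with
constant sales vectors have undefined correlation and score the minimum
attainable (−1) with a warning.

**Suspect set.** Membership uses ≥ at the threshold, so the ML estimate
(ratio exactly 1) is a member at every threshold including t = 1.

## Outbreak simulation

Sampling uses Walker's alias method in Vose's large/small worklist
variant: O(|R|) construction, O(1) per draw, and a reconstruction
invariant (each region's direct-plus-redirected mass equals its weight
to 1e-12) that the tests verify by brute force. Per-(product, run)
seeds are derived as SeedSequence(base_seed, crc32(product_id),
run_index), so the full experiment is reproducible piecewise and safe
to parallelize; all derived seeds stay below 2^31.

## Evaluation harness

Per (guilty product, run), one outbreak of M_max cases is drawn once
and every smaller m reuses its prefix, matching the cumulative
"after observing m case reports" framing and making curves over m
internally consistent.

* Success rate A_{x,m}: fraction of runs where x is the unique argmax.
* TPR(t): fraction of runs with P̂(x) ≥ t. FPR(t): per run,
  FP/(FP + TN) over the non-guilty, non-zero-probability products, then
  averaged over runs (the ratio is averaged, not the pooled counts).
* Zero-probability products are determined operationally per scenario:
  never sold in any location sampled across all S runs × M_max cases,
  not from theoretical supports. When this leaves an empty FP/TN
  universe (e.g. fully disjoint supports), per-run FPR is defined as 0:
  no false positive is possible.
* ROC points are (mean FPR, mean TPR) over the 9-point threshold grid
  {1/256 … 1}, averaged over all scenarios; AUC is the trapezoid rule
  after appending (0,0) and (1,1) anchors and sorting by FPR. The
  integration rule and the averaged-over-all-products convention are
  package choices.
* The null calibration (`randomize_scores`) replaces each stored score
  vector by i.i.d. uniform(0,1) values rescaled to max 1; an
  information-free classifier must land on the diagonal (AUC ≈ 0.5).

## Clustering

Pairwise Spearman ρ between sales rows (computed as Pearson on ranks,
vectorized; constant rows scored 0 against everything with a warning so
the matrix stays valid), complete-linkage agglomeration on D = 1 − ρ
via scipy, and a horizontal cut. Complete linkage gives the guarantee
the analysis relies on: at cut height h every within-cluster
dissimilarity is ≤ h, so h = 0.25 bounds within-cluster ρ ≥ 0.75. The
hard-to-identify relation is summarized by least-squares regression of
per-cluster mean success rate on the natural log of cluster size; with
fewer than two distinct sizes the slope is flagged undefined rather
than computed.

## Synthetic sales generator

Stands in for proprietary retail data while reproducing the structural
features that drive performance:

* **Footprints.** Each product sells in a local (5% of regions),
  regional (20%) or national (100%) footprint, chosen at random or, on
  request, as exactly disjoint blocks.
* **Counts.** Sales are negative-binomial (default dispersion shape 8)
  around a log-normal regional intensity surface (log-sd 1.5, mean
  intensity 100 units/region). Overdispersion is deliberate — retail
  sales are bursty, and rank correlations under Poisson at high means
  behave degenerately. The intensity spread and moderate dispersion
  reflect multi-year aggregated sales, where relative count noise is
  modest compared with between-region heterogeneity.
* **Correlation groups.** Group members share a footprint and mix a
  common latent surface with idiosyncratic noise; the one-dimensional
  mixing weight is bisected (tolerance 0.02, count noise redrawn from a
  fixed seed per iteration so the search is deterministic) against the
  measured pairwise Spearman ρ of the realized rows. Achievable ρ is
  bounded below by the tie floor from shared structural zeros (≈ 0.9
  for a shared footprint covering 20% of regions, ≈ 0 for national
  footprints) and above by a count-noise ceiling (≈ 0.92–0.98);
  calibration warns when a target lies outside this band. The realized
  correlation, not the target, is what downstream analyses measure.
* **All-zero guard.** A row that realizes all zeros (possible at very
  low intensity) gets one sales unit in its first footprint region so
  every product has a valid consumption distribution.

Canonical fixtures (fixed seeds, regenerated on demand): `disjoint`
(5 products, disjoint supports — the perfect-classifier limit),
`identical_pair` (two byte-identical products — the Y-identical limit
in which ties are permanent and the suspect set never falls below Y),
`clustered` (planted blocks of sizes 1/2/4/8 with within-block ρ ≈ 0.9
on independent latent surfaces, realized within-block ρ ≥ 0.89,
cross-block ρ < 0.1), and `paper_like` (60 products over 500 regions,
20 local / 20 regional / 20 national, with embedded correlation groups
of 6 national and 4 regional products at ρ ≈ 0.9 — a scaled-down analog
of a real retail dataset that contains both easy, well-separated
products and hard, highly correlated ones).

What the generator does **not** emulate: real postal-zone geography or
population, spatial autocorrelation of neighbouring zones, seasonal or
weekly sales dynamics, reporting noise or under-reporting. Passing
tests therefore demonstrate the method's behaviour under its own
modelling assumptions, not robustness to their violation.

## Problem sizes and numerics

Simulation studies run at desk scale: 5–60 products, 50–500 regions,
10–50 runs per product, up to 100 cases — sizes at which every
experiment in the test suite completes in seconds while the Monte-Carlo
directions of interest (success rising with m, likelihood beating the
correlation classifier, success falling with log cluster size and the
slope flattening as m grows) are stable across seeds. The experiment
loop is vectorized over products via a cumulative sum of gathered
log-probability columns, so paper-scale inputs (hundreds of products,
thousands of regions) remain tractable.

Tolerances: consumption rows sum to 1 within 1e-12; alias-table mass
reconstruction 1e-12; log-space vs brute-force likelihood agreement
1e-10 relative; tie detection 1e-12 relative. Dendrogram tie-breaks
follow scipy's deterministic ordering; cluster membership at the cut
heights used is insensitive to it.

## Known limitations

* The likelihood method's hard exclusion is brittle under real-world
  travel: one mis-located case report can eliminate the true source.
  Smoothing the sales surface (gravity models) is the natural
  extension and is deliberately not implemented here.
* The Spearman classifier's shift-and-scale normalization makes its
  suspect sets large by construction (scores are relative to the worst
  correlation); comparisons between classifiers should rely on ROC/AUC
  rather than raw suspect-set sizes.
* Correlation-group calibration cannot reach targets below the
  shared-footprint tie floor; fixtures are designed inside the
  achievable band.
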