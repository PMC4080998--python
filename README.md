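# foodtrace

Likelihood-based identification of contaminated food products from
retail sales data and the geographic pattern of illness case reports.

When a foodborne-disease outbreak is detected, investigators must work
out *which* product is contaminated, fast. If a retailer's product ×
region sales matrix is available, the spatial pattern of case reports
itself carries a strong signal: cases cluster where the guilty product
is actually sold. `foodtrace` implements a likelihood method that
exploits this, an outbreak simulator to test it, a rival rank-correlation
classifier, a full ROC/success-rate evaluation harness, and a clustering
analysis that predicts *a priori* which products will be hard to
identify.

## The method

Let `sales(n, r)` be the units of product *n* sold in region *r*.
Normalizing each product's row gives its consumption distribution

    f_c(n, r) = sales(n, r) / Σ_r' sales(n, r'),

under the simplifying assumption that food is consumed where it is
sold. Assuming a single contaminated product, the likelihood that
product *k* generated case reports at locations r_1, …, r_m is

    P_k(m) ∝ Π_{i=1..m} f_c(k, r_i).

Dividing by the largest element gives the likelihood-ratio vector
`P̂(m)`; its maximal element is the maximum-likelihood estimate, and the
products with `P̂_k(m) ≥ t` for a discrimination threshold *t* form the
**suspect product set** — the actionable shortlist for investigators. A
single case in a region where a product is never sold excludes that
product exactly. Scoring is done in log space, so ratios stay exact
even when the raw products underflow at m = 100.

Outbreaks are simulated by drawing case locations from `f_c(x, ·)` of a
chosen guilty product *x* with Walker's alias method. Performance is
measured by the success rate (statistic *A*: the guilty product is the
*unique* argmax; ties count as failures), and by TPR/FPR over the
threshold grid 1/256 … 1, with per-scenario "zero-probability" products
excluded from the specificity denominator. Products whose sales
distributions have high pairwise Spearman ρ are intrinsically hard to
separate; complete-linkage clustering on 1 − ρ with a cut at 0.25
groups products whose pairwise ρ is ≥ 0.75.

## Worked example

```python
import foodtrace as ft

sales = ft.fixture("paper_like")          # 60 products x 500 regions
model = ft.to_consumption_model(sales)
outbreak = ft.generate_outbreak(model, "reg12", m=10, seed=42)

res = ft.SourceAttribution(sales, outbreak.case_locations).fit()
print(res.summary(top=5))
print(sorted(res.suspect_set(1/32).members))
```

```
Source attribution results
method: likelihood   cases: 10
estimate: reg12

product_id         raw  normalized     method  m_cases
     reg12 6.75641e-16           1 likelihood       10
     nat00  1.0775e-27 1.59478e-12 likelihood       10
     nat05 1.92287e-28   2.846e-13 likelihood       10
     nat01 1.11378e-28 1.64847e-13 likelihood       10
     nat19 1.04787e-28 1.55093e-13 likelihood       10
['reg12']
```

With only ten case reports the guilty product is eleven orders of
magnitude more likely than its closest competitor, and the suspect set
at threshold 1/32 already contains just the guilty product.

The end-to-end experiment is available from the command line:

```sh
foodtrace reproduce --seed 1 --out results/ --runs 20
```

which writes `performance.csv` (success rate, AUC, suspect-set size for
both classifiers at m = 1 … 50; e.g. the likelihood method's average
success rate rises from 0.45 at m = 1 to 0.99 at m = 50, the mean
suspect-set size at t = 1/32 falls to 1.04) and `cluster_slopes.csv`
(regression of per-cluster success on log cluster size: −0.22 at
m = 10, −0.03 at m = 50). The other subcommands — `synth`, `simulate`,
`infer`, `evaluate`, `cluster` — expose each pipeline stage separately.

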