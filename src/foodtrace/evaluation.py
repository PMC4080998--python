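"""Simulation harness and performance statistics.

The experiment simulates, for every candidate guilty product x and every
run s, one outbreak of M_max cases, then scores all N products on the
first m cases for each requested m (cumulative prefixes of one outbreak,
so curves over m are internally consistent).  From the stored normalized
score vectors it derives the performance statistics:

* success rate (statistic A): fraction of runs in which the guilty
  product is the *unique* maximum-score product -- ties count as
  failures;
* TPR / FPR over a threshold grid, with the per-scenario
  "zero-probability" products (never sold in any sampled location across
  all runs and cases of that scenario) excluded from the FP/TN universe
  so specificity is not artificially inflated;
* ROC curves and trapezoidal AUC over the grid with (0,0)/(1,1) anchors;
* suspect-set size and containment summaries.

FPR is averaged Eq.-style: per-run FP/(FP+TN), then the mean over runs.
When the FP/TN universe for a scenario is empty (every other product
structurally excluded, e.g. fully disjoint supports) the per-run FPR is
defined as 0: no false positive is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from foodtrace.inference import (
    TIE_RTOL,
    _likelihood_from_log,
    _spearman_normalize,
    _spearman_raw,
)
from foodtrace.sales import ConsumptionModel, SalesMatrix
from foodtrace.simulate import _sample_indices, build_alias_table, derive_seed

#: Discrimination-threshold grid used for the ROC analysis.
THRESHOLD_GRID = (1 / 256, 1 / 128, 1 / 64, 1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0)


@dataclass
class ExperimentConfig:
    """Parameters of one simulation experiment.

    ``m_values`` selects the case counts at which score vectors are
    stored (all are prefixes of one M_max-case outbreak per run);
    defaults to every m from 1 to M_max.
    """

    s_runs: int = 100
    m_max: int = 100
    m_values: tuple[int, ...] | None = None
    thresholds: tuple[float, ...] = THRESHOLD_GRID
    method: str = "likelihood"
    base_seed: int = 0
    products: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.s_runs < 1:
            raise ValueError(f"s_runs must be >= 1, got {self.s_runs}")
        if self.m_max < 1:
            raise ValueError(f"m_max must be >= 1, got {self.m_max}")
        if self.m_values is None:
            self.m_values = tuple(range(1, self.m_max + 1))
        self.m_values = tuple(int(m) for m in self.m_values)
        if any(not 1 <= m <= self.m_max for m in self.m_values):
            raise ValueError("m_values must lie in [1, m_max]")
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.method not in ("likelihood", "spearman"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ExperimentResult:
    """Stored normalized score vectors for a full experiment.

    ``scores[g, s, j, k]`` is the normalized score of product k when
    guilty product ``guilty_ids[g]``, run s, after ``m_values[j]`` cases.
    ``outbreak_locs[g, s]`` holds the M_max sampled region indices, and
    ``zero_prob[g, k]`` flags the scenario's zero-probability products.
    """

    config: ExperimentConfig
    product_ids: list[str]
    region_ids: list[str]
    guilty_ids: list[str]
    scores: np.ndarray
    outbreak_locs: np.ndarray
    zero_prob: np.ndarray
    _pindex: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pindex = {p: i for i, p in enumerate(self.product_ids)}
        self._gindex = {p: i for i, p in enumerate(self.guilty_ids)}
        self._mindex = {m: j for j, m in enumerate(self.config.m_values)}

    def _g(self, x: str) -> int:
        try:
            return self._gindex[x]
        except KeyError:
            raise KeyError(f"product {x!r} is not a scenario of this experiment") from None

    def _m(self, m: int) -> int:
        try:
            return self._mindex[m]
        except KeyError:
            raise KeyError(f"case count m={m} was not evaluated") from None


def run_experiment(model: ConsumptionModel, sales: SalesMatrix | None,
                   config: ExperimentConfig) -> ExperimentResult:
    """Run the full (guilty product x run x case count) experiment.

    Deterministic given ``config.base_seed``: each (product, run) pair
    draws from its own derived seed, so scenarios are independent and
    the experiment is reproducible piecewise.
    """
    if config.method == "spearman":
        if sales is None:
            raise ValueError("the spearman method requires the sales matrix")
        from scipy.stats import rankdata
        sales_ranks = rankdata(sales.values, axis=1)
    guilty_ids = list(config.products) if config.products else list(model.product_ids)
    n, r = model.n_products, model.n_regions
    g, s_runs = len(guilty_ids), config.s_runs
    m_values = config.m_values
    scores = np.zeros((g, s_runs, len(m_values), n))
    locs = np.zeros((g, s_runs, config.m_max), dtype=np.intp)
    zero_prob = np.zeros((g, n), dtype=bool)
    L = model.log_probs
    for gi, x in enumerate(guilty_ids):
        xi = model.product_index(x)
        table = build_alias_table(model.probs[xi], model.region_ids)
        for s in range(s_runs):
            run_seed = derive_seed(config.base_seed, x, s)
            rng = np.random.default_rng(run_seed)
            idx = _sample_indices(table, config.m_max, rng)
            locs[gi, s] = idx
            if config.method == "likelihood":
                cum = np.cumsum(L[:, idx], axis=1)
                for j, m in enumerate(m_values):
                    _, normalized, _ = _likelihood_from_log(cum[:, m - 1])
                    scores[gi, s, j] = normalized
            else:
                for j, m in enumerate(m_values):
                    counts = np.bincount(idx[:m], minlength=r).astype(float)
                    raw = _spearman_raw(sales_ranks, counts)
                    normalized, _ = _spearman_normalize(raw)
                    scores[gi, s, j] = normalized
        sampled = np.unique(locs[gi])
        zero_prob[gi] = model.probs[:, sampled].max(axis=1) == 0
    return ExperimentResult(config, list(model.product_ids),
                            list(model.region_ids), guilty_ids,
                            scores, locs, zero_prob)


def _unique_hit(vectors: np.ndarray, guilty_idx: int) -> np.ndarray:
    """Per-run indicator that guilty is the unique maximum (ties fail)."""
    top = vectors.max(axis=-1)
    tied = (vectors >= top[..., None] * (1.0 - TIE_RTOL)).sum(axis=-1)
    hit = (vectors[..., guilty_idx] >= top * (1.0 - TIE_RTOL)) & (tied == 1) & (top > 0)
    return hit


def success_rate(result: ExperimentResult, x: str | None, m: int) -> float:
    """Statistic A: fraction of runs where guilty is the unique argmax.

    With ``x=None`` the rate is additionally averaged over all guilty
    products of the experiment.
    """
    j = result._m(m)
    if x is not None:
        gi = result._g(x)
        return float(_unique_hit(result.scores[gi, :, j, :],
                                 result._pindex[x]).mean())
    rates = [success_rate(result, xx, m) for xx in result.guilty_ids]
    return float(np.mean(rates))


def tpr(result: ExperimentResult, x: str, m: int, t: float) -> float:
    """Average true-positive rate: P(guilty's score >= t) over runs."""
    if not 0 < t <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    gi, j = result._g(x), result._m(m)
    return float((result.scores[gi, :, j, result._pindex[x]] >= t).mean())


def fpr(result: ExperimentResult, x: str, m: int, t: float) -> float:
    """Average false-positive rate with zero-probability exclusion.

    Per run, FP counts non-guilty, non-zero-probability products at or
    above the threshold and TN those below; the run's rate FP/(FP+TN)
    is then averaged over runs (0 when the universe is empty).
    """
    if not 0 < t <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    gi, j = result._g(x), result._m(m)
    mask = ~result.zero_prob[gi]
    mask[result._pindex[x]] = False
    universe = int(mask.sum())
    if universe == 0:
        return 0.0
    fp = (result.scores[gi, :, j, :][:, mask] >= t).sum(axis=1)
    return float((fp / universe).mean())


@dataclass
class ROCCurve:
    """ROC points over the threshold grid plus trapezoidal AUC."""

    thresholds: tuple[float, ...]
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    m_cases: int
    method: str


def _trapezoid_auc(fpr_pts: np.ndarray, tpr_pts: np.ndarray) -> float:
    x = np.concatenate([[0.0], fpr_pts, [1.0]])
    y = np.concatenate([[0.0], tpr_pts, [1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def roc_curve(result: ExperimentResult, m: int,
              thresholds: tuple[float, ...] | None = None,
              x: str | None = None) -> ROCCurve:
    """ROC over the threshold grid, averaged over guilty products.

    Each point is (mean FPR(t), mean TPR(t)) over scenarios (or the
    single scenario ``x``); AUC integrates the points sorted by FPR with
    (0,0) and (1,1) anchors appended.
    """
    ts = tuple(sorted(thresholds if thresholds is not None else result.config.thresholds))
    products = [x] if x is not None else result.guilty_ids
    tprs = np.array([[tpr(result, xx, m, t) for xx in products] for t in ts])
    fprs = np.array([[fpr(result, xx, m, t) for xx in products] for t in ts])
    mean_tpr, mean_fpr = tprs.mean(axis=1), fprs.mean(axis=1)
    return ROCCurve(ts, mean_tpr, mean_fpr,
                    _trapezoid_auc(mean_fpr, mean_tpr),
                    m, result.config.method)


@dataclass
class SuspectSetStats:
    mean_size: float
    containment: float
    m_cases: int
    threshold: float


def suspect_set_size_stats(result: ExperimentResult, m: int, t: float) -> SuspectSetStats:
    """Mean suspect-set size and guilty-containment probability.

    The mean is over all (guilty product, run) pairs; containment is the
    fraction of pairs whose suspect set contains the guilty product.
    """
    if not 0 < t <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    j = result._m(m)
    vectors = result.scores[:, :, j, :]
    sizes = (vectors >= t).sum(axis=-1)
    guilty_idx = np.array([result._pindex[x] for x in result.guilty_ids])
    contained = vectors[np.arange(len(result.guilty_ids)), :, guilty_idx] >= t
    return SuspectSetStats(float(sizes.mean()), float(contained.mean()), m, t)


def zero_probability_products(result: ExperimentResult, x: str) -> set[str]:
    """Products never sold in any sampled location of scenario ``x``.

    Computed from the realized samples over all runs and all M_max
    cases, not from theoretical supports.
    """
    gi = result._g(x)
    return {result.product_ids[i] for i in np.flatnonzero(result.zero_prob[gi])}


def randomize_scores(result: ExperimentResult, seed: int) -> ExperimentResult:
    """Null harness: scores drawn independently of the truth.

    Every stored score vector is replaced by i.i.d. uniform(0, 1) values
    rescaled to maximum 1, keeping the outbreaks and zero-probability
    bookkeeping intact.  A classifier with these scores carries no
    information, so its ROC should hug the diagonal (AUC near 0.5);
    used to calibrate the evaluation harness.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(result.scores.shape)
    u /= u.max(axis=-1, keepdims=True)
    return replace(result, scores=u)
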