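"""Scoring products against an observed case-report pattern.

Two classifiers are implemented.

*Likelihood method.*  Under the single-contaminant assumption, the
likelihood that product k generated case reports at locations
r_1, ..., r_m is proportional to  P_k(m) = prod_i f_c(k, r_i).  Dividing
every element of P(m) by its maximum gives the likelihood-ratio vector:
the maximal product scores exactly 1 and is the maximum-likelihood
estimate of the contaminated product.  A single case in a region where a
product is never sold forces its likelihood to exactly zero.  Products
are computed in log space with max-subtraction, so the ratios stay exact
even when the raw products underflow at m = 100.

*Spearman method.*  The rival classifier correlates each product's sales
vector with the per-region case-count vector using Spearman's rank
correlation (average ranks for ties), then maps the correlation vector
onto [0, 1] by shifting by its minimum and dividing by the shifted
maximum, so both classifiers share one threshold grid.

The :class:`SourceAttribution` model wraps both behind a fit() /
results / summary() interface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from foodtrace.sales import ConsumptionModel, SalesMatrix, to_consumption_model

logger = logging.getLogger(__name__)

#: Relative tolerance within which two top scores count as tied.
TIE_RTOL = 1e-12


@dataclass
class ScoreVector:
    """One score per product for a single case-report set.

    ``raw`` is the likelihood P_k(m) (up to a common scale) or the
    Spearman correlation; ``normalized`` is in [0, 1] with max exactly 1
    unless the vector is degenerate (every product excluded, or all
    correlations equal).
    """

    product_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    method: str
    m_cases: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "product_id": self.product_ids,
            "raw": self.raw,
            "normalized": self.normalized,
            "method": self.method,
            "m_cases": self.m_cases,
        })


@dataclass
class MLEstimate:
    """Maximum-score product(s); more than one means an unresolved tie."""

    products: tuple[str, ...]
    degenerate: bool = False

    @property
    def is_tie(self) -> bool:
        return len(self.products) > 1

    @property
    def product(self) -> str | None:
        """The unique estimate, or None on a tie or degenerate vector."""
        if self.degenerate or self.is_tie:
            return None
        return self.products[0]


@dataclass
class SuspectSet:
    """Products whose normalized score meets or exceeds a threshold."""

    threshold: float
    members: frozenset[str]
    m_cases: int

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, product: str) -> bool:
        return product in self.members


def _case_indices(region_ids_index, cases: list[str]) -> np.ndarray:
    idx = []
    for r in cases:
        try:
            idx.append(region_ids_index[r])
        except KeyError:
            raise KeyError(f"unknown region id in case reports: {r!r}") from None
    return np.asarray(idx, dtype=np.intp)


def _likelihood_from_log(loglik: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Map per-product log-likelihoods to (raw, normalized, degenerate)."""
    top = loglik.max()
    if np.isneginf(top):
        n = loglik.shape[0]
        return np.zeros(n), np.zeros(n), True
    with np.errstate(under="ignore"):
        normalized = np.exp(loglik - top)
        raw = np.exp(loglik)  # may underflow to 0 at large m; ratios stay exact
    normalized[np.isneginf(loglik)] = 0.0
    return raw, normalized, False


def likelihood_scores(model: ConsumptionModel, cases: list[str]) -> ScoreVector:
    """Likelihood-ratio score of every product for the observed cases.

    ``raw`` is the probability product itself (it underflows to 0 for
    large m; ``normalized`` is computed in log space and stays exact).
    Scores depend on the cases only through per-region counts.  If every
    product is structurally excluded the result is flagged degenerate
    instead of raising.
    """
    if not cases:
        raise ValueError("case list is empty")
    idx = _case_indices(model._region_index, cases)
    counts = np.bincount(idx, minlength=model.n_regions).astype(float)
    L = model.log_probs
    sampled = counts > 0
    Ls = L[:, sampled]
    excluded = np.isneginf(Ls).any(axis=1)
    loglik = np.where(np.isneginf(Ls), 0.0, Ls) @ counts[sampled]
    loglik[excluded] = -np.inf
    raw, normalized, degenerate = _likelihood_from_log(loglik)
    if degenerate:
        logger.warning("all %d products excluded by the observed cases", model.n_products)
    return ScoreVector(list(model.product_ids), raw, normalized,
                       "likelihood", len(cases), degenerate)


def _spearman_raw(sales_ranks: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho of pre-ranked sales against a count vector."""
    cr = stats.rankdata(counts)
    a = sales_ranks - sales_ranks.mean(axis=1, keepdims=True)
    b = cr - cr.mean()
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum())
    rho = np.full(sales_ranks.shape[0], -1.0)
    if (b * b).sum() == 0:
        # constant count vector: correlation undefined against everything
        return rho
    ok = denom > 0
    rho[ok] = (a[ok] @ b) / denom[ok]
    return rho


def _spearman_normalize(rho: np.ndarray) -> tuple[np.ndarray, bool]:
    shifted = rho - rho.min()
    top = shifted.max()
    if top == 0:
        return np.zeros_like(rho), True
    return shifted / top, False


def spearman_scores(sales: SalesMatrix, cases: list[str]) -> ScoreVector:
    """Rank-correlation score of every product for the observed cases.

    The outbreak vector holds, per region, the number of cases drawn
    there.  Products with constant sales vectors (undefined correlation)
    score the minimum attainable rho of -1, with a warning.
    """
    if not cases:
        raise ValueError("case list is empty")
    idx = _case_indices(sales._region_index, cases)
    counts = np.bincount(idx, minlength=sales.n_regions).astype(float)
    sales_ranks = stats.rankdata(sales.values, axis=1)
    constant = np.all(sales.values == sales.values[:, :1], axis=1)
    if constant.any():
        warnings.warn(
            "constant sales vector(s), correlation undefined, scored as -1: "
            f"{[sales.product_ids[i] for i in np.flatnonzero(constant)]}",
            stacklevel=2,
        )
    raw = _spearman_raw(sales_ranks, counts)
    normalized, degenerate = _spearman_normalize(raw)
    return ScoreVector(list(sales.product_ids), raw, normalized,
                       "spearman", len(cases), degenerate)


def score(model: ConsumptionModel | None, sales: SalesMatrix | None,
          cases: list[str], method: str) -> ScoreVector:
    """Uniform dispatch over the two classifiers."""
    if method == "likelihood":
        if model is None:
            model = to_consumption_model(sales)
        return likelihood_scores(model, cases)
    if method == "spearman":
        if sales is None:
            raise ValueError("the spearman method requires the sales matrix")
        return spearman_scores(sales, cases)
    raise ValueError(f"unknown method {method!r}; expected 'likelihood' or 'spearman'")


def ml_estimate(scores: ScoreVector) -> MLEstimate:
    """Argmax product, with explicit tie and degenerate markers.

    Identically distributed products always tie: their likelihoods are
    equal for every outbreak, so no amount of data separates them and a
    tie is reported rather than silently broken.
    """
    if scores.degenerate:
        return MLEstimate(tuple(), degenerate=True)
    top = scores.normalized.max()
    tied = np.flatnonzero(scores.normalized >= top * (1.0 - TIE_RTOL))
    return MLEstimate(tuple(scores.product_ids[i] for i in tied))


def suspect_set(scores: ScoreVector, threshold: float) -> SuspectSet:
    """Products whose normalized score is >= threshold.

    Membership uses >= so the maximum-likelihood estimate (score exactly
    1) is always a member, even at threshold 1.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    members = frozenset(
        scores.product_ids[i]
        for i in np.flatnonzero(scores.normalized >= threshold)
    )
    return SuspectSet(threshold, members, scores.m_cases)


class SourceAttribution:
    """Source-attribution model for one observed case-report set.

    Parameters
    ----------
    sales
        Product x region sales matrix.
    cases
        Observed case-report locations (region ids, repeats allowed).
    method
        'likelihood' (default) or 'spearman'.

    Examples
    --------
    >>> model = SourceAttribution(sales, ["10115", "10115", "80331"])
    >>> res = model.fit()
    >>> res.ml_estimate.product
    'product_7'
    >>> len(res.suspect_set(1 / 32))
    3
    """

    def __init__(self, sales: SalesMatrix, cases: list[str],
                 method: str = "likelihood"):
        if method not in ("likelihood", "spearman"):
            raise ValueError(f"unknown method {method!r}")
        self.sales = sales
        self.consumption = to_consumption_model(sales)
        self.cases = list(cases)
        self.method = method

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, cases: list[str],
                       method: str = "likelihood") -> "SourceAttribution":
        """Build from a products x regions DataFrame of sales."""
        return cls(SalesMatrix.from_frame(frame), cases, method=method)

    def fit(self) -> "SourceAttributionResults":
        sv = score(self.consumption, self.sales, self.cases, self.method)
        return SourceAttributionResults(self, sv)


@dataclass
class SourceAttributionResults:
    """Fitted scores plus the estimates derived from them."""

    model: SourceAttribution
    scores: ScoreVector
    _ml: MLEstimate = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._ml = ml_estimate(self.scores)

    @property
    def ml_estimate(self) -> MLEstimate:
        return self._ml

    def suspect_set(self, threshold: float) -> SuspectSet:
        return suspect_set(self.scores, threshold)

    def to_frame(self) -> pd.DataFrame:
        """Scores as a DataFrame sorted by decreasing normalized score."""
        return (self.scores.to_frame()
                .sort_values("normalized", ascending=False, kind="stable")
                .reset_index(drop=True))

    def summary(self, top: int = 10) -> str:
        """Plain-text ranking of the top-scoring products."""
        frame = self.to_frame().head(top)
        est = self._ml
        if est.degenerate:
            headline = "estimate: degenerate (all products excluded)"
        elif est.is_tie:
            headline = f"estimate: tied between {', '.join(est.products)}"
        else:
            headline = f"estimate: {est.product}"
        lines = [
            "Source attribution results",
            f"method: {self.scores.method}   cases: {self.scores.m_cases}",
            headline,
            "",
            frame.to_string(index=False,
                            float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)
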