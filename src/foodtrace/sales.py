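"""Sales matrices and per-product consumption distributions.

The raw input is a matrix of non-negative sales quantities, one row per
food product and one column per postal-code region, aggregated over the
study window.  Normalizing each row to sum to one turns it into the
product's *consumption distribution* f_c(n, .) -- the probability that a
unit of product ``n`` is consumed in region ``r`` -- under the modelling
assumption that food is consumed where it is sold.

Region identifiers are opaque strings: the method uses only the identity
of regions, never their geography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-12


class SalesValidationError(ValueError):
    """Raised when a sales matrix violates its structural invariants."""


@dataclass
class SalesMatrix:
    """Non-negative sales quantities per (product, region).

    Parameters
    ----------
    product_ids
        Unique opaque product identifiers, one per row.
    region_ids
        Unique opaque postal-zone identifiers, one per column.
    values
        Array of shape ``(n_products, n_regions)`` with sales >= 0.
        Every product must have at least one strictly positive entry.
    """

    product_ids: list[str]
    region_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.product_ids = [str(p) for p in self.product_ids]
        self.region_ids = [str(r) for r in self.region_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SalesValidationError("values must be a 2-D array")
        n, r = self.values.shape
        if n != len(self.product_ids) or r != len(self.region_ids):
            raise SalesValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.product_ids)} products x {len(self.region_ids)} regions"
            )
        if len(set(self.product_ids)) != n:
            dupes = sorted({p for p in self.product_ids if self.product_ids.count(p) > 1})
            raise SalesValidationError(f"duplicate product ids: {dupes}")
        if len(set(self.region_ids)) != r:
            dupes = sorted({z for z in self.region_ids if self.region_ids.count(z) > 1})
            raise SalesValidationError(f"duplicate region ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise SalesValidationError("non-finite sales values")
        if np.any(self.values < 0):
            bad = [self.product_ids[i] for i in np.unique(np.argwhere(self.values < 0)[:, 0])]
            raise SalesValidationError(f"negative sales for products: {bad}")
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            bad = [self.product_ids[i] for i in zero_rows]
            raise SalesValidationError(
                f"products with all-zero sales rows (consumption distribution "
                f"undefined): {bad}"
            )
        self._product_index = {p: i for i, p in enumerate(self.product_ids)}
        self._region_index = {z: j for j, z in enumerate(self.region_ids)}

    @property
    def n_products(self) -> int:
        return len(self.product_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def product_index(self, product: str) -> int:
        try:
            return self._product_index[product]
        except KeyError:
            raise KeyError(f"unknown product id: {product!r}") from None

    def region_index(self, region: str) -> int:
        try:
            return self._region_index[region]
        except KeyError:
            raise KeyError(f"unknown region id: {region!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.product_ids, columns=self.region_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SalesMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))


@dataclass
class ConsumptionModel:
    """Per-product consumption probability mass functions over regions.

    ``probs[n, r]`` is f_c(n, r): each row sums to one, and a cell is
    positive exactly where the underlying sales cell is positive.
    """

    product_ids: list[str]
    region_ids: list[str]
    probs: np.ndarray
    _log_probs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        row_sums = self.probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise SalesValidationError("consumption rows must sum to 1")
        self._product_index = {p: i for i, p in enumerate(self.product_ids)}
        self._region_index = {z: j for j, z in enumerate(self.region_ids)}

    @property
    def n_products(self) -> int:
        return len(self.product_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def product_index(self, product: str) -> int:
        try:
            return self._product_index[product]
        except KeyError:
            raise KeyError(f"unknown product id: {product!r}") from None

    def region_index(self, region: str) -> int:
        try:
            return self._region_index[region]
        except KeyError:
            raise KeyError(f"unknown region id: {region!r}") from None

    @property
    def log_probs(self) -> np.ndarray:
        """log f_c with -inf at structural zeros; cached."""
        if self._log_probs is None:
            with np.errstate(divide="ignore"):
                self._log_probs = np.log(self.probs)
        return self._log_probs


def load_sales_csv(path, delimiter: str = ",", products_in_rows: bool = True) -> SalesMatrix:
    """Read a sales matrix from CSV.

    Layout: first column product id, remaining columns one per postal
    zone, header row of zone ids.  ``products_in_rows=False`` transposes
    (products in columns).  Absent cells and empty strings are structural
    zeros: sparse retail coverage means most products are simply not sold
    in most zones.
    """
    frame = pd.read_csv(path, index_col=0, sep=delimiter, dtype=str,
                        keep_default_na=False)
    if not products_in_rows:
        frame = frame.T
    raw = np.char.strip(frame.to_numpy(dtype=str))
    raw[raw == ""] = "0"
    try:
        values = raw.astype(float)
    except ValueError:
        # slow path only to localize the offending cell for the diagnostic
        values = None
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    float(raw[i, j])
                except ValueError:
                    raise SalesValidationError(
                        f"malformed numeric cell at product {frame.index[i]!r}, "
                        f"region {frame.columns[j]!r}: {raw[i, j]!r}"
                    ) from None
    matrix = SalesMatrix(list(map(str, frame.index)),
                         list(map(str, frame.columns)), values)
    logger.info("loaded sales matrix: N=%d products, |R|=%d regions",
                matrix.n_products, matrix.n_regions)
    return matrix


def write_sales_csv(sales: SalesMatrix, path, delimiter: str = ",") -> None:
    """Write the matrix in the same layout ``load_sales_csv`` reads."""
    sales.to_frame().to_csv(path, sep=delimiter, index_label="product_id")


def to_consumption_model(sales: SalesMatrix) -> ConsumptionModel:
    """Row-normalize sales into consumption distributions.

    f_c(n, r) = sales(n, r) / sum_r' sales(n, r').  Idempotent on
    already-normalized input, and support-preserving: a region gets
    positive probability iff it has positive sales.
    """
    totals = sales.values.sum(axis=1, keepdims=True)
    return ConsumptionModel(list(sales.product_ids), list(sales.region_ids),
                            sales.values / totals)


def support(model: ConsumptionModel, product: str) -> set[str]:
    """Regions where the product has positive consumption probability."""
    i = model.product_index(product)
    return {model.region_ids[j] for j in np.flatnonzero(model.probs[i] > 0)}
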