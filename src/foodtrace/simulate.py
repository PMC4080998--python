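"""Synthetic outbreak generation by sampling consumption distributions.

An outbreak of a known "guilty" product x is an ordered multiset of M
case-report locations drawn i.i.d. from the product's consumption
distribution f_c(x, .).  Draws use Walker's alias method (Vose's
large/small worklist construction), giving O(|R|) setup and O(1) per
draw.  Case reports carry no timestamps and no spatial noise: the
simplifying assumption that food is consumed where it is sold is built
in, so no case can ever fall outside the guilty product's sales support.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass

import numpy as np

from foodtrace.sales import ConsumptionModel

WEIGHT_SUM_TOL = 1e-9


@dataclass
class AliasTable:
    """Walker alias table over a list of regions.

    Cell ``i`` holds an acceptance probability ``prob[i]`` and a
    redirection index ``alias[i]``; a draw picks a uniform cell and
    accepts it with probability ``prob[i]``, otherwise returns its alias.
    The mass attributable to each region (its own acceptances plus
    redirections from other cells) reconstructs the input weights to
    1e-12.
    """

    region_ids: list[str]
    prob: np.ndarray
    alias: np.ndarray

    def reconstructed_mass(self) -> np.ndarray:
        """Per-region probability implied by the table (oracle check)."""
        n = len(self.region_ids)
        mass = self.prob / n
        np.add.at(mass, self.alias, (1.0 - self.prob) / n)
        return mass


def build_alias_table(weights, region_ids: list[str] | None = None) -> AliasTable:
    """Construct an alias table for a discrete distribution.

    Uses Vose's two-worklist variant: cells are scaled by n and split
    into a "small" (< 1) and "large" (>= 1) list; each small cell is
    topped up by a large one, which donates the excess.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-D vector")
    if np.any(w < 0):
        raise ValueError("negative weight in distribution")
    total = w.sum()
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"weights sum to {total!r}, expected 1 within {WEIGHT_SUM_TOL}")
    if region_ids is None:
        region_ids = [str(i) for i in range(w.size)]
    n = w.size
    scaled = w * n / total
    prob = np.ones(n)
    alias = np.arange(n)
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    while small and large:
        s = small.pop()
        g = large.pop()
        prob[s] = scaled[s]
        alias[s] = g
        scaled[g] = (scaled[g] + scaled[s]) - 1.0
        if scaled[g] < 1.0:
            small.append(g)
        else:
            large.append(g)
    # leftovers are 1 up to rounding
    for i in small + large:
        prob[i] = 1.0
        alias[i] = i
    return AliasTable(list(region_ids), prob, alias)


def _sample_indices(table: AliasTable, m: int, rng: np.random.Generator) -> np.ndarray:
    n = len(table.region_ids)
    cells = rng.integers(0, n, size=m)
    accept = rng.random(m) < table.prob[cells]
    return np.where(accept, cells, table.alias[cells])


def sample_locations(table: AliasTable, m: int, seed: int) -> list[str]:
    """Draw ``m`` i.i.d. region ids; deterministic given (table, m, seed)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    rng = np.random.default_rng(seed)
    idx = _sample_indices(table, m, rng)
    return [table.region_ids[i] for i in idx]


@dataclass
class Outbreak:
    """One simulated outbreak of a known guilty product.

    ``case_locations`` is ordered and may repeat regions: there is no
    constraint on how many cases come from a particular location.
    """

    guilty_product: str
    case_locations: list[str]
    seed: int
    run_index: int = 0

    @property
    def m(self) -> int:
        return len(self.case_locations)


def derive_seed(base_seed: int, product_id: str, run_index: int) -> int:
    """Stable per-(product, run) seed below 2**31.

    Hashing the product id with CRC32 keeps the full experiment
    reproducible and parallelizable without shared RNG state.
    """
    ss = np.random.SeedSequence(
        [int(base_seed) & 0x7FFFFFFF, zlib.crc32(product_id.encode()), int(run_index)]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_outbreak(model: ConsumptionModel, guilty: str, m: int,
                      seed: int, run_index: int = 0) -> Outbreak:
    """Sample an outbreak of ``m`` cases from f_c(guilty, .)."""
    i = model.product_index(guilty)
    table = build_alias_table(model.probs[i], model.region_ids)
    run_seed = derive_seed(seed, guilty, run_index)
    locations = sample_locations(table, m, run_seed)
    return Outbreak(guilty, locations, seed=seed, run_index=run_index)


def case_count_profile(outbreak: Outbreak) -> np.ndarray:
    """Per-region case counts, sorted most- to least-frequent.

    Widely distributed products yield flatter profiles than local ones;
    the counts always sum to M.
    """
    if not outbreak.case_locations:
        raise ValueError("outbreak has no cases")
    _, counts = np.unique(outbreak.case_locations, return_counts=True)
    return np.sort(counts)[::-1]


def write_outbreaks_csv(outbreaks: list[Outbreak], path) -> None:
    """Write outbreaks as rows ``<productID>_<runIndex>, r_1, ..., r_M``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for ob in outbreaks:
            writer.writerow([f"{ob.guilty_product}_{ob.run_index}", *ob.case_locations])


def read_outbreaks_csv(path) -> list[Outbreak]:
    """Read outbreaks written by :func:`write_outbreaks_csv`.

    The product id is the text before the last underscore in the first
    column; the run index is the integer after it.
    """
    outbreaks = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            label = row[0]
            product, _, run = label.rpartition("_")
            if not product:
                raise ValueError(f"malformed outbreak label (no underscore): {label!r}")
            outbreaks.append(Outbreak(product, [c for c in row[1:] if c != ""],
                                      seed=-1, run_index=int(run)))
    return outbreaks
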