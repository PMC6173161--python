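"""Diet composition metrics: utilization matrices, N%/V%/F%, IRI, vacuity,
vertebrate aggregation, and the predator-size/prey-volume regression.

The composite importance of a prey category follows the Pinkas form of the
Index of Relative Importance,

    IRI_i = (N%_i + V%_i) * F%_i,

with N% the category's share of prey counts, V% its share of total prey
volume, and F% the percentage of predator individuals containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DomainError,
    UndefinedCompositionError,
    VocabularyError,
)
from .types import PredatorRecord, TraitTable

BASES = ("count", "volume", "frequency")
F_DENOMINATORS = ("all", "non_empty")

UNIDENTIFIED_LABEL = "Unidentified"


@dataclass
class DietMatrix:
    """Predator-taxon × prey-category utilization matrix.

    ``basis`` records what the cells tally: prey counts, summed volume
    (mm^3), or the number of individuals containing the category.
    """

    data: pd.DataFrame
    basis: str = "count"

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise VocabularyError(f"unknown basis {self.basis!r}; expected one of {BASES}")
        if (self.data.to_numpy() < 0).any():
            raise DomainError("utilization cells must be non-negative")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise VocabularyError("row/column labels must be unique")

    def row(self, taxon: str) -> np.ndarray:
        return self.data.loc[taxon].to_numpy(dtype=float)

    @property
    def categories(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CompositionTable:
    """Per-category N%, V%, F%, IRI for one predator taxon."""

    data: pd.DataFrame  # index: category; columns: N_pct, V_pct, F_pct, IRI
    n_items: int
    n_predators: int

    def __post_init__(self) -> None:
        missing = {"N_pct", "V_pct", "F_pct", "IRI"} - set(self.data.columns)
        if missing:
            raise VocabularyError(f"composition table missing columns {sorted(missing)}")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of transformed prey volume on transformed predator size."""

    slope: float
    intercept: float
    se: float
    pvalue: float
    n: int


def build_diet_matrix(
    records: Sequence[PredatorRecord],
    basis: str = "count",
    include_unidentified: bool = True,
    categories: Sequence[str] | None = None,
) -> DietMatrix:
    """Tally per-species utilization of prey categories.

    ``categories`` fixes the column set (and order); otherwise columns are
    the sorted union of observed taxa. Empty stomachs contribute all-zero
    rows, which downstream overlap refuses.
    """
    if not records:
        raise UndefinedCompositionError("no predator records")
    if basis not in BASES:
        raise VocabularyError(f"unknown basis {basis!r}; expected one of {BASES}")

    if categories is None:
        cats = sorted({it.taxon for r in records for it in r.stomach})
    else:
        cats = list(categories)
    species = sorted({r.taxon for r in records})
    data = pd.DataFrame(0.0, index=species, columns=cats)

    for r in records:
        seen = set()
        for it in r.stomach:
            if it.taxon not in data.columns:
                continue
            if basis == "count":
                data.loc[r.taxon, it.taxon] += 1
            elif basis == "volume":
                if it.volume_mm3 is None:
                    raise UndefinedCompositionError(
                        f"item of taxon {it.taxon!r} has no volume; impute first"
                    )
                data.loc[r.taxon, it.taxon] += it.volume_mm3
            else:  # frequency
                if it.taxon not in seen:
                    data.loc[r.taxon, it.taxon] += 1
                    seen.add(it.taxon)

    if not include_unidentified and UNIDENTIFIED_LABEL in data.columns:
        data = data.drop(columns=[UNIDENTIFIED_LABEL])
    return DietMatrix(data=data, basis=basis)


def iri(n_pct: float, v_pct: float, f_pct: float) -> float:
    """Index of Relative Importance, (N% + V%) × F%."""
    for name, v in (("n_pct", n_pct), ("v_pct", v_pct), ("f_pct", f_pct)):
        if not 0 <= v <= 100:
            raise DomainError(f"{name}={v} outside [0, 100]")
    return (n_pct + v_pct) * f_pct


def composition_table(
    records: Sequence[PredatorRecord],
    categories: Sequence[str] | None = None,
    f_denominator: str = "all",
) -> CompositionTable:
    """N%, V%, F% and IRI over prey categories for one predator taxon.

    Requires volumes to be present (impute first). F% divides by all
    sampled individuals by default; ``f_denominator="non_empty"`` restricts
    the denominator to individuals with at least one prey item.
    """
    if f_denominator not in F_DENOMINATORS:
        raise VocabularyError(f"unknown f_denominator {f_denominator!r}")
    if not records:
        raise UndefinedCompositionError("no predator records")
    taxa = {r.taxon for r in records}
    if len(taxa) > 1:
        raise VocabularyError(
            f"composition_table expects a single predator taxon, got {sorted(taxa)}"
        )

    items = [it for r in records for it in r.stomach]
    if not items:
        raise UndefinedCompositionError("all stomachs empty; composition undefined")
    for it in items:
        if it.volume_mm3 is None:
            raise UndefinedCompositionError(
                f"item of taxon {it.taxon!r} lacks a volume; impute first"
            )

    cats = list(categories) if categories is not None else sorted({it.taxon for it in items})
    counts = pd.Series(0.0, index=cats)
    vols = pd.Series(0.0, index=cats)
    freq = pd.Series(0.0, index=cats)
    for it in items:
        if it.taxon in counts.index:
            counts[it.taxon] += 1
            vols[it.taxon] += it.volume_mm3
    for r in records:
        for t in {it.taxon for it in r.stomach}:
            if t in freq.index:
                freq[t] += 1

    n_pred = len(records)
    if f_denominator == "non_empty":
        n_pred = sum(1 for r in records if not r.is_empty)

    n_pct = 100.0 * counts / counts.sum()
    v_pct = 100.0 * vols / vols.sum()
    f_pct = 100.0 * freq / n_pred
    iri_col = (n_pct + v_pct) * f_pct
    df = pd.DataFrame({"N_pct": n_pct, "V_pct": v_pct, "F_pct": f_pct, "IRI": iri_col})
    return CompositionTable(data=df, n_items=int(counts.sum()), n_predators=len(records))


def vacuity_index(
    records: Sequence[PredatorRecord],
    season: str | None = None,
    habitat: str | None = None,
) -> float:
    """Proportion of individuals with empty stomachs in the stratum."""
    subset = [
        r
        for r in records
        if (season is None or r.season == season)
        and (habitat is None or r.habitat == habitat)
    ]
    if not subset:
        raise UndefinedCompositionError("no records in requested stratum")
    return sum(r.is_empty for r in subset) / len(subset)


def reconstruct_counts(pct: float, total: int) -> int:
    """Invert a printed percentage to an integer count, ties half-up."""
    if not 0 <= pct <= 100:
        raise DomainError(f"pct={pct} outside [0, 100]")
    if total <= 0:
        raise DomainError("total must be a positive integer")
    return int(math.floor(pct * total / 100.0 + 0.5))


def apportion_counts(pcts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of a percentage vector to integers.

    Guarantees the reconstructed counts sum exactly to ``total`` even when
    per-cell half-up rounding would not; used for fixture matrices where
    the row total is known.
    """
    raw = np.asarray(pcts, dtype=float) * total / 100.0
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if not 0 <= short <= len(raw):
        raise DomainError("percentages inconsistent with the stated total")
    order = np.argsort(-(raw - base), kind="stable")
    out = base.copy()
    out[order[:short]] += 1
    return out


def aggregate_by_class(
    table: CompositionTable,
    class_filter: Iterable[str],
    trait_table: TraitTable,
    reconstruct_n_from_counts: bool = False,
) -> tuple[float, float]:
    """Summed (N%, V%) over categories in the given vertebrate classes.

    With ``reconstruct_n_from_counts`` the N% sum is recomputed from
    integer counts reconstructed off the printed percentages — the route
    that matches published headline numbers, which were computed on raw
    counts rather than summed rounded percentages.
    """
    wanted = set(class_filter)
    mask = [
        trait_table.lookup(cat).vertebrate_class in wanted for cat in table.data.index
    ]
    n_sum = float(table.data.loc[mask, "N_pct"].sum())
    v_sum = float(table.data.loc[mask, "V_pct"].sum())
    if reconstruct_n_from_counts:
        counts = [
            reconstruct_counts(p, table.n_items)
            for p in table.data.loc[mask, "N_pct"]
        ]
        n_sum = 100.0 * sum(counts) / table.n_items
    return n_sum, v_sum


def count_nonzero_categories(
    table: CompositionTable, exclude: Iterable[str] = ()
) -> int:
    """Number of categories with N% > 0, minus the excluded labels."""
    excluded = set(exclude)
    return int(
        ((table.data["N_pct"] > 0) & ~table.data.index.isin(excluded)).sum()
    )


def size_prey_regression(
    records: Sequence[PredatorRecord],
) -> dict[str, RegressionResult]:
    """Per-predator-taxon OLS of cube-root prey volume on log SVL.

    One data point per prey item with a volume; the cube-root/log
    transforms stabilise the heavy right tail of prey volumes. Returns a
    result per predator taxon with ≥ 3 usable items.
    """
    by_taxon: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        for it in r.stomach:
            if it.volume_mm3 is not None:
                by_taxon.setdefault(r.taxon, []).append(
                    (math.log(r.svl_mm), it.volume_mm3 ** (1.0 / 3.0))
                )
    out: dict[str, RegressionResult] = {}
    for taxon, pts in by_taxon.items():
        if len(pts) < 3:
            continue
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(x) == 0:
            raise DomainError(
                f"predictor variance is zero for taxon {taxon!r}; fit is singular"
            )
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        out[taxon] = RegressionResult(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            se=float(fit.bse[1]),
            pvalue=float(fit.pvalues[1]),
            n=len(pts),
        )
    return out
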