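"""Prey electivity against pitfall availability, and availability diversity.

Selectivity follows the relativized electivity index of Vanderploeg &
Scavia: with consumption proportions r_i and availability proportions p_i
over n included groups, the selectivity coefficients are

    W_i = (r_i / p_i) / sum_j (r_j / p_j),        sum_i W_i = 1,

and the relativized electivity is

    E*_i = (W_i - 1/n) / (W_i + 1/n)  in [-1, 1],

with 0 neutral, +1 exclusive selection and -1 complete avoidance.
Availability diversity uses Simpson's index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DomainError,
    UndefinedElectivityError,
)
from .types import AvailabilitySample, PredatorRecord, TraitTable
from .volumetrics import ellipsoid_volume

GROUPINGS = ("taxon", "size_bin", "trait")
SIMPSON_VARIANTS = ("complement", "finite_sample")

#: default electivity sample-size cut-offs per predator taxon
DEFAULT_MIN_ITEMS = {"H_tigerinus": 10, "Limnonectes": 10, "Fejervarya": 5}


@dataclass(frozen=True)
class SizeBins:
    """Ordered prey-volume bin edges (mm^3) with open outer bins.

    Edges (10, 100, 500) give bins (0,10], (10,100], (100,500], (500,inf);
    the defaults bracket the size anchors small (<10 mm^3), medium and
    large (>=100 mm^3) prey.
    """

    edges: tuple[float, ...] = (10.0, 100.0, 500.0)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edges) or list(self.edges) != sorted(set(self.edges)):
            raise ConfigError("bin edges must be positive and strictly increasing")

    @property
    def labels(self) -> list[str]:
        lo = ["(0"] + [f"({e:g}" for e in self.edges]
        hi = [f"{e:g}]" for e in self.edges] + ["inf)"]
        return [f"{a}, {b}" for a, b in zip(lo, hi)]

    def assign(self, volume_mm3: float) -> str:
        if not volume_mm3 > 0:
            raise DomainError("volume must be positive")
        idx = int(np.searchsorted(np.asarray(self.edges), volume_mm3, side="left"))
        return self.labels[idx]


def _item_group(item, grouping: str, bins: SizeBins, trait_axis: str | None) -> str:
    if grouping == "taxon":
        return item.taxon
    if grouping == "size_bin":
        vol = item.volume_mm3
        if vol is None and item.length_mm is not None and item.width_mm is not None:
            vol = ellipsoid_volume(item.length_mm, item.width_mm)
        if vol is None:
            raise UndefinedElectivityError(
                f"item of taxon {item.taxon!r} has no volume for size binning"
            )
        return bins.assign(vol)
    if grouping == "trait":
        if trait_axis not in ("hardness", "motility"):
            raise ConfigError("trait grouping needs trait_axis in {hardness, motility}")
        return getattr(item, trait_axis)
    raise ConfigError(f"unknown grouping {grouping!r}")


def availability_proportions(
    samples: Sequence[AvailabilitySample],
    grouping: str = "taxon",
    site: str | None = None,
    habitat: str | None = None,
    season: str | None = None,
    bins: SizeBins = SizeBins(),
    trait_axis: str | None = None,
) -> pd.Series:
    """Normalized availability proportions over groups in a stratum."""
    if grouping not in GROUPINGS:
        raise ConfigError(f"unknown grouping {grouping!r}")
    items = [
        it
        for s in samples
        if (site is None or s.site == site)
        and (habitat is None or s.habitat == habitat)
        and (season is None or s.season == season)
        for it in s.items
    ]
    if not items:
        raise UndefinedElectivityError("no availability items in requested stratum")
    counts: dict[str, int] = {}
    for it in items:
        g = _item_group(it, grouping, bins, trait_axis)
        counts[g] = counts.get(g, 0) + 1
    ser = pd.Series(counts, dtype=float).sort_index()
    return ser / ser.sum()


def electivity(
    r: pd.Series,
    p: pd.Series,
    n_consumed: pd.Series | None = None,
) -> pd.DataFrame:
    """Relativized electivity for aligned consumption/availability vectors.

    ``r`` and ``p`` must index the same groups; both are renormalized over
    that common set. Raises when a consumed group has zero availability —
    the caller must exclude or pool such groups first.
    """
    r = pd.Series(r, dtype=float)
    p = pd.Series(p, dtype=float)
    if set(r.index) != set(p.index):
        raise UndefinedElectivityError(
            "consumption and availability must cover identical groups"
        )
    p = p.reindex(r.index)
    if (r < 0).any() or (p < 0).any():
        raise DomainError("proportions must be non-negative")
    if r.sum() <= 0 or p.sum() <= 0:
        raise UndefinedElectivityError("zero-sum consumption or availability")
    bad = p[(p == 0) & (r > 0)]
    if len(bad):
        raise UndefinedElectivityError(
            f"groups consumed but unavailable: {sorted(bad.index)}; "
            "exclude them or pool categories before computing electivity"
        )
    keep = p > 0
    r = r[keep] / r[keep].sum()
    p = p[keep] / p[keep].sum()
    n = len(r)
    ratio = r / p
    w = ratio / ratio.sum()
    e_star = (w - 1.0 / n) / (w + 1.0 / n)
    out = pd.DataFrame({"r": r, "p": p, "W": w, "E_star": e_star})
    out["n_consumed"] = (
        n_consumed.reindex(out.index).fillna(0).astype(int)
        if n_consumed is not None
        else pd.NA
    )
    return out


def consumption_counts(
    records: Sequence[PredatorRecord],
    predator_taxon: str,
    grouping: str = "taxon",
    site: str | None = None,
    habitat: str | None = None,
    season: str | None = None,
    bins: SizeBins = SizeBins(),
    trait_axis: str | None = None,
) -> pd.Series:
    """Raw consumed-item counts per group for one predator taxon."""
    counts: dict[str, int] = {}
    for rec in records:
        if rec.taxon != predator_taxon:
            continue
        if site is not None and rec.site != site:
            continue
        if habitat is not None and rec.habitat != habitat:
            continue
        if season is not None and rec.season != season:
            continue
        for it in rec.stomach:
            g = _item_group(it, grouping, bins, trait_axis)
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=float).sort_index()


def apply_sample_filter(
    records: Sequence[PredatorRecord],
    predator_taxon: str,
    threshold: int | None = None,
) -> set[str]:
    """Prey taxa with at least ``threshold`` consumed items.

    Default thresholds are the published cut-offs: 10 items for
    H. tigerinus and Limnonectes, 5 for the smaller Fejervarya sample.
    """
    if threshold is None:
        threshold = DEFAULT_MIN_ITEMS.get(predator_taxon, 10)
    if threshold < 1:
        raise ConfigError("threshold must be >= 1")
    counts = consumption_counts(records, predator_taxon, grouping="taxon")
    return set(counts[counts >= threshold].index)


def electivity_by_taxon(
    records: Sequence[PredatorRecord],
    samples: Sequence[AvailabilitySample],
    predator_taxon: str,
    threshold: int | None = None,
    **stratum,
) -> pd.DataFrame:
    """Taxon-level electivity with the minimum-sample filter applied.

    Consumed taxa absent from the availability sample are dropped (the
    pitfall design cannot estimate their availability) and both vectors
    are renormalized over the retained set.
    """
    kept = apply_sample_filter(records, predator_taxon, threshold)
    r_counts = consumption_counts(records, predator_taxon, grouping="taxon", **stratum)
    r_counts = r_counts[r_counts.index.isin(kept)]
    p = availability_proportions(samples, grouping="taxon", **stratum)
    common = sorted(set(r_counts.index) & set(p.index))
    if not common:
        raise UndefinedElectivityError(
            "no overlap between filtered diet taxa and availability taxa"
        )
    r = r_counts.reindex(common)
    return electivity(r / r.sum(), p.reindex(common), n_consumed=r_counts.reindex(common))


def electivity_by_size(
    records: Sequence[PredatorRecord],
    samples: Sequence[AvailabilitySample],
    predator_taxon: str,
    bins: SizeBins = SizeBins(),
    **stratum,
) -> pd.DataFrame:
    """Size-bin electivity over prey-volume classes."""
    r_counts = consumption_counts(
        records, predator_taxon, grouping="size_bin", bins=bins, **stratum
    )
    p = availability_proportions(samples, grouping="size_bin", bins=bins, **stratum)
    common = [b for b in bins.labels if b in set(r_counts.index) | set(p.index)]
    r = r_counts.reindex(common).fillna(0.0)
    p = p.reindex(common).fillna(0.0)
    keep = p > 0
    r, p = r[keep], p[keep]
    if r.sum() <= 0:
        raise UndefinedElectivityError("no consumed items fall in available size bins")
    return electivity(r / r.sum(), p / p.sum(), n_consumed=r)


def electivity_by_trait(
    records: Sequence[PredatorRecord],
    samples: Sequence[AvailabilitySample],
    trait_axis: str,
    season: str | None = None,
    predator_taxon: str | None = None,
    **stratum,
) -> pd.DataFrame:
    """Electivity over functional-trait levels (hardness or motility).

    Items with an unknown trait level are excluded from both sides; the
    remaining levels are renormalized before applying the index.
    """
    preds = (
        [predator_taxon]
        if predator_taxon is not None
        else sorted({r.taxon for r in records})
    )
    r_counts = pd.Series(dtype=float)
    for pt in preds:
        r_counts = r_counts.add(
            consumption_counts(
                records, pt, grouping="trait", trait_axis=trait_axis,
                season=season, **stratum
            ),
            fill_value=0.0,
        )
    p = availability_proportions(
        samples, grouping="trait", trait_axis=trait_axis, season=season, **stratum
    )
    levels = sorted((set(r_counts.index) | set(p.index)) - {"unknown"})
    r = r_counts.reindex(levels).fillna(0.0)
    pv = p.reindex(levels).fillna(0.0)
    keep = pv > 0
    r, pv = r[keep], pv[keep]
    if r.sum() <= 0:
        raise UndefinedElectivityError("no consumed items with known trait levels")
    return electivity(r / r.sum(), pv / pv.sum(), n_consumed=r)


def simpson_diversity(counts, variant: str = "complement") -> float:
    """Simpson's diversity of an availability count vector, in [0, 1].

    ``complement`` is 1 - sum p_i^2; ``finite_sample`` is the unbiased
    1 - sum n_i (n_i - 1) / (N (N - 1)).
    """
    if variant not in SIMPSON_VARIANTS:
        raise ConfigError(f"unknown Simpson variant {variant!r}")
    n = np.asarray(counts, dtype=float)
    if (n < 0).any():
        raise DomainError("counts must be non-negative")
    total = n.sum()
    if total < 1:
        raise DomainError("need at least one individual")
    if variant == "complement":
        p = n / total
        return float(1.0 - np.sum(p * p))
    if total < 2:
        raise DomainError("finite_sample variant needs at least two individuals")
    return float(1.0 - np.sum(n * (n - 1.0)) / (total * (total - 1.0)))
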