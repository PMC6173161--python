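"""Prey volume estimation and imputation for fragmented prey.

Intact prey volume is modelled as a prolate ellipsoid of the measured
length and width,

    V = (4/3) * pi * (l/2) * (w/2)^2   [mm^3],

the standard geometric approximation in gut-content studies. Fragmented
prey (no usable dimensions) receive the median volume of measurable items
of the same taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from statistics import median
from typing import Sequence

import pandas as pd

from .errors import ConfigError, DomainError, ImputationError
from .types import PreyItem, PredatorRecord, TraitTable

IMPUTATION_SCOPES = ("per-taxon-pooled", "per-taxon-per-predator-species")
FALLBACKS = ("global-median", "error")


@dataclass(frozen=True)
class VolumePolicy:
    """How fragment volumes are imputed.

    ``imputation_scope`` controls whether median donors pool across predator
    species (default) or are taken within each predator species;
    ``fallback`` decides what happens for a taxon with no measurable donor.
    """

    imputation_scope: str = "per-taxon-pooled"
    fallback: str = "global-median"

    def __post_init__(self) -> None:
        if self.imputation_scope not in IMPUTATION_SCOPES:
            raise ConfigError(f"unknown imputation_scope {self.imputation_scope!r}")
        if self.fallback not in FALLBACKS:
            raise ConfigError(f"unknown fallback {self.fallback!r}")


def ellipsoid_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid volume in mm^3 from prey length and width in mm."""
    if not length_mm > 0 or not width_mm > 0:
        raise DomainError(
            f"dimensions must be positive, got l={length_mm}, w={width_mm}"
        )
    return (4.0 / 3.0) * math.pi * (length_mm / 2.0) * (width_mm / 2.0) ** 2


def compute_volume(item: PreyItem) -> PreyItem:
    """Fill ``volume_mm3`` from dimensions when both are present."""
    if item.volume_mm3 is not None:
        return item
    if item.length_mm is not None and item.width_mm is not None:
        return replace(item, volume_mm3=ellipsoid_volume(item.length_mm, item.width_mm),
                       volume_imputed=False)
    return item


def impute_fragment_volumes(
    items: Sequence[PreyItem], policy: VolumePolicy = VolumePolicy()
) -> list[PreyItem]:
    """Return items with every volume filled; fragments get taxon medians.

    Measured items are never altered (idempotent); imputed items are
    flagged via ``volume_imputed``. A taxon with no measurable donor falls
    back to the global median of all measured volumes, or raises if the
    policy says ``fallback="error"``.
    """
    computed = [compute_volume(it) for it in items]
    measured = [it for it in computed if it.volume_mm3 is not None and not it.volume_imputed]
    by_taxon: dict[str, list[float]] = {}
    for it in measured:
        by_taxon.setdefault(it.taxon, []).append(it.volume_mm3)

    global_donors = [it.volume_mm3 for it in measured]
    out = []
    for it in computed:
        if it.volume_mm3 is not None:
            out.append(it)
            continue
        donors = by_taxon.get(it.taxon, [])
        if donors:
            out.append(replace(it, volume_mm3=median(donors), volume_imputed=True))
        elif policy.fallback == "global-median" and global_donors:
            out.append(replace(it, volume_mm3=median(global_donors), volume_imputed=True))
        else:
            raise ImputationError(
                f"no measured volumes available to impute taxon {it.taxon!r}"
            )
    return out


def impute_record_volumes(
    records: Sequence[PredatorRecord], policy: VolumePolicy = VolumePolicy()
) -> tuple[list[PredatorRecord], pd.DataFrame]:
    """Impute volumes across a whole diet dataset.

    With the pooled scope, median donors come from every predator species;
    with the per-species scope each predator taxon is imputed separately.
    Returns the updated records plus an audit frame (individual_id, taxon,
    assigned volume, donor count) describing every imputed item.
    """
    if policy.imputation_scope == "per-taxon-pooled":
        groups = {None: list(records)}
    else:
        groups = {}
        for r in records:
            groups.setdefault(r.taxon, []).append(r)

    new_by_id: dict[str, list[PreyItem]] = {}
    audit_rows = []
    for _, recs in groups.items():
        flat: list[tuple[str, PreyItem]] = [
            (r.individual_id, it) for r in recs for it in r.stomach
        ]
        imputed = impute_fragment_volumes([it for _, it in flat], policy)
        donors: dict[str, int] = {}
        for it in imputed:
            if not it.volume_imputed:
                donors[it.taxon] = donors.get(it.taxon, 0) + 1
        for (ind_id, old), new in zip(flat, imputed):
            new_by_id.setdefault(ind_id, []).append(new)
            if new.volume_imputed and old.volume_mm3 is None:
                audit_rows.append(
                    {
                        "individual_id": ind_id,
                        "taxon": new.taxon,
                        "volume_mm3": new.volume_mm3,
                        "donor_count": donors.get(new.taxon, 0),
                    }
                )

    out_records = [
        replace(r, stomach=new_by_id.get(r.individual_id, []))
        for r in records
    ]
    audit = pd.DataFrame(
        audit_rows, columns=["individual_id", "taxon", "volume_mm3", "donor_count"]
    )
    return out_records, audit


def classify_traits(item: PreyItem, table: TraitTable) -> PreyItem:
    """Populate an item's functional-trait fields from the trait table."""
    return table.apply(item)
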