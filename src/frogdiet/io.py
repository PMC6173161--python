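"""CSV readers and writers for the three long-format schemas.

Diet CSV (one row per prey item; empty stomachs carry one sentinel row with
prey taxon "NONE"):
    individual_id, predator_taxon, svl_mm, hw_mm, ljl_mm, sex, site,
    habitat, season, prey_taxon, prey_life_stage, prey_length_mm,
    prey_width_mm

Availability CSV (one row per trapped item; a trap occasion with no items
may carry a sentinel row):
    site, habitat, season, trap_id, occasion, prey_taxon, prey_length_mm,
    prey_width_mm

Trait CSV:
    taxon, hardness, motility, habitat_origin, vertebrate_class

All files are UTF-8 with a header row. Readers are order-independent:
shuffling input rows yields the same set of records.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .errors import OrphanRowError, SchemaError, VocabularyError
from .types import (
    EMPTY_STOMACH_SENTINEL,
    AvailabilitySample,
    PredatorRecord,
    PreyItem,
    TraitRecord,
    TraitTable,
)

DIET_COLUMNS = [
    "individual_id", "predator_taxon", "svl_mm", "hw_mm", "ljl_mm", "sex",
    "site", "habitat", "season", "prey_taxon", "prey_life_stage",
    "prey_length_mm", "prey_width_mm",
]
AVAILABILITY_COLUMNS = [
    "site", "habitat", "season", "trap_id", "occasion",
    "prey_taxon", "prey_length_mm", "prey_width_mm",
]
TRAIT_COLUMNS = ["taxon", "hardness", "motility", "habitat_origin", "vertebrate_class"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing columns {missing}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _fmt(value) -> str:
    # repr of a float is its shortest exact form: lossless round-trips
    return "" if value is None else repr(float(value))


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TRAIT_COLUMNS, "trait")
    mapping = {}
    for i, row in df.iterrows():
        mapping[row["taxon"]] = TraitRecord(
            row["hardness"], row["motility"],
            row["habitat_origin"], row["vertebrate_class"],
        )
    return TraitTable(mapping)


def read_diet_records(path, trait_table: TraitTable | None = None) -> list[PredatorRecord]:
    """Parse a diet CSV into predator records with traits joined.

    Each predator appears exactly once; its prey rows are grouped under it.
    Conflicting morphometrics for one individual_id raise a schema error,
    and a prey row whose predator fields are blank is an orphan.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str},
                     float_precision="round_trip")
    _require_columns(df, DIET_COLUMNS, "diet")

    records: dict[str, PredatorRecord] = {}
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        ind = row["individual_id"]
        if not isinstance(ind, str) or ind.strip() == "" or pd.isna(row["predator_taxon"]):
            raise OrphanRowError(f"row {rownum}: prey row lacks predator identity")
        try:
            rec = PredatorRecord(
                individual_id=ind,
                taxon=str(row["predator_taxon"]),
                svl_mm=float(row["svl_mm"]),
                hw_mm=_opt_float(row["hw_mm"]),
                ljl_mm=_opt_float(row["ljl_mm"]),
                sex=str(row["sex"]) if pd.notna(row["sex"]) else "unknown",
                site=str(row["site"]),
                habitat=str(row["habitat"]),
                season=str(row["season"]),
            )
        except VocabularyError as err:
            raise VocabularyError(f"row {rownum}: {err}") from None
        prev = records.get(ind)
        if prev is None:
            records[ind] = rec
            prev = rec
        else:
            same = (
                prev.taxon == rec.taxon
                and prev.svl_mm == rec.svl_mm
                and prev.hw_mm == rec.hw_mm
                and prev.ljl_mm == rec.ljl_mm
                and prev.site == rec.site
                and prev.habitat == rec.habitat
                and prev.season == rec.season
            )
            if not same:
                raise SchemaError(
                    f"row {rownum}: individual_id {ind!r} repeated with "
                    "conflicting predator fields"
                )
        prey_taxon = row["prey_taxon"]
        if pd.isna(prey_taxon) or prey_taxon == EMPTY_STOMACH_SENTINEL:
            continue
        stage = row["prey_life_stage"]
        try:
            item = PreyItem(
                taxon=str(prey_taxon),
                life_stage=str(stage) if pd.notna(stage) else "unknown",
                length_mm=_opt_float(row["prey_length_mm"]),
                width_mm=_opt_float(row["prey_width_mm"]),
            )
        except VocabularyError as err:
            raise VocabularyError(f"row {rownum}: {err}") from None
        if trait_table is not None:
            item = trait_table.apply(item)
        prev.stomach.append(item)

    out = list(records.values())
    out.sort(key=lambda r: r.individual_id)
    for r in out:
        r.stomach.sort(key=lambda it: (it.taxon, it.length_mm or 0.0, it.width_mm or 0.0))
    return out


def write_diet_records(records: Sequence[PredatorRecord], path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.individual_id):
        base = {
            "individual_id": r.individual_id,
            "predator_taxon": r.taxon,
            "svl_mm": _fmt(r.svl_mm),
            "hw_mm": _fmt(r.hw_mm),
            "ljl_mm": _fmt(r.ljl_mm),
            "sex": r.sex,
            "site": r.site,
            "habitat": r.habitat,
            "season": r.season,
        }
        if not r.stomach:
            rows.append({**base, "prey_taxon": EMPTY_STOMACH_SENTINEL,
                         "prey_life_stage": "", "prey_length_mm": "", "prey_width_mm": ""})
        for it in r.stomach:
            rows.append({
                **base,
                "prey_taxon": it.taxon,
                "prey_life_stage": it.life_stage,
                "prey_length_mm": _fmt(it.length_mm),
                "prey_width_mm": _fmt(it.width_mm),
            })
    pd.DataFrame(rows, columns=DIET_COLUMNS).to_csv(path, index=False)


def read_availability(path, trait_table: TraitTable) -> list[AvailabilitySample]:
    """Parse an availability CSV into per-trap-occasion samples.

    Availability estimation covers crawling terrestrial invertebrates
    only, so rows whose taxon maps to a vertebrate class or to a volant
    origin are rejected.
    """
    df = pd.read_csv(path, dtype={"trap_id": str}, float_precision="round_trip")
    _require_columns(df, AVAILABILITY_COLUMNS, "availability")
    samples: dict[tuple, AvailabilitySample] = {}
    for i, row in df.iterrows():
        rownum = i + 2
        try:
            occ = int(row["occasion"])
        except (TypeError, ValueError):
            raise SchemaError(f"row {rownum}: occasion must be an integer") from None
        key = (str(row["site"]), str(row["habitat"]), str(row["season"]),
               str(row["trap_id"]), occ)
        if key not in samples:
            try:
                samples[key] = AvailabilitySample(*key)
            except VocabularyError as err:
                raise VocabularyError(f"row {rownum}: {err}") from None
        taxon = row["prey_taxon"]
        if pd.isna(taxon) or taxon == EMPTY_STOMACH_SENTINEL:
            continue
        try:
            item = PreyItem(
                taxon=str(taxon),
                length_mm=_opt_float(row["prey_length_mm"]),
                width_mm=_opt_float(row["prey_width_mm"]),
            )
        except VocabularyError as err:
            raise VocabularyError(f"row {rownum}: {err}") from None
        item = trait_table.apply(item)
        if item.vertebrate_class != "none":
            raise VocabularyError(
                f"row {rownum}: vertebrate taxon {item.taxon!r} not allowed "
                "in availability data"
            )
        if item.habitat_origin == "volant":
            raise VocabularyError(
                f"row {rownum}: volant taxon {item.taxon!r} not sampled by "
                "pitfall traps"
            )
        samples[key].items.append(item)

    out = list(samples.values())
    out.sort(key=lambda s: (s.site, s.habitat, s.season, s.trap_id, s.occasion))
    for s in out:
        s.items.sort(key=lambda it: (it.taxon, it.length_mm or 0.0, it.width_mm or 0.0))
    return out


def write_availability(samples: Sequence[AvailabilitySample], path) -> None:
    rows = []
    key = lambda s: (s.site, s.habitat, s.season, s.trap_id, s.occasion)
    for s in sorted(samples, key=key):
        base = {
            "site": s.site, "habitat": s.habitat, "season": s.season,
            "trap_id": s.trap_id, "occasion": s.occasion,
        }
        if not s.items:
            rows.append({**base, "prey_taxon": EMPTY_STOMACH_SENTINEL,
                         "prey_length_mm": "", "prey_width_mm": ""})
        for it in s.items:
            rows.append({
                **base,
                "prey_taxon": it.taxon,
                "prey_length_mm": _fmt(it.length_mm),
                "prey_width_mm": _fmt(it.width_mm),
            })
    pd.DataFrame(rows, columns=AVAILABILITY_COLUMNS).to_csv(path, index=False)


def write_trait_table(table: TraitTable, path) -> None:
    rows = [
        {"taxon": t, **vars(table.lookup(t))}
        for t in table.taxa()
    ]
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, index=False)
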