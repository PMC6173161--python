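"""Packaged reference datasets for the Andaman anuran assemblage.

Ships the published diet-composition table (per-category N%, V%, F% and IRI
for the invasive Indian bullfrog *Hoplobatrachus tigerinus* and the native
*Limnonectes* and *Fejervarya*), the published sampling-effort design, an
integer count matrix reconstructed from the percentages, and a default
functional-trait table. These are the desk fixtures every downstream stage
can be exercised against without access to the raw field data.

Note the assemblage table lists "Gastropoda" twice (terrestrial and aquatic
snails); the second row is carried as the distinct label ``Gastropoda_2`` so
the table is reproduced verbatim.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .composition import CompositionTable, DietMatrix, apportion_counts
from .types import TraitRecord, TraitTable

#: total prey items recovered per predator taxon in the Andaman study
ANDAMAN_TOTALS = {"H_tigerinus": 687, "Limnonectes": 618, "Fejervarya": 173}

#: predator-individual sample sizes behind the F% columns
ANDAMAN_N_PREDATORS = {"H_tigerinus": 358, "Limnonectes": 375, "Fejervarya": 65}

_PREFIX = {"H_tigerinus": "Ht", "Limnonectes": "Lim", "Fejervarya": "Fej"}


def _read_packaged(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("frogdiet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def andaman_composition_tables() -> dict[str, CompositionTable]:
    """Published per-species composition tables, keyed by predator taxon.

    Each table carries the printed N%, V%, F% and IRI columns over the 35
    prey categories, bit-stable across calls.
    """
    raw = _read_packaged("andaman_diet_table.tsv", sep="\t", index_col="taxon")
    out: dict[str, CompositionTable] = {}
    for species, pre in _PREFIX.items():
        df = pd.DataFrame(
            {
                "N_pct": raw[f"{pre}_N"].astype(float),
                "V_pct": raw[f"{pre}_V"].astype(float),
                "F_pct": raw[f"{pre}_F"].astype(float),
                "IRI": raw[f"{pre}_IRI"].astype(float),
            },
            index=raw.index,
        )
        out[species] = CompositionTable(
            data=df,
            n_items=ANDAMAN_TOTALS[species],
            n_predators=ANDAMAN_N_PREDATORS[species],
        )
    return out


def andaman_count_matrix() -> DietMatrix:
    """Species × category integer count matrix reconstructed from N%.

    Counts are apportioned by the largest-remainder rule so each row sums
    exactly to the published per-species item totals (687/618/173); per-cell
    values agree with plain half-up rounding everywhere except where that
    rounding loses an item to the total.
    """
    tables = andaman_composition_tables()
    rows = {}
    for species, table in tables.items():
        rows[species] = apportion_counts(
            table.data["N_pct"].to_numpy(), ANDAMAN_TOTALS[species]
        )
    first = next(iter(tables.values()))
    data = pd.DataFrame(rows, index=first.data.index).T.astype(float)
    return DietMatrix(data=data, basis="count")


def andaman_fixture() -> tuple[DietMatrix, dict[str, CompositionTable]]:
    """The (count matrix, composition tables) pair used as the desk fixture."""
    return andaman_count_matrix(), andaman_composition_tables()


def andaman_sampling_effort() -> pd.DataFrame:
    """Published long-format individuals-sampled design.

    Columns: species, site, habitat, season, n — one row per stratum with
    at least one stomach-flushed individual.
    """
    return _read_packaged("andaman_sampling_effort.csv")


def default_trait_table() -> TraitTable:
    """Three-level hardness/motility functional classification.

    Authored for the assemblage's 35 prey categories following the
    conventional scheme for anuran diet studies (soft/medium/hard;
    sedentary/medium/evasive); shipped as editable configuration since
    trait assignments are a field judgement, not a computation.
    """
    df = _read_packaged("default_traits.csv")
    mapping = {
        row.taxon: TraitRecord(row.hardness, row.motility,
                               row.habitat_origin, row.vertebrate_class)
        for row in df.itertuples()
    }
    return TraitTable(mapping)


def prey_categories() -> list[str]:
    """The 35 prey-category labels, in published row order."""
    raw = _read_packaged("andaman_diet_table.tsv", sep="\t")
    return raw["taxon"].tolist()


def numeric_proportions(species: str) -> np.ndarray:
    """Numeric (count-based) diet proportions for one predator taxon."""
    table = andaman_composition_tables()[species]
    n = table.data["N_pct"].to_numpy(dtype=float)
    return n / n.sum()
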