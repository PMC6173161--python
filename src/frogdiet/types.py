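"""Domain types for stomach-flush diet data and pitfall availability data.

All linear measurements are millimetres and all volumes cubic millimetres.
Categorical fields are drawn from closed vocabularies defined here; readers
and constructors validate against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import TraitLookupError, VocabularyError

HARDNESS_LEVELS = ("soft", "medium", "hard")
MOTILITY_LEVELS = ("sedentary", "medium", "evasive")
HABITAT_ORIGINS = ("terrestrial", "aquatic", "volant")
VERTEBRATE_CLASSES = ("Amphibia", "Reptilia", "Mammalia", "none")
LIFE_STAGES = ("adult", "larva", "unknown")
HABITATS = ("agriculture", "plantation", "disturbed_forest", "undisturbed_forest")
SEASONS = ("dry", "wet")
SEXES = ("M", "F", "unknown")
PREDATOR_TAXA = ("H_tigerinus", "Limnonectes", "Fejervarya", "other")

#: Sentinel prey taxon marking an explicit empty-stomach row in diet CSVs.
EMPTY_STOMACH_SENTINEL = "NONE"


def _check_vocab(value: str, allowed: tuple[str, ...], fieldname: str,
                 extra: tuple[str, ...] = ("unknown",)) -> str:
    if value not in allowed and value not in extra:
        raise VocabularyError(
            f"{fieldname}={value!r} not in vocabulary {sorted(set(allowed) | set(extra))}"
        )
    return value


@dataclass
class PreyItem:
    """One prey item, either consumed (from a stomach) or trapped (pitfall).

    ``length_mm``/``width_mm`` are ``None`` for fragmented prey whose
    dimensions could not be measured; ``volume_mm3`` stays ``None`` until
    computed or imputed, and ``volume_imputed`` records which path filled it.
    """

    taxon: str
    life_stage: str = "unknown"
    length_mm: float | None = None
    width_mm: float | None = None
    volume_mm3: float | None = None
    volume_imputed: bool = False
    hardness: str = "unknown"
    motility: str = "unknown"
    habitat_origin: str = "unknown"
    vertebrate_class: str = "none"

    def __post_init__(self) -> None:
        if not self.taxon:
            raise VocabularyError("prey taxon must be non-empty")
        _check_vocab(self.life_stage, LIFE_STAGES, "life_stage")
        _check_vocab(self.hardness, HARDNESS_LEVELS, "hardness")
        _check_vocab(self.motility, MOTILITY_LEVELS, "motility")
        _check_vocab(self.habitat_origin, HABITAT_ORIGINS, "habitat_origin")
        _check_vocab(self.vertebrate_class, VERTEBRATE_CLASSES, "vertebrate_class",
                     extra=())
        for name in ("length_mm", "width_mm", "volume_mm3"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise VocabularyError(f"{name} must be positive when present, got {v}")


@dataclass
class PredatorRecord:
    """One stomach-flushed individual and its (possibly empty) gut contents."""

    individual_id: str
    taxon: str
    svl_mm: float
    hw_mm: float | None = None
    ljl_mm: float | None = None
    sex: str = "unknown"
    site: str = ""
    habitat: str = "agriculture"
    season: str = "dry"
    stomach: list[PreyItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_vocab(self.taxon, PREDATOR_TAXA, "predator taxon", extra=())
        _check_vocab(self.sex, SEXES, "sex")
        _check_vocab(self.habitat, HABITATS, "habitat", extra=())
        _check_vocab(self.season, SEASONS, "season", extra=())
        if not self.svl_mm > 0:
            raise VocabularyError(f"svl_mm must be positive, got {self.svl_mm}")

    @property
    def is_empty(self) -> bool:
        return len(self.stomach) == 0


@dataclass
class AvailabilitySample:
    """Contents of one pitfall trap on one occasion within a stratum."""

    site: str
    habitat: str
    season: str
    trap_id: str
    occasion: int
    items: list[PreyItem] = field(default_factory=list)

    #: inclusive bounds on the trap-occasion index within a stratum
    OCCASION_RANGE = (1, 30)

    def __post_init__(self) -> None:
        _check_vocab(self.habitat, HABITATS, "habitat", extra=())
        _check_vocab(self.season, SEASONS, "season", extra=())
        lo, hi = self.OCCASION_RANGE
        if not lo <= self.occasion <= hi:
            raise VocabularyError(
                f"occasion {self.occasion} outside range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class TraitRecord:
    hardness: str
    motility: str
    habitat_origin: str
    vertebrate_class: str


class TraitTable:
    """Total mapping from prey taxon to its functional-trait levels.

    Trait levels follow the three-level hardness (soft/medium/hard) and
    motility (sedentary/medium/evasive) scheme standard in anuran diet
    studies, plus habitat origin and vertebrate class used for aggregation
    and for screening availability data.
    """

    def __init__(self, mapping: Mapping[str, TraitRecord]):
        self._map = dict(mapping)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._map

    def __len__(self) -> int:
        return len(self._map)

    def taxa(self) -> list[str]:
        return sorted(self._map)

    def lookup(self, taxon: str) -> TraitRecord:
        try:
            return self._map[taxon]
        except KeyError:
            raise TraitLookupError(f"taxon {taxon!r} missing from trait table") from None

    def apply(self, item: PreyItem) -> PreyItem:
        """Return a copy of *item* with trait fields filled from the table."""
        rec = self.lookup(item.taxon)
        return replace(
            item,
            hardness=rec.hardness,
            motility=rec.motility,
            habitat_origin=rec.habitat_origin,
            vertebrate_class=rec.vertebrate_class,
        )

    def validate_total(self, taxa: Iterable[str]) -> None:
        missing = sorted({t for t in taxa if t not in self._map})
        if missing:
            raise TraitLookupError(f"taxa missing from trait table: {missing}")
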