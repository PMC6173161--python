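"""End-to-end orchestration: volumes → composition/IRI → overlap + null
models → electivity → diversity → regression, with a consolidated report.

`run_full_analysis` consumes the three input CSVs (or in-memory records),
stratifies by season/habitat where the design calls for it, writes one TSV
per stage plus a machine-readable JSON summary, and is byte-reproducible
for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import datasets
from .composition import (
    build_diet_matrix,
    composition_table,
    size_prey_regression,
    vacuity_index,
)
from .electivity import (
    DEFAULT_MIN_ITEMS,
    SizeBins,
    electivity_by_size,
    electivity_by_taxon,
    electivity_by_trait,
    simpson_diversity,
)
from .errors import ConfigError, FrogdietError, UndefinedElectivityError
from .io import read_availability, read_diet_records, read_trait_table
from .overlap import null_model_overlap
from .types import SEASONS, AvailabilitySample, PredatorRecord, TraitTable
from .volumetrics import VolumePolicy, impute_record_volumes

log = logging.getLogger("frogdiet")

#: month-of-capture to season mapping (monsoon calendar)
MONTH_TO_SEASON = {m: ("dry" if m <= 4 else "wet") for m in range(1, 8)}

#: default per-taxon habitat restrictions for electivity
DEFAULT_ELECTIVITY_STRATA: dict[str, dict] = {
    "H_tigerinus": {"habitat": ("agriculture", "plantation")},
    "Fejervarya": {"site": ("Wandoor",)},
    "Limnonectes": {},
}


@dataclass
class RunConfig:
    """Inputs and knobs for a full analysis run."""

    diet_path: str | Path | None = None
    availability_path: str | Path | None = None
    trait_path: str | Path | None = None
    out_dir: str | Path = "results"
    predator_taxa: tuple[str, ...] = ("H_tigerinus", "Limnonectes", "Fejervarya")
    overlap_basis: str = "count"
    null_algorithm: str = "RA3"
    iterations: int = 1000
    seed: int = 0
    electivity_thresholds: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_ITEMS))
    size_bins: SizeBins = field(default_factory=SizeBins)
    simpson_variant: str = "complement"
    volume_policy: VolumePolicy = field(default_factory=VolumePolicy)

    def __post_init__(self) -> None:
        if self.iterations < 100:
            raise ConfigError(
                "iterations must be >= 100 for reported null-model p-values"
            )


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def run_full_analysis(
    config: RunConfig,
    records: Sequence[PredatorRecord] | None = None,
    samples: Sequence[AvailabilitySample] | None = None,
    trait_table: TraitTable | None = None,
    truth: Mapping | None = None,
) -> dict:
    """Run every analysis stage and write the report bundle.

    Inputs come either from the config's CSV paths or directly as
    in-memory records/samples. Returns the machine-readable summary dict
    (also written to ``summary.json``); every number in the TSV reports
    appears in the summary.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if trait_table is None:
        trait_table = (read_trait_table(config.trait_path)
                       if config.trait_path else datasets.default_trait_table())
    if records is None:
        if config.diet_path is None:
            raise ConfigError("no diet records given and no diet_path configured")
        records = read_diet_records(config.diet_path, trait_table)
    if samples is None and config.availability_path is not None:
        samples = read_availability(config.availability_path, trait_table)

    records = [r for r in records if r.taxon in config.predator_taxa]
    if not records:
        raise ConfigError("no records for the configured predator taxa")

    summary: dict = {"config": {
        "overlap_basis": config.overlap_basis,
        "null_algorithm": config.null_algorithm,
        "iterations": config.iterations,
        "seed": config.seed,
        "simpson_variant": config.simpson_variant,
    }}

    # volumes -----------------------------------------------------------
    stage = time.time()
    records, audit = impute_record_volumes(records, config.volume_policy)
    audit.to_csv(out_dir / "imputation_audit.tsv", sep="\t", index=False)
    summary["imputation"] = {"n_imputed": int(len(audit))}
    log.info("volumes imputed (%d items) in %.2fs", len(audit), time.time() - stage)

    # composition -------------------------------------------------------
    stage = time.time()
    present = sorted({r.taxon for r in records})
    comp_summary = {}
    for sp in present:
        sp_records = [r for r in records if r.taxon == sp]
        table = composition_table(sp_records)
        out = table.data.copy()
        _write_tsv(out, out_dir / f"composition_{sp}.tsv", "taxon")
        comp_summary[sp] = {
            "n_items": table.n_items,
            "n_predators": table.n_predators,
            "table": {c: out[c].round(6).to_dict() for c in out.columns},
        }
    summary["composition"] = comp_summary
    summary["vacuity"] = {
        season: round(vacuity_index(records, season=season), 6)
        for season in SEASONS
        if any(r.season == season for r in records)
    }
    pd.DataFrame(
        [{"season": s, "vacuity": v} for s, v in summary["vacuity"].items()]
    ).to_csv(out_dir / "vacuity.tsv", sep="\t", index=False)
    log.info("composition tables done in %.2fs", time.time() - stage)

    # overlap + null models ---------------------------------------------
    stage = time.time()
    matrix = build_diet_matrix(records, basis=config.overlap_basis)
    overlap_rows = []
    for i, j in ((a, b) for idx, a in enumerate(present) for b in present[idx + 1:]):
        res = null_model_overlap(
            matrix, (i, j), algorithm=config.null_algorithm,
            iterations=config.iterations, seed=config.seed,
        )
        overlap_rows.append({
            "pair": f"{i}-{j}", "form": res.form,
            "observed": round(res.observed, 6),
            "null_mean": round(res.null_mean, 6),
            "null_sd": round(res.null_sd, 6),
            "p_lower": round(res.p_lower, 6), "p_upper": round(res.p_upper, 6),
            "algorithm": res.algorithm, "iterations": res.iterations,
            "seed": res.seed,
        })
    pd.DataFrame(overlap_rows).to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    summary["overlap"] = overlap_rows
    log.info("overlap + null models done in %.2fs", time.time() - stage)

    # electivity --------------------------------------------------------
    stage = time.time()
    elect_summary: dict = {}
    if samples:
        for sp in present:
            strat = DEFAULT_ELECTIVITY_STRATA.get(sp, {})
            sp_records = [
                r for r in records
                if r.taxon == sp
                and all(getattr(r, k) in v for k, v in strat.items())
            ]
            sp_samples = [
                s for s in samples
                if all(getattr(s, k) in v for k, v in strat.items())
            ]
            sp_el: dict = {}
            try:
                taxon_el = electivity_by_taxon(
                    sp_records, sp_samples, sp,
                    threshold=config.electivity_thresholds.get(sp),
                )
                _write_tsv(taxon_el, out_dir / f"electivity_taxon_{sp}.tsv", "group")
                sp_el["taxon"] = taxon_el["E_star"].round(6).to_dict()
            except UndefinedElectivityError as err:
                log.warning("taxon electivity skipped for %s: %s", sp, err)
            try:
                size_el = electivity_by_size(sp_records, sp_samples, sp,
                                             bins=config.size_bins)
                _write_tsv(size_el, out_dir / f"electivity_size_{sp}.tsv", "size_bin")
                sp_el["size"] = size_el["E_star"].round(6).to_dict()
            except UndefinedElectivityError as err:
                log.warning("size electivity skipped for %s: %s", sp, err)
            trait_block = {}
            for axis in ("hardness", "motility"):
                for season in SEASONS:
                    try:
                        tr = electivity_by_trait(
                            sp_records, sp_samples, axis,
                            season=season, predator_taxon=sp,
                        )
                        trait_block[f"{axis}/{season}"] = (
                            tr["E_star"].round(6).to_dict()
                        )
                    except (UndefinedElectivityError, FrogdietError) as err:
                        log.warning("trait electivity %s/%s skipped for %s: %s",
                                    axis, season, sp, err)
            if trait_block:
                flat = pd.DataFrame(
                    [
                        {"axis_season": ks, "level": lvl, "E_star": v}
                        for ks, d in trait_block.items()
                        for lvl, v in d.items()
                    ]
                )
                flat.to_csv(out_dir / f"electivity_trait_{sp}.tsv",
                            sep="\t", index=False)
                sp_el["trait"] = trait_block
            elect_summary[sp] = sp_el

        # availability diversity per site × habitat × season ------------
        div_rows = []
        strata = sorted({(s.site, s.habitat, s.season) for s in samples})
        for site, habitat, season in strata:
            counts: dict[str, int] = {}
            for s in samples:
                if (s.site, s.habitat, s.season) == (site, habitat, season):
                    for it in s.items:
                        counts[it.taxon] = counts.get(it.taxon, 0) + 1
            if counts:
                div_rows.append({
                    "site": site, "habitat": habitat, "season": season,
                    "simpson": round(
                        simpson_diversity(list(counts.values()),
                                          config.simpson_variant), 6),
                })
        pd.DataFrame(div_rows).to_csv(out_dir / "simpson.tsv", sep="\t", index=False)
        summary["simpson"] = div_rows
    summary["electivity"] = elect_summary
    log.info("electivity + diversity done in %.2fs", time.time() - stage)

    # size regression ---------------------------------------------------
    stage = time.time()
    fits = size_prey_regression(records)
    reg_rows = [
        {"taxon": sp, "slope": round(f.slope, 6), "intercept": round(f.intercept, 6),
         "se": round(f.se, 6), "pvalue": round(f.pvalue, 6), "n": f.n}
        for sp, f in sorted(fits.items())
    ]
    pd.DataFrame(reg_rows).to_csv(out_dir / "regression.tsv", sep="\t", index=False)
    summary["regression"] = reg_rows
    log.info("size regression done in %.2fs", time.time() - stage)

    # truth vs estimate (synthetic runs only) ---------------------------
    if truth is not None:
        block: dict = {"truth": dict(truth), "estimates": {}}
        if "empty_prob" in truth:
            block["estimates"]["vacuity"] = summary["vacuity"]
        if "beta_true" in truth:
            block["estimates"]["slope"] = {
                r["taxon"]: r["slope"] for r in summary["regression"]
            }
        summary["truth_vs_estimate"] = block

    summary["elapsed_s"] = round(time.time() - t0, 3)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "elapsed_s"},
                  fh, indent=2, sort_keys=True)
    return summary
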