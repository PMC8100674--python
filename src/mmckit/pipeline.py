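"""End-to-end orchestration: inputs -> quantities -> profiles -> associations.

``run_pipeline`` glues the stage modules together in study order:

1. genotype CSV -> mother/child pairs, informative targets, compatibility;
2. plate CSV -> per-compartment microchimerism quantities (purity-gated);
3. serology CSV -> MoM values with ART flags (optional input);
4. cytometry CSV -> subset percentages and the positive/negative comparison;
5. covariates + everything above -> the cohort table and the association
   battery.

Every excluded pair or fraction is logged with a machine-readable reason, and
result tables are sorted by sample id so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cytometry import compare_composition, purity_gate, subset_percentages
from .errors import MmcKitError
from .hla import AssayPanel, pairs_to_frame, read_genotypes
from .qpcr import DEFAULT_CURVE, StandardCurve, quantify_plate, read_plate
from .scoring import cohort_summary, profiles_from_quant, profiles_to_frame
from .serology import MedianTable, mom_wide, read_serology
from .stats import association_battery


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    genotypes: Path
    plate: Path
    covariates: Optional[Path] = None
    serology: Optional[Path] = None
    cytometry: Optional[Path] = None
    purity: Optional[Path] = None
    median_tables: Optional[dict[str, MedianTable]] = None
    curve: StandardCurve = field(default_factory=lambda: DEFAULT_CURVE)
    positive_well_threshold_geq: float = 0.5
    purity_threshold: float = 95.0
    small_cell_threshold: float = 5.0
    include_wb_in_mean: bool = False
    panel: AssayPanel = field(default_factory=AssayPanel)

    @classmethod
    def from_dict(cls, d: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")
        paths = {k: base / d[k] for k in
                 ("genotypes", "plate", "covariates", "serology", "cytometry", "purity")
                 if d.get(k)}
        kwargs = {k: d[k] for k in
                  ("positive_well_threshold_geq", "purity_threshold",
                   "small_cell_threshold", "include_wb_in_mean") if k in d}
        return cls(**paths, **kwargs)


@dataclass
class PipelineResult:
    pairs_table: pd.DataFrame
    quant: pd.DataFrame
    profiles: pd.DataFrame
    summary: pd.DataFrame
    cohort: pd.DataFrame
    associations: pd.DataFrame
    composition: Optional[pd.DataFrame]
    log: list[dict]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "pairs": self.pairs_table, "quant": self.quant,
            "profiles": self.profiles, "summary": self.summary,
            "cohort": self.cohort, "associations": self.associations,
        }
        if self.composition is not None:
            tables["composition_comparison"] = self.composition
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        logp = outdir / "run_log.json"
        logp.write_text(json.dumps(
            {"mmckit_version": __version__, "events": self.log}, indent=2))
        paths["log"] = logp
        return paths


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    log: list[dict] = []

    # 1. genotypes ----------------------------------------------------------
    pairs = read_genotypes(config.genotypes)
    valid_pairs = []
    for p in pairs:
        if not p.valid:
            log.append({"event": "pair_excluded", "pair_id": p.pair_id,
                        "reason": "no-shared-allele",
                        "loci": list(p.invalid_loci)})
        else:
            valid_pairs.append(p)
    pairs_table = pairs_to_frame(valid_pairs, config.panel).sort_values(
        "pair_id", ignore_index=True)

    # 2. purity gate + quantification ---------------------------------------
    plate = read_plate(config.plate)
    if config.purity is not None and Path(config.purity).exists():
        purity = purity_gate(pd.read_csv(config.purity), config.purity_threshold)
        failing = purity.loc[~purity["pass"], ["sample_id", "compartment"]]
        for row in failing.itertuples():
            log.append({"event": "fraction_excluded", "sample_id": row.sample_id,
                        "compartment": row.compartment,
                        "reason": "purity-below-threshold"})
        bad = set(zip(failing["sample_id"], failing["compartment"]))
        keep = [
            (s, c) not in bad
            for s, c in zip(plate["sample_id"], plate["compartment"])
        ]
        plate = plate.loc[keep]
    quant = quantify_plate(
        plate, config.curve,
        positive_well_threshold_geq=config.positive_well_threshold_geq,
    ).sort_values(["sample_id", "compartment"], ignore_index=True)

    # 3. profiles & summary --------------------------------------------------
    profiles = profiles_from_quant(quant, config.include_wb_in_mean)
    profile_table = profiles_to_frame(profiles).sort_values(
        "sample_id", ignore_index=True)
    summary = cohort_summary(profiles)

    # 4. cohort table --------------------------------------------------------
    cohort = profile_table[["sample_id", "positive_any", "positive_wb",
                            "mean_total_mmc", "category"]].copy()
    cohort = cohort.merge(pairs_table.rename(columns={"pair_id": "sample_id"}),
                          on="sample_id", how="left")
    if config.covariates is not None and Path(config.covariates).exists():
        cov = pd.read_csv(config.covariates)
        cohort = cohort.merge(cov, on="sample_id", how="left")
    else:
        log.append({"event": "input_missing", "input": "covariates"})
    if config.serology is not None and Path(config.serology).exists():
        sero = read_serology(config.serology, config.median_tables)
        wide = mom_wide(sero)
        cohort = cohort.merge(
            wide.drop(columns=[c for c in ("art_conception",) if c in cohort.columns
                               and c in wide.columns]),
            on="sample_id", how="left")
    else:
        log.append({"event": "input_missing", "input": "serology",
                    "consequence": "serology comparisons skipped"})
    cohort = cohort.sort_values("sample_id", ignore_index=True)

    # 5. associations --------------------------------------------------------
    associations = association_battery(
        cohort, small_cell_threshold=config.small_cell_threshold)

    composition = None
    if config.cytometry is not None and Path(config.cytometry).exists():
        events = pd.read_csv(config.cytometry)
        pct = subset_percentages(events)
        merged = pct.merge(cohort[["sample_id", "positive_any"]], on="sample_id")
        try:
            composition = compare_composition(
                merged.drop(columns=["positive_any"]),
                merged["positive_any"].astype(bool))
        except MmcKitError as exc:
            log.append({"event": "composition_skipped", "reason": str(exc)})
    else:
        log.append({"event": "input_missing", "input": "cytometry"})

    return PipelineResult(
        pairs_table=pairs_table, quant=quant, profiles=profile_table,
        summary=summary, cohort=cohort, associations=associations,
        composition=composition, log=log,
    )
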