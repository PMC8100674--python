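"""Synthetic cohort generator with planted effect structure.

Generates every input the analysis pipeline consumes — mother/child HLA
genotypes, well-level qPCR plates, first-trimester serology, flow-cytometry
event counts, obstetric covariates, sorted-fraction purities — plus a
ground-truth table for parameter-recovery tests.

The default configuration emulates a 55-pair primigravid cord-blood cohort:

* maternal genotypes drawn from realistic European first-field allele-group
  frequencies; the child inherits one maternal allele per locus plus a
  paternal allele drawn from the same population frequencies;
* microchimerism positivity follows a logistic model on feto-maternal HLA-A
  and/or DRB1 compatibility;
* maternal PAPP-A is lognormal with median 1.41 MoM in MMc-positive and
  1.01 MoM in MMc-negative pregnancies (sigma_log 0.4);
* positive samples carry a per-subset mean quantity drawn log-uniformly over
  0.3-3021 gEq/10^6, split across tested subsets by a Dirichlet draw;
* each tested compartment is assayed in ten replicate wells of 20,000 gEq,
  with Poisson loading of maternal genomes and Gaussian Cq noise;
* cord blood from MMc-positive pregnancies is enriched in CD56+ (NK) cells.

All randomness flows from one explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FrequencyError
from .hla import AssayPanel, Genotype, HLAAllele, LOCI, MotherChildPair
from .qpcr import DEFAULT_CURVE, StandardCurve
from .serology import SCREEN_WINDOW_DAYS, synthetic_median_table

# first-field allele-group frequencies, European-ancestry magnitudes
DEFAULT_ALLELE_FREQUENCIES: dict[str, dict[str, float]] = {
    "A": {
        "A*01": 0.16, "A*02": 0.29, "A*03": 0.13, "A*11": 0.06, "A*24": 0.10,
        "A*26": 0.04, "A*29": 0.04, "A*32": 0.04, "A*68": 0.05, "A*23": 0.02,
        "A*30": 0.03, "A*31": 0.02, "A*33": 0.02,
    },
    "B": {
        "B*07": 0.13, "B*08": 0.10, "B*44": 0.13, "B*35": 0.10, "B*15": 0.08,
        "B*40": 0.07, "B*51": 0.07, "B*18": 0.06, "B*27": 0.04, "B*57": 0.04,
        "B*13": 0.03, "B*14": 0.04, "B*49": 0.02, "B*55": 0.02, "B*39": 0.02,
        "B*37": 0.02, "B*52": 0.02, "B*58": 0.01,
    },
    "DRB1": {
        "DRB1*01": 0.09, "DRB1*03": 0.11, "DRB1*04": 0.13, "DRB1*07": 0.13,
        "DRB1*08": 0.03, "DRB1*10": 0.01, "DRB1*11": 0.12, "DRB1*12": 0.02,
        "DRB1*13": 0.11, "DRB1*14": 0.04, "DRB1*15": 0.13, "DRB1*16": 0.03,
        "DRB1*09": 0.05,
    },
}

DEFAULT_CYTOMETRY_MEANS: dict[str, tuple[float, float]] = {
    # percent of CD45+ events: (mean, sd)
    "CD20": (5.0, 2.0), "CD3": (30.0, 8.0), "CD66": (35.0, 10.0),
    "CD16": (8.0, 3.0), "CD56": (10.0, 4.0), "CD16_56": (12.0, 4.0),
    "CD3_16_56": (3.0, 1.5), "CD34": (1.5, 0.7),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_pairs: int = 55
    allele_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ALLELE_FREQUENCIES.items()})

    # logistic model for planted MMc positivity; the baseline is chosen so
    # that, after detection attenuation of low planted quantities, measured
    # prevalence sits near the ~55% seen in real cord-blood cohorts
    baseline_logodds: float = 0.4
    compat_logodds: float = 1.4
    pappa_logodds_per_mom: float = 0.0  # when nonzero, PAPP-A drives positivity

    # PAPP-A MoM, lognormal per planted MMc group
    pappa_median_positive: float = 1.41
    pappa_median_negative: float = 1.01
    pappa_sigma_log: float = 0.4
    bhcg_median: float = 1.0
    bhcg_sigma_log: float = 0.5

    # planted quantities, gEq per million host cells
    quantity_range: tuple[float, float] = (0.3, 3021.0)  # log-uniform mean/subset
    dirichlet_alpha: float = 1.0
    wb_quantity_factor: float = 0.5  # whole blood dilutes the subset signal

    # qPCR plate design
    n_replicates: int = 10
    n_host_replicates: int = 2
    host_geq_per_well: float = 20_000.0
    cq_noise_sd: float = 0.15
    curve: StandardCurve = field(default_factory=lambda: DEFAULT_CURVE)

    # which compartments get sorted and tested
    subset_test_probs: dict[str, float] = field(default_factory=lambda: {
        "PBMC": 0.5, "CD3": 0.9, "CD19": 0.9, "CD66": 0.9, "CD34": 0.62})
    purity_mean: float = 98.0
    purity_sd: float = 1.5

    # cytometry composition
    cytometry_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CYTOMETRY_MEANS))
    cd56_shift_positive: float = 8.0  # percentage points added for planted positives
    cd45_events: int = 10_000

    # covariates
    center_probs: dict[str, float] = field(default_factory=lambda: {
        "center_1": 32 / 55, "center_2": 22 / 55, "center_3": 1 / 55})
    csection_prob: float = 5 / 55
    same_day_prob: float = 21 / 55
    serology_prob: float = 46 / 55
    art_prob: float = 4 / 46
    male_prob: float = 0.5
    weight_mean_g: float = 3400.0
    weight_sd_g: float = 450.0
    gestation_mean_weeks: float = 39.5
    gestation_sd_weeks: float = 1.2


def _check_frequencies(freqs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    names = list(freqs)
    p = np.array([freqs[k] for k in names], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise FrequencyError(f"allele frequencies sum to {p.sum()!r}, not 1")
    return names, p


def _draw_allele(names: list[str], p: np.ndarray, locus: str,
                 rng: np.random.Generator) -> HLAAllele:
    return HLAAllele.parse(names[rng.choice(len(names), p=p)], locus)


def simulate_pair(config: SimulationConfig, rng: np.random.Generator,
                  pair_id: str = "P1") -> MotherChildPair:
    """One mother/child pair: maternal alleles from population frequencies,
    child = one uniformly chosen maternal allele + one paternal allele drawn
    from the same frequencies, independently per locus."""
    mother_alleles: dict = {}
    child_alleles: dict = {}
    for locus in LOCI:
        names, p = _check_frequencies(config.allele_frequencies[locus])
        m1 = _draw_allele(names, p, locus, rng)
        m2 = _draw_allele(names, p, locus, rng)
        transmitted = m1 if rng.random() < 0.5 else m2
        paternal = _draw_allele(names, p, locus, rng)
        mother_alleles[locus] = (m1, m2)
        child_alleles[locus] = (transmitted, paternal)
    return MotherChildPair(pair_id, Genotype(mother_alleles), Genotype(child_alleles))


def simulate_informative_pair(config: SimulationConfig, rng: np.random.Generator,
                              pair_id: str, panel: Optional[AssayPanel] = None,
                              max_attempts: int = 1000) -> MotherChildPair:
    """Resample pairs until one has an informative panel target.

    Mirrors study enrolment: only pairs with a usable non-shared,
    non-inherited maternal target can be quantified at all.
    """
    panel = panel or AssayPanel()
    for _ in range(max_attempts):
        pair = simulate_pair(config, rng, pair_id)
        if pair.best_target(panel) is not None:
            return pair
    raise RuntimeError("no informative pair found; check panel/frequencies")


def simulate_plate_detection(true_frequency: float, n_wells: int,
                             host_geq_per_well: float, n_plates: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Vectorised plate-level detection under Poisson template loading.

    Returns one boolean per plate: did any well receive >=1 microchimeric
    genome?  Used to check the closed-form detection-probability model.
    """
    lam = true_frequency * host_geq_per_well
    counts = rng.poisson(lam, size=(int(n_plates), int(n_wells)))
    return (counts >= 1).any(axis=1)


@dataclass
class CohortBundle:
    """The five pipeline input tables plus purity checks and ground truth."""

    genotypes: pd.DataFrame
    plate: pd.DataFrame
    serology: pd.DataFrame
    cytometry: pd.DataFrame
    covariates: pd.DataFrame
    purity: pd.DataFrame
    truth: pd.DataFrame

    _FILES = ("genotypes", "plate", "serology", "cytometry", "covariates",
              "purity", "truth")

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in self._FILES:
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _genotype_rows(pair: MotherChildPair) -> list[dict]:
    rows = []
    for role, g in (("mother", pair.mother), ("child", pair.child)):
        row = {"pair_id": pair.pair_id, "role": role}
        for locus in LOCI:
            a, b = g.pair(locus)
            row[f"{locus}_1"], row[f"{locus}_2"] = a.name, b.name
        rows.append(row)
    return rows


def _simulate_wells(quantity_per_million: float, assay: str, sample_id: str,
                    compartment: str, config: SimulationConfig,
                    rng: np.random.Generator) -> list[dict]:
    """Well rows for one sample/compartment: target replicates + host wells."""
    rows = []
    lam = quantity_per_million / 1e6 * config.host_geq_per_well
    genomes = rng.poisson(lam, size=config.n_replicates)
    for i, g in enumerate(genomes, start=1):
        if g >= 1:
            cq = config.curve.cq_of(float(g)) + rng.normal(0.0, config.cq_noise_sd)
        else:
            cq = np.nan
        rows.append({"sample_id": sample_id, "compartment": compartment,
                     "assay": assay, "replicate": i, "cq": cq})
    for i in range(1, config.n_host_replicates + 1):
        cq = config.curve.cq_of(config.host_geq_per_well) + rng.normal(
            0.0, config.cq_noise_sd)
        rows.append({"sample_id": sample_id, "compartment": compartment,
                     "assay": "BGLOBIN", "replicate": i, "cq": cq})
    return rows


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | int,
                    panel: Optional[AssayPanel] = None) -> CohortBundle:
    """Generate the full input bundle for one synthetic cohort."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    panel = panel or AssayPanel()
    median_tables = {"PAPPA": synthetic_median_table("PAPPA"),
                     "BHCG": synthetic_median_table("BHCG")}

    geno_rows: list[dict] = []
    plate_rows: list[dict] = []
    sero_rows: list[dict] = []
    cyto_rows: list[dict] = []
    cov_rows: list[dict] = []
    purity_rows: list[dict] = []
    truth_rows: list[dict] = []

    centers = list(config.center_probs)
    center_p = np.array([config.center_probs[c] for c in centers])
    center_p = center_p / center_p.sum()

    for i in range(1, config.n_pairs + 1):
        sid = f"S{i:03d}"
        pair = simulate_informative_pair(config, rng, sid, panel)
        geno_rows.extend(_genotype_rows(pair))
        locus, target = pair.best_target(panel)
        compat = bool(pair.compatibility_any(("A", "DRB1")))

        # --- planted positivity and PAPP-A ---------------------------------
        if config.pappa_logodds_per_mom != 0.0:
            pappa_mom = float(rng.lognormal(
                math.log(config.pappa_median_negative), config.pappa_sigma_log))
            eta = (config.baseline_logodds + config.compat_logodds * compat
                   + config.pappa_logodds_per_mom * (pappa_mom - 1.0))
            planted_positive = bool(rng.random() < _sigmoid(eta))
        else:
            eta = config.baseline_logodds + config.compat_logodds * compat
            planted_positive = bool(rng.random() < _sigmoid(eta))
            med = (config.pappa_median_positive if planted_positive
                   else config.pappa_median_negative)
            pappa_mom = float(rng.lognormal(math.log(med), config.pappa_sigma_log))
        bhcg_mom = float(rng.lognormal(math.log(config.bhcg_median),
                                       config.bhcg_sigma_log))

        # --- planted per-compartment quantities ----------------------------
        tested_subsets = [c for c, pr in config.subset_test_probs.items()
                          if rng.random() < pr]
        lo, hi = config.quantity_range
        if planted_positive:
            mean_q = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if tested_subsets:
                split = rng.dirichlet([config.dirichlet_alpha] * len(tested_subsets))
                subset_q = dict(zip(tested_subsets,
                                    split * mean_q * len(tested_subsets)))
            else:
                subset_q = {}
            wb_q = mean_q * config.wb_quantity_factor
        else:
            mean_q, wb_q = 0.0, 0.0
            subset_q = {c: 0.0 for c in tested_subsets}

        # --- purity gate on sorted fractions -------------------------------
        kept_subsets = []
        for comp in tested_subsets:
            if comp == "PBMC":  # gradient fraction, not immunosorted
                kept_subsets.append(comp)
                continue
            purity = float(min(100.0, rng.normal(config.purity_mean,
                                                 config.purity_sd)))
            purity_rows.append({"sample_id": sid, "compartment": comp,
                                "purity": purity})
            if purity > 95.0:
                kept_subsets.append(comp)

        # --- qPCR wells -----------------------------------------------------
        plate_rows.extend(_simulate_wells(wb_q, target, sid, "WB", config, rng))
        for comp in kept_subsets:
            plate_rows.extend(_simulate_wells(subset_q.get(comp, 0.0), target,
                                              sid, comp, config, rng))

        # --- serology -------------------------------------------------------
        has_serology = rng.random() < config.serology_prob
        art = bool(has_serology and rng.random() < config.art_prob)
        if has_serology:
            day = int(rng.integers(SCREEN_WINDOW_DAYS[0], SCREEN_WINDOW_DAYS[1] + 1))
            for analyte, mom in (("PAPPA", pappa_mom), ("BHCG", bhcg_mom)):
                raw = mom * median_tables[analyte].median_at(day)
                sero_rows.append({"sample_id": sid, "analyte": analyte,
                                  "raw": raw, "gestational_day": day,
                                  "art_conception": art})

        # --- cytometry ------------------------------------------------------
        cd45 = int(rng.poisson(config.cd45_events))
        pct = {}
        for marker, (mean, sd) in config.cytometry_means.items():
            shift = (config.cd56_shift_positive
                     if marker == "CD56" and planted_positive else 0.0)
            pct[marker] = max(0.1, rng.normal(mean + shift, sd))
        cd3 = pct["CD3"]
        f4 = np.clip(rng.normal(0.60, 0.08), 0.05, 0.93)
        f8 = np.clip(rng.normal(0.30, 0.05), 0.02, 0.98 - f4)
        cyto = {"sample_id": sid, "CD45": cd45}
        for marker, v in pct.items():
            cyto[marker] = int(round(v / 100.0 * cd45))
        cyto["CD4"] = int(round(cd3 * f4 / 100.0 * cd45))
        cyto["CD8"] = int(round(cd3 * f8 / 100.0 * cd45))
        cyto_rows.append(cyto)

        # --- covariates -----------------------------------------------------
        same_day = rng.random() < config.same_day_prob
        cov_rows.append({
            "sample_id": sid,
            "center": centers[rng.choice(len(centers), p=center_p)],
            "delivery_mode": ("c_section" if rng.random() < config.csection_prob
                              else "vaginal"),
            "processing_delay_h": (float(rng.uniform(2, 20)) if same_day
                                   else float(rng.uniform(24, 30))),
            "sex": "M" if rng.random() < config.male_prob else "F",
            "weight_g": float(rng.normal(config.weight_mean_g, config.weight_sd_g)),
            "gestation_weeks": float(rng.normal(config.gestation_mean_weeks,
                                                config.gestation_sd_weeks)),
            "art_conception": art,
        })

        truth_rows.append({
            "sample_id": sid, "planted_positive": planted_positive,
            "planted_mean_quantity": mean_q, "planted_wb_quantity": wb_q,
            "pappa_mom_true": pappa_mom, "bhcg_mom_true": bhcg_mom,
            "compat_A": pair.compatibility["A"],
            "compat_B": pair.compatibility["B"],
            "compat_DRB1": pair.compatibility["DRB1"],
            "compat_A_or_DRB1": compat,
            "target_locus": locus, "target": target,
            "has_serology": has_serology,
        })

    return CohortBundle(
        genotypes=pd.DataFrame(geno_rows),
        plate=pd.DataFrame(plate_rows),
        serology=pd.DataFrame(sero_rows),
        cytometry=pd.DataFrame(cyto_rows),
        covariates=pd.DataFrame(cov_rows),
        purity=pd.DataFrame(purity_rows),
        truth=pd.DataFrame(truth_rows),
    )
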