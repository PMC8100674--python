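# mmckit

Analysis toolkit for **maternal microchimerism (MMc) in umbilical cord
blood**: small numbers of maternal cells cross the placenta during pregnancy
and persist in the child's blood. For cord-blood banking and transplantation
it matters which units are MMc-rich, so this package implements the complete
analysis chain used to quantify maternal cells in a cord-blood cohort and to
test what predicts their presence.

For biostatisticians and transplant-immunology labs, it covers:

* **HLA calculus** — from mother/child HLA-A/-B/-DRB1 genotypes, derive the
  non-inherited maternal antigen (NIMA, the qPCR detection target), the
  paternally inherited allele, informative-marker selection against a probe
  panel, and *compatibility from the child's perspective* (every maternal
  allele group present in the child, so maternal cells look like self).
* **qPCR quantification** — genome-equivalent arithmetic (1 gEq = 6.6 pg;
  132 ng = 20,000 gEq per well), standard-curve fitting and inversion,
  ten-replicate aggregation to gEq per million host cells (gEq/10⁶), and
  explicit detection limits: 0.005% per well, 0.0005% across ten wells, with
  a Poisson model `P(detect) = 1 − exp(−n·gEq·f)` for rare templates.
* **Chimerism scoring** — positivity per compartment (whole blood, PBMC,
  CD3, CD19, CD66, CD34), mean-of-subsets score, and the four categories
  negative / slight (≤10 gEq/10⁶) / moderate (10–100) / high (≥100).
* **Serology MoM** — PAPP-A and β-hCG as multiples of the gestational-day
  median, with interpolation and ART-conception exclusion.
* **Cytometry composition** — subset percentages of CD45+ events, the >95%
  purity gate, and positive-vs-negative composition comparison.
* **Exact small-sample statistics** — Mann-Whitney (exact by enumeration for
  small tie-free samples), Pearson chi-square without continuity correction,
  Fisher's exact 2×K by full enumeration with the point-probability
  two-sided criterion, and Spearman correlation (exact for n ≤ 9).
* **A synthetic cohort generator** that plants the effect structure the
  analysis assumes (PAPP-A medians 1.41 vs 1.01 MoM, compatibility-driven
  positivity, quantities spanning 0.3–3021 gEq/10⁶, CD56+ enrichment), so
  the whole pipeline is testable end to end without any patient data.

## Worked example

Simulate a 55-pair cohort and push it through the full pipeline:

```python
import mmckit as mk
from mmckit.pipeline import PipelineConfig, run_pipeline

bundle = mk.simulate_cohort(mk.SimulationConfig(), 42)
paths = bundle.write("cohort/")
res = run_pipeline(PipelineConfig(
    genotypes=paths["genotypes"], plate=paths["plate"],
    covariates=paths["covariates"], serology=paths["serology"],
    cytometry=paths["cytometry"], purity=paths["purity"]))
print(res.summary.head(7).to_string(index=False))
```

```
          group  n_positive  n_tested  frequency  percent
any_compartment          27        55   0.490909       49
           CD19          21        50   0.420000       42
            CD3          19        51   0.372549       37
           CD34          16        36   0.444444       44
           CD66          19        51   0.372549       37
           PBMC          12        30   0.400000       40
             WB          22        55   0.400000       40
```

27 of the 55 simulated units (49%) carry detectable maternal DNA in at least
one compartment. The association battery then tests what predicts
positivity; for this draw the planted compatibility effect reaches
significance in the category comparison, while the planted PAPP-A shift does
not — at n = 55 single draws legitimately vary, which is why calibration is
checked by simulation rather than by any one cohort:

```
pappa_mom~positive_wb          mann-whitney-normal    p=0.2557
compat_A~positive_wb           fisher-exact-2x2       p=0.1056
compat_A_or_DRB1~category      fisher-exact-2x4       p=0.0051
pappa_mom~mean_total_mmc       spearman-t             p=0.1293
```

The composition comparison flags the planted CD56+ (NK cell) enrichment in
MMc-positive units (means 17.3% vs 10.6% of CD45+ events, Mann-Whitney
p ≈ 2×10⁻⁶).

The same stages are available from the shell:

```sh
mmckit simulate --seed 42 --outdir cohort/
mmckit run --indir cohort/ --outdir results/
mmckit quantify cohort/plate.csv --out quant.csv
```

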