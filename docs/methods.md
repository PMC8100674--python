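# Methods

## Scientific setting

During pregnancy a small number of maternal cells cross the placenta and
persist in the child — maternal microchimerism (MMc). In umbilical cord blood
(CB) this matters for transplantation: maternal cells in a banked graft may
contribute alloreactive (graft-versus-leukemia-like) effects, so factors that
predict an MMc-rich unit are of practical interest. `mmckit` implements the
full analysis chain used in this setting: selecting an HLA target that can
distinguish maternal from fetal DNA, quantifying it by real-time PCR,
scoring and categorising samples, normalising first-trimester serology, and
testing the cohort-level associations.

## HLA calculus

All genetics are at first-field ("two-digit" allele group) resolution at
HLA-A, -B and -DRB1, the resolution of the detection assays. For each
mother/child pair and locus the child's genotype decomposes into the
**inherited maternal allele**, the mother's other allele (the **NIMA**,
non-inherited maternal antigen) and the paternally inherited allele
(**IPA**). Maternal cells are detected by amplifying the NIMA, which is
absent from the child's own genome provided the child does not coincidentally
carry the same group — hence a target is *informative* only when the mother
is heterozygous, the NIMA group is not carried by the child, and the panel
has a probe for it. The default panel covers DRB1\*01, \*15/16 (one combined
probe), \*03, \*04, \*07, \*08, \*10, \*11, \*12, \*13, \*14 and A\*01,
\*02, \*11. Because the \*15/16 probe cannot discriminate the two groups, a
NIMA of DRB1\*15 counts as "shared" when the child carries DRB1\*16 — for
panel purposes only; the two groups stay distinct for compatibility calls.

**Compatibility from the child's perspective** holds at a locus when every
maternal allele group is present in the child (equivalently, the NIMA group
is carried by the child): maternal cells then present nothing foreign to the
child's immune system. Informativity therefore implies incompatibility, and
for heterozygous mothers under a complete panel the two are equivalent — a
property the test suite verifies by exhaustive enumeration.

Two genuinely open corners are resolved as follows. When a heterozygous
mother {X, Y} has a child {X, Y}, which allele was transmitted cannot be
known; the pair is flagged `inheritance-ambiguous`, a deterministic
(lexicographic) assignment is made, and the locus is still classified
compatible (unambiguous) and non-informative (any NIMA candidate is shared).
Untyped loci carry null derived fields and are dropped pairwise downstream.

## qPCR quantification

One genome equivalent (gEq) is fixed at 6.6 pg of human DNA, so the nominal
132 ng well input is 20,000 gEq. Quantification inverts a log-linear
standard curve `Cq = intercept + slope*log10(gEq)`; the default simulated
curve uses the ideal slope −1/log10(2) ≈ −3.32 (100% efficiency) with
intercept 35, and curves can be fitted from dilution series by least squares
(slope, intercept, efficiency, R² are reported). Host input per reaction is
taken from β-globin reference wells when present, else from a column in the
plate export, else the nominal 20,000 gEq.

A sample/compartment is measured in ten replicate wells; the microchimerism
quantity is the summed target gEq over the summed host gEq scaled to
gEq/10⁶. Detection limits are explicit: one genome in one 20,000-gEq well is
0.005% per well and 0.0005% across ten wells. Under Poisson loading of rare
templates, the chance that any well receives a maternal genome is
`1 − exp(−n_wells · host_gEq · f)`.

**Per-well positivity threshold.** A well is called positive when its
estimated quantity reaches 0.5 gEq (configurable). The assay's nominal
sensitivity is one template per well, but a single-template well quantifies
symmetrically *around* 1 gEq once Cq noise is present; a cut at exactly
1 gEq would discard about half of true single-genome detections, while
0.5 gEq is the midpoint separating zero from one template. Cq values beyond
cycle 45 are treated as no amplification.

## Scoring and categories

A sample is positive when any tested compartment (whole blood, PBMC, CD3,
CD19, CD66, CD34) is positive. Its quantitative score is the arithmetic mean
of the per-subset quantities over subsets actually tested; whole blood is
excluded from this mean by default because it is a mixture of the subsets,
not a subset (configurable). Categories: negative; slight (0 < mean ≤ 10
gEq/10⁶); moderate (10–100); high (≥ 100). The printed boundary rules
overlap at 10 and 100; the closed bounds as written are respected (exactly
10 → slight, exactly 100 → high), and a positive sample whose mean rounds to
zero stays slight — the positivity call dominates.

## Serology MoM

PAPP-A and free β-hCG depend strongly on gestational age, so each raw
concentration is divided by the reference median for the same gestational
day (multiple of the median, MoM), with linear interpolation between
tabulated days and a hard error outside the table window (default 70–98
days). The shipped median table is synthetic and non-clinical — a smooth
monotone stand-in for testing; real analyses must supply laboratory-specific
reference medians. ART-conceived pregnancies can be excluded by flag, since
assisted reproduction shifts first-trimester markers.

## Cytometry composition

Subset percentages are event counts over CD45+ (total leukocyte) events.
Sorted fractions enter chimerism testing only above 95% purity (strict
inequality). Composition is compared between MMc-positive and -negative
samples subset-by-subset with two-sided Mann-Whitney tests at α = 0.05, with
no multiple-testing correction by default (matching per-subset reporting
practice in this literature); Benjamini-Hochberg adjustment is available.

## Statistical battery

* **Mann-Whitney U** — exact by enumerating the null rank-sum distribution
  (a shift/convolution recursion) when n₁+n₂ ≤ 12 with no ties; the
  two-sided exact p is twice the smaller tail, capped at 1. Otherwise a
  normal approximation with tie correction and 0.5 continuity correction.
* **Pearson chi-square** on 2×2 tables, df = 1, *without* continuity
  correction — with the Yates correction the centre-comparison counts
  14/22 vs 15/32 would not reproduce the p = 0.22 that plain Pearson gives.
* **Fisher exact 2×K** (K ≤ 4) by full enumeration of all tables with the
  observed margins under the multivariate hypergeometric law, summing point
  probabilities ≤ the observed table's (the point-probability two-sided
  criterion used by the classical 2×K exact calculators). Ties in point
  probability are absorbed by a 10⁻⁹ relative tolerance; enumeration is
  refused above a configurable 200-observation cap.
* **Spearman ρ** with average ranks; exact permutation p for n ≤ 9 without
  ties, t approximation (df = n−2) otherwise.
* The cohort battery applies a small-cell rule: 2×2 tables switch from
  chi-square to Fisher when any expected count is below 5 (configurable);
  wider tables always use Fisher. Comparisons whose inputs are absent (e.g.
  no serology collected) are reported as skipped, not failed.

## Synthetic cohort generator

The generator exists so every stage is testable end to end without any
protected data. Defaults encode the study conditions: 55 primigravid
mother/child pairs; maternal genotypes from realistic European-ancestry
first-field allele-group frequencies with Mendelian transmission and a
population-drawn paternal allele (full paternal genotypes are not modelled —
only the transmitted allele matters downstream); enrolment-style resampling
until each pair has an informative panel target; planted MMc positivity from
a logistic model on HLA-A/DRB1 compatibility (+1.4 log-odds, baseline +0.4 —
chosen so that measured prevalence, after detection attenuation of low
planted quantities, sits near the ~55% of real cohorts); PAPP-A lognormal
with median 1.41 MoM in positives vs 1.01 in negatives (σ_log 0.4); planted
mean-per-subset quantities log-uniform over 0.3–3021 gEq/10⁶, split across
tested subsets by a Dirichlet draw (quantities correlate across subsets
within a sample, as observed in high-MMc units) with whole blood at half the
mean; ten-well plates with Poisson template loading, Gaussian Cq noise
(sd 0.15) and β-globin host wells; immunosorted-fraction purities near 98%
with occasional gate failures; CD56+ (NK) percentage shifted +8 points in
planted positives; covariates (centres 32/22/1, 5/55 C-sections, 21/55
same-day processing, serology in 46/55 with 4 ART conceptions) matching the
emulated cohort's margins.

What the generator does **not** emulate: HLA linkage disequilibrium and
haplotype structure, population-specific panels, PCR inhibition or
competition between maternal and host templates, sorting losses, or any
correlation between covariates and genetics. Passing tests therefore
demonstrate the correctness of the calculus and the calibration of the
statistics under the planted model — not the biological effect sizes of any
real cohort.

## Numerical and design choices

* All randomness flows from one explicitly passed `numpy.random.Generator`;
  identical seeds give identical bundles, and pipeline reruns on identical
  inputs are byte-identical (stable sort orders, no global state).
* Enumerations are done in log-space via `gammaln` to avoid overflow;
  exact-test p-values are clamped into (0, 1].
* Higher-resolution HLA strings are truncated to allele groups with a
  warning rather than rejected.
* Degenerate inputs raise typed errors (`NoSharedAlleleError`,
  `DegenerateCurveError`, `ZeroMarginError`, …) so the pipeline can exclude
  and log rather than abort; every exclusion carries a machine-readable
  reason code in the run log.

## Problem sizes used in the shipped checks

The test suite and the acceptance script verify: exact-test agreement with
brute-force oracles over all 2×2 tables with n ≤ 40 and all rank partitions
with n ≤ 10; detection frequency over 10⁵ simulated plates; PAPP-A median
recovery on a 500-pair cohort; quantity recovery over 500 plates per level
at 5 and 50 gEq/10⁶ (Poisson loading makes the estimator unbiased, so the
averaged relative bias stays below 10% from ~5 gEq/10⁶ upward); and type-I
calibration over 1000 null cohorts of n = 200. These sizes were chosen as
the smallest that make the statistical assertions sharp.

## Known limitations

* First-field resolution only; no HLA-C/-DQ, no phasing, no KIR.
* The paper-style cohort-level p-values (e.g. PAPP-A vs positivity) are not
  fixed targets of the package: at n = 55 they vary legitimately from draw
  to draw, which is exactly what the power/type-I simulations quantify.
* The serology median table shipped for tests is synthetic; MoM values
  produced with it are not clinically interpretable.
* The Fisher enumeration is exponential in K; the 200-observation cap keeps
  2×4 tables tractable and refuses anything larger.
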