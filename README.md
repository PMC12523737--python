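# haarisk

Analysis toolkit for **heterocyclic aromatic amines (HAAs) in plant-based
milk alternatives (PBMAs)**: analytical method-validation figures of merit,
two-level factorial screening with desirability-based optimization of the
extraction, exploratory statistics on concentration profiles, and a
deterministic dietary-exposure / incremental-lifetime-cancer-risk (ILCR)
assessment — all runnable end to end on seeded synthetic surveys.

## The problem

HAAs are mutagenic compounds formed when protein- and sugar-rich foods are
heated: the *thermal* class (4,8-DiMeIQx, DMIP, IQ, MeIQ, MeIQx, PhIP)
forms at 150–300 °C through Maillard chemistry, the *pyrolytic* class
(AαC, MeAαC, Trp-P-1, Trp-P-2) above 300 °C. Plant milks made from almond,
soy, cashew or peanut carry exactly these precursors, and both sweetening
and pasteurization push HAA formation — with a synergy when combined. This
package is aimed at food-safety analysts who need to go from trace-level
concentration tables (with values left-censored below detection limits) to
a defensible cancer-risk statement per beverage type, preparation, age
group and consumption scenario.

## The model

Concentrations `C` (µg L⁻¹) enter per sample and compound with a censoring
flag. For an exposure scenario with ingestion rate `IR = servings × 0.2 L`,
body weight `BW` (21 / 49 / 65 kg for ages 5 / 13 / 84), exposure duration
`ED` (years), frequency `EF = 365 d yr⁻¹` and averaging time
`AT = ED × 365 d`:

```
EDI  = consumption × C                      (mg day⁻¹)
CDI  = C × IR × ED × EF / (BW × AT)         (mg kg⁻¹ day⁻¹)  — collapses to C × IR / BW
ILCR = Σ_compounds CDI × CSF × ADAF
```

where `CSF` is the oral cancer slope factor (defined for seven of the ten
HAAs: IQ 1.4, MeIQ 1.5, MeIQx 1.7, AαC 0.4, MeAαC 1.2, Trp-P-1 2.6,
Trp-P-2 3.2 per mg kg⁻¹ day⁻¹) and `ADAF` the age-dependent adjustment
factor (3 inside the 3–15-year window, else 1). ILCR < 10⁻⁶ is negligible,
\> 10⁻⁴ unacceptable, anything between needs further evaluation; total
intake is additionally checked against the 1 µg person⁻¹ day⁻¹ European
Council limit.

Around this core sit the standard method-validation calculus
(LOD/LOQ from the signal-to-noise 3.3/10 rule, spike recovery, enrichment
factor, matrix effect from slope ratios, lack-of-fit F-test), a 2³
factorial screen with Lenth-based Pareto significance, a
Derringer–Suich desirability optimizer over quadratic or small-network
surrogates, and Welch/PCA/hierarchical-clustering profile statistics.

## Worked example

```python
from haarisk import (GeneratorConfig, generate_concentrations, ExposureScenario,
                     ilcr_total, edi, ec_limit_check, compare_commercial_homemade)
from haarisk.data import totals_by_sample

survey = generate_concentrations(GeneratorConfig(seed=42))   # 4 bases × 5 treatments × 3 reps
totals = totals_by_sample(survey)
print(f"total HAA range: {totals.min():.2f} - {totals.max():.2f} ug/L")

cmp = compare_commercial_homemade(survey)
print(f"commercial - homemade: {cmp.mean_difference:.2f} ug/L "
      f"(95% CI {cmp.ci95[0]:.2f}-{cmp.ci95[1]:.2f}, p = {cmp.p_value:.4f})")

adult = ilcr_total({"Trp-P-1": 2.72}, ExposureScenario(84, 1))
print(f"adult ILCR: {adult.ilcr_total:.3e} ({adult.band.value})")

intake = edi(13.66, 0.2) * 1000    # ug/day from one 200 mL serving
print(f"intake: {intake:.3f} ug/day, exceeds EC limit: {ec_limit_check(intake)}")
```

prints

```
total HAA range: 0.26 - 12.97 ug/L
commercial - homemade: 4.29 ug/L (95% CI 2.00-6.57, p = 0.0013)
adult ILCR: 2.176e-05 (further_evaluation)
intake: 2.732 ug/day, exceeds EC limit: True
```

The synthetic survey spans sub-µg L⁻¹ totals for untreated almond drinks up
to >10 µg L⁻¹ for commercial soy; the Welch test confirms the built-in
commercial > homemade shift. An adult drinking one 200 mL serving of the
most contaminated commercial soy beverage daily accumulates an ILCR of
about 2.2 × 10⁻⁵ from its dominant HAA — above the 10⁻⁵ "moderate concern"
mark but below the 10⁻⁴ unacceptability threshold — while that single
serving already carries 2.7 µg of HAAs, breaching the 1 µg/day limit.

A full pipeline run (synthesis → validation → screening/optimization →
risk grid → statistics) is available from the shell:

```bash
haarisk --config config.yaml --out-dir out run   # writes report.json / report.md
```

with a minimal `config.yaml` of `{seed: 1, risk: {}}`.

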