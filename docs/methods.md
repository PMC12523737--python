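# Methods

This note documents the models, defaults and numerical choices behind
`haarisk`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Exposure and risk model

The risk chain is deliberately deterministic. Estimated daily intake is
`EDI = consumption × C` with the concentration converted from µg L⁻¹ to
mg L⁻¹ in a single helper (`risk.ug_per_l_to_mg_per_l`) so the unit
convention cannot drift between equations. Chronic daily intake is
evaluated in its full regulatory form `C·IR·ED·EF / (BW·AT)`; because the
package always derives `AT = ED × 365` days and fixes `EF = 365` days per
year, the expression collapses algebraically to `C·IR/BW`. Both routes are
kept: the full form for auditability, the collapse as a tested invariant
(agreement to 1 part in 10¹²). Cumulative risk assumes additive
carcinogenicity across co-occurring HAAs: `ILCR = Σ CDI·CSF·ADAF` over the
seven compounds with an oral slope factor. DMIP, 4,8-DiMeIQx and PhIP have
no validated slope factor; they contribute nothing to ILCR, are flagged in
every result, but still count toward the 1 µg day⁻¹ total-intake check,
which concerns total HAA burden rather than modeled risk.

Key parameters (all configurable):

| parameter | default | units | rationale |
|---|---|---|---|
| serving volume | 0.200 (0.250 optional) | L | typical PBMA serving |
| servings/day | 1–5 grid | — | recommended dairy-replacement range |
| body weight | 21 / 49 / 65 by age 5 / 13 / 84 | kg | standard age-group weights |
| exposure duration | 5 / 13 / 84 | yr | equals the age of each group |
| ADAF | 3 / 3 / 1 | — | ages 5 and 13 both fall in the 3–15-yr susceptibility window |
| risk bands | 10⁻⁶, 10⁻⁴ | — | regulatory negligible/unacceptable cut-offs |

The ADAF for the 13-year group is a genuine ambiguity: adolescents are
sometimes grouped with adults (factor 1). We default to 3 because 13 lies
inside the stated 3–15-year window, and expose the mapping in the config
so the alternative reading is one line away. The grid aggregates
replicates per (base, treatment) by arithmetic mean; a `max` mode provides
the worst-case reading.

## Censored concentrations

Values below the limit of quantification are never stored as measurements:
records carry the bound (LOD or LOQ) plus a flag. Totals substitute 0 by
default — conservative when totals are reported as ranges — with LOD/2
available as the other common convention. The policy is explicit in every
report.

## Method-validation calculus

Calibration lines are ordinary least squares of response on concentration
(≥ 5 distinct positive levels). `r²` is the squared Pearson correlation of
fitted vs observed responses. Lack of fit uses the replicate-based F-test,
`F = MS_LOF/MS_PE` with (L−2, N−L) degrees of freedom; when the test
rejects at α = 0.05 and more than five levels are available, the highest
level is dropped and the line refitted, fixing the linear-range upper
bound at the highest surviving level. The lower bound is the LOQ.

LOD and LOQ follow the signal-to-noise rule (3.3σ/slope and 10σ/slope).
The noise σ is, by default, the residual standard deviation of an
auxiliary fit over the three lowest levels — where trace-method noise is
actually measured — with a blank-replicate SD estimator as the
alternative; both are IUPAC-compatible and the choice is recorded in the
report. Recovery, enrichment factor, matrix effect and percent RSD are the
standard closed forms; the matrix-effect sign convention is positive =
suppression.

## Factorial screening and optimization

Effects of a full 2^k design are the classical contrasts
`mean(+1) − mean(−1) = (2/N)Σ sign·y`; the test suite proves equivalence
with a brute-force oracle over *all* 4⁸ integer-response 2³ designs.
Significance uses Lenth's pseudo-standard-error for unreplicated runs
(margin `t(0.975, m/3) × PSE`, α = 0.05, ties broken lexicographically by
term label) and center-point pure error (`SE = 2s/√N`, df = n_c − 1) when
at least two center runs exist. Which method applied is recorded in the
effect table.

Multi-response optimization uses Derringer–Suich desirabilities (linear
ramps, weight exponents, geometric-mean overall D) maximized by an
exhaustive deterministic grid search over the coded hypercube, 41 points
per factor by default, first occurrence winning ties. Surrogates are a
full quadratic fit by least squares (default, deterministic, requires at
least as many runs as coefficients) or a seeded single-hidden-layer
perceptron (8 tanh units, L-BFGS) for a neural-network-style fit. The
27-point training layout used in examples is a face-centered 3-level
composite (16 cube + 8 axial + 3 center points) — a standard geometry
able to identify all quadratic terms in four factors.

## Profile statistics

The commercial-vs-homemade comparison is Welch's t on per-sample total
HAA, chosen over the pooled-variance test because group sizes and spreads
differ; the 95% CI of the mean difference comes from the same Welch
machinery (cross-checked against an independent implementation in the test
suite). PCA runs on the autoscaled matrix by default since compounds span
two orders of magnitude; a center-only mode exists. Hierarchical
clustering is Ward (or average) linkage on Euclidean distances, with
cluster ids relabeled in first-occurrence order so results are
deterministic.

## What the generator emulates — and what it does not

The concentration generator draws
`C = base_profile × treatment_multiplier × synergy × LogNormal(0, σ)`,
with lognormal noise (σ = 0.25) because trace-level concentration errors
are non-negative and right-skewed. Default multipliers are H 1.0, HS 1.6,
HP 2.2, HSP = HS×HP, CSP = HS×HP×1.35, with a synergy factor 1.8 applied
only when sweetening and pasteurization combine — so HSP/CSP dominate any
single treatment, and commercial totals stochastically dominate homemade.
Base profiles weight pyrolytic amines in soy/peanut and thermal amines in
almond/cashew, anchored so that commercial-soy Trp-P-1 sits near 2.7
µg L⁻¹ and survey totals span roughly 0.1–14 µg L⁻¹; detection limits
default to 0.01–0.04 µg L⁻¹ (LOQs 0.02–0.05) so censoring arises naturally
in the untreated low-protein matrices.

Passing tests on this generator demonstrate *pipeline correctness under a
known truth* — matrix factors, factorial coefficients and the commercial
shift are all recovered within stated bounds — not agreement with any
particular real survey: real beverages have between-brand heterogeneity,
correlated compound levels, batch effects and non-lognormal tails that the
generator does not model. Per-compound treatment responses are also
uniform within a sample (one multiplier per treatment), whereas real
pasteurization shifts thermal and pyrolytic amines differently.

## Problem sizes and runtime choices

The default survey is 4 bases × 5 treatments × 3 replicates × 10 compounds
(600 records, 60 samples). Power statements use 200 replicate surveys;
the survey-range calibration uses ≥ 1000 sample totals; the optimization
examples use the 27-run design with a 41-point (reports: 21-point) grid.
These sizes keep every check closed-form-verifiable or completable in
seconds while leaving the estimators identical to what larger inputs
would use.

## Known limitations

* The exposure model is deterministic by design: no Monte-Carlo intake
  distributions, no toxicokinetics, no between-individual variability.
* ILCR covers only the seven slope-factor compounds; risk from DMIP,
  4,8-DiMeIQx and PhIP is structurally invisible to it.
* The lack-of-fit-driven linear-range trim cannot go below five levels,
  so strong curvature in a five-level series is flagged but not trimmed.
* Lenth significance is calibrated for effect sparsity; designs where
  most contrasts are active inflate the PSE and lose power.
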