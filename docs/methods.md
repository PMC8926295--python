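# Methods

## Scope and design

`thalscreen` separates four concerns:

* **records** — typed CBC/iron/HPLC records with explicit absence (a missing
  RDW is `None`, never a sentinel number) and a single CSV interchange
  format. Units are fixed: Hb g/dL, RBC ×10⁶/µL, MCV fL, MCH pg, MCHC g/dL,
  HCT %, RDW %, serum iron and TIBC µg/dL, HbA2 %. The reader performs no
  unit conversion; every index threshold assumes these units.
* **indices** — a frozen registry of 16 discriminant indices with formula,
  positivity direction and two cutoffs each (the defining publication's
  "original" cutoff and the antenatal study's ROC-derived "present" cutoff).
* **roc** — empirical ROC, AUC, Youden-optimal cutoff and
  printed-percentage inversion, all implemented directly (no statistics
  package stands behind them; scikit-learn appears only in the test suite as
  an independent oracle).
* **cascade / simulate / report / cli** — the screening program, the
  synthetic cohort generator and the reporting surface.

## Decision rules and boundary semantics

All threshold comparisons in the package are **strict**, matching the
`<`/`>` glyphs of published index tables: a Mentzer value of exactly 14.1
does not flag, a triage panel of exactly (MCV 80, MCH 27, Hb 11) does not
triage, a transferrin saturation of exactly 16% is not called iron
deficient. The HbA2 rule is the one place with inclusive bounds on both
sides — ≤ 3.5% normal, ≥ 3.6% BTT — leaving the open interval (3.5, 3.6)
as an explicit *equivocal* class routed to genetic testing. Chromatograms
are not parsed: a non-A2 variant is an input label (`variant_window`), and
it takes precedence over the HbA2 bands.

The iron-exclusion criterion is transferrin saturation < 16%, a standard
clinical convention chosen here because screening reports typically name
"serum iron and TIBC" without printing cutoffs; it is fully configurable,
with optional serum-iron and TIBC conjuncts.

The analyzer flag rule defaults to *Mentzer < 14.1 OR Sehgal < 971.55*. An
"any" rule is evaluated over its computable components; if none is
computable the result is a not-computable marker, never a silent negative.
Records missing an analyte an index requires are excluded from that index's
denominators and counted separately, so a missing RDW cannot bias an
RDW-free index's sensitivity.

## ROC construction

Candidate thresholds are midpoints between consecutive distinct observed
values plus ∓∞ sentinels — reproducible and independent of instrument
resolution. Each operating point is exactly the confusion matrix of the
strict rule at that threshold; the test suite asserts point-for-point
equality with a brute-force sweep. AUC is the trapezoid over
(1 − specificity, sensitivity) with vertical segments kept in path order,
which makes it identical (to 1e−12) to the pairwise concordance probability
with ties counted ½.

The Youden-optimal cut maximizes J = sensitivity + specificity − 100. Ties
are broken by higher sensitivity (a screening program prefers catching
carriers), then by proximity to a supplied reference cutoff, then by lower
threshold — fully deterministic.

`reconstruct_count` inverts a printed percentage to its integer numerator
over a known denominator. Published tables mix half-away-from-zero rounding
with truncation at 1–5 decimals (e.g. 41/43 = 95.349% printed as 95.34, and
42/43 = 97.674% printed as 97.6), so a count matches if *either* convention
reproduces the printed value at its printed precision; no match and multiple
matches are distinct outcomes (`None` / `AMBIGUOUS`). The package's own
output never needs this tolerance: it prints exact fractions alongside
percentages rounded half-away-from-zero at 2 decimals.

Confidence intervals (DeLong, bootstrap) and partial AUC are deliberate
extensions, not implemented.

## Synthetic cohort generator

The generator emulates the **enrolled** population of an antenatal
hemoglobinopathy screening study — women already satisfying the microcytic
hypochromic triage — as a four-class mixture with default weights
BTT 0.235, IDA 0.38, HPLC-normal 0.25, other-variant 0.135. The BTT weight
and the minority variant weight follow the modeled series' observed
fractions (23.5% and 13.1% of the chromatographed); the IDA/normal split of
the remainder is a design choice, since excluded iron-deficient women are
not enumerated in such reports.

Within a class, analytes are independent truncated normals. The BTT class
pins the modeled series' reported ranges and means: Hb (mean 8.9, bounds
7.8–10.8 g/dL), RBC (5.21, 3.82–5.89 ×10⁶/µL), MCV (65.12, 50.3–70.9 fL),
MCH (20.86, 13.2–27.1 pg), plus HbA2 4.8% bounded to [3.6, 7.0] so carriers
are HPLC-positive by construction. IDA, normal and other-variant parameters
are literature-typical and pinned in `simulate.default_config`: IDA has low
RBC (mean 3.9), high RDW (mean 18.5) and iron bounds (serum iron ≤ 55,
TIBC ≥ 360 µg/dL) that guarantee transferrin saturation < 16%; the normal
class is microcytic but iron-replete with HbA2 bounded to ≤ 3.5%.

Two parameterisation details matter:

* **The configured mean is the truncated mean.** With asymmetric bounds the
  truncated-normal mean shifts away from its location parameter (for the
  BTT MCV spec the shift would be ≈0.86 fL). The generator solves the
  location numerically (Brent's method on `scipy.stats.truncnorm.mean`) so
  sample moments converge to the configured means; `sd` remains the
  underlying normal's scale.
* **Derived analytes obey physical identities**: HCT% = MCV·RBC/10 and
  MCHC = 100·Hb/HCT, rather than being sampled independently.

Records are re-drawn until they satisfy the triage rule (the study's
inclusion criterion, `condition_on_triage=True` by default; the only
default-parameter class this clips is BTT MCH above 27 pg, about 0.7% of
draws). Class counts are multinomial in the mixture weights, or fixed
exactly via `class_counts` — `study_cohort()` uses this to reproduce the
modeled series' 43/24/116 composition. Spouse testing of carriers is a
Bernoulli accounting field (p = 0.5581), not a behavioral model. A single
seeded generator stream drives everything; record order is shuffled after
class assignment.

**What passing tests do not show about real data:** analytes are independent
within class, so real MCV–MCH correlation, analyzer noise, α-thalassemia
interactions, gestational-age effects and HbA2 assay variation are absent.
Index separations on these cohorts (Mentzer AUC ≈ 0.99 at n = 2000) are
cleaner than clinical series typically achieve; the generator's role is to
exercise the pipeline in the regime where index comparisons are meaningful
(AUC > 0.85), not to predict field performance.

## Known print artifacts in the modeled series

Recorded in `indices` module docs rather than reproduced: the series' prose
quotes a Mentzer sensitivity of 76.44% where its table prints 76.74 (the
table is treated as authoritative); "Ricera" is read as the Ricerca index;
the MCH original-cutoff row (sensitivity 36.2 at < 27) is internally
inconsistent with an all-MCH<27 inclusion cohort; and several printed
percentages are truncations rather than roundings of their underlying k/43
or k/116 fractions. Specificity denominators reproduce as k/116
(HPLC-normal women only), not k/140 — other-variant carriers sit in neither
ROC class.

## Problem sizes

The test suite and acceptance script use n = 183 for fixed-composition
accounting, n = 2000 (20 seeds) for cutoff-recovery checks, n = 10⁵ for
moment convergence, and 500 random cohorts of size ≤ 50 for exhaustive ROC
oracle equivalence — sizes at which every probabilistic band asserted (3σ
moment bands, binomial class-count bands, the [12, 16] Mentzer cutoff band)
has comfortable margin.

## England & Fraser constant

Several variants of the England & Fraser formula circulate; this package
fixes MCV − RBC − 5·Hb − 3.4. All 16 formulas are cross-checked in the test
suite against independently written expressions and against their algebraic
identities (Sehgal = Mentzer·MCV, MCHD·MCV = MCH, MDHL·MCV = MCH·RBC).
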