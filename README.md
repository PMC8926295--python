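# thalscreen

Antenatal screening for the β-thalassemia carrier state from ordinary
complete-blood-count (CBC) data: discriminant red-cell indices, from-scratch
ROC/Youden statistics, an executable screening cascade, and a synthetic
cohort generator so the whole pipeline is testable without patient data.

## The problem

β-thalassemia trait (BTT) is a symptom-free heterozygous carrier state, but a
couple of two carriers risks a severely affected child, so antenatal carrier
detection matters wherever carrier frequency is high. Carriers present with
microcytic hypochromic red cells — small (low MCV) and pale (low MCH) — a
picture shared with iron-deficiency anemia (IDA). The two are cheap to tell
apart *approximately* with arithmetic "discriminant indices" over CBC
analytes, and definitively with HbA2 quantification by HPLC, which is too
expensive to run on everyone. A practical program therefore stages the
work-up:

1. **CBC triage** — microcytic hypochromic anemia: MCV < 80 fL and
   MCH < 27 pg and Hb < 11 g/dL (all strict);
2. **iron studies** — transferrin saturation below 16% is treated as iron
   deficiency and excluded from chromatography;
3. **HPLC** — HbA2 ≤ 3.5% is normal, HbA2 ≥ 3.6% is BTT, the gap in
   between is equivocal (→ genetic testing), and a labeled non-A2 peak is
   another hemoglobin variant;
4. **analyzer flag** — a pop-up rule on the hematology analyzer
   (Mentzer index MCV/RBC < 14.1 **or** Sehgal index MCV²/RBC < 971.55)
   that alerts to samples which must not miss HPLC;
5. **spouse testing** of confirmed carriers.

`thalscreen` implements each stage as a library module plus a CLI, and
evaluates 16 published discriminant indices (Mentzer, RDWI, Shine & Lal,
Srivastava, Green & King, Sirdah, Ehsani, England & Fraser, Ricerca, MDHL,
MCHD, Sehgal, and the raw RBC count/MCV/MCH/RDW) against the HPLC reference
standard. For each index it reports sensitivity and specificity at the
published cutoff and at the cohort-specific Youden-optimal cutoff

    J = sensitivity + specificity − 100,  maximized over the empirical ROC,

with AUC computed by trapezoidal integration (equal to the rank/concordance
statistic with ties counted ½). Printed percentages come with their exact
fractions, so rounding ambiguities cannot creep into the output.

## Worked example

Generate a labeled synthetic cohort of 183 antenatal women, run the cascade,
and derive a Mentzer cutoff:

```sh
$ thalscreen simulate --n 183 --seed 42 --out cohort.csv
wrote 183 records to cohort.csv
$ thalscreen cascade --in cohort.csv --out summary.json
screened 183, HPLC run 124, carriers 49
$ thalscreen roc --in cohort.csv --index mentzer --out roc.csv
mentzer: AUC=0.9965 optimal threshold=14.37 (sens 95.92%, spec 100.00%)
```

`summary.json` contains the stage-by-stage accounting (abridged):

```json
{
  "n_screened": 183,
  "n_iron_deficient_excluded": 59,
  "n_hplc_run": 124,
  "n_btt": 49,
  "n_other_variant": 29,
  "n_normal": 46,
  "prevalence_btt": 39.516129032258064,
  "spouse_uptake": 44.89795918367347
}
```

All 183 simulated women pass triage (the generator emulates the *enrolled*
population), 59 are excluded as iron-deficient, and of the 124 reaching
HPLC, 49 are carriers — a 39.5% prevalence among the chromatographed, driven
by the mixture weights of the generator. `thalscreen report` produces the
full 16-row index-performance table; the first rows of seed 42:

```
index_id,threshold_original,sens_original_frac,threshold_derived,sens_derived_frac,spec_derived
mentzer,13.0,30/49,14.37158468760559,47/49,100.0
rdwi,220.0,41/49,214.82176391781434,41/49,86.96
shine_lal,1530.0,49/49,1110.3163218831364,48/49,95.65
```

Read: at the classical Mentzer cutoff <13 only 30 of 49 carriers flag, while
the Youden-optimal cutoff ≈14.4 on this cohort catches 47 of 49 at 100%
specificity — the reason screening programs re-derive cutoffs locally
instead of importing them.

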