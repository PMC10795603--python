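# vaconcord

Agreement evaluation for verbal autopsy (VA) cause-of-death coding.

In settings without routine medical certification, the cause of a death is
often inferred from a *verbal autopsy* — a structured interview with the
family about the signs and symptoms preceding death. The interview can be
coded by physicians (PCVA, often the reference standard) or by automated
algorithms (CCVA: InterVA-5, InSilicoVA, Tariff 2.0, ...). Before an
algorithm can replace physician coding in a vital statistics system, its
assignments have to be validated against the reference, both death by death
and at the level of the population's cause composition.

`vaconcord` is a toolkit for exactly that comparison. It is written for
burden-of-disease and CRVS (civil registration and vital statistics)
analysts who have a table of deaths with paired cause assignments and need
the standard stratified agreement report.

## What it computes

Deaths are first collapsed onto a short **analysis cause list** (by default
25 substantive causes plus a distinguished *undetermined* category), and
deaths the reference coder left undetermined are excluded before agreement
is measured. With `TP_j`, `FP_j`, `FN_j` from the reference-by-coder
confusion table, `C` the number of substantive causes and `N` deaths:

**Individual level**

- Positive predictive value: `PPV_j = TP_j / (TP_j + FP_j)`
- Sensitivity: `Sens_j = TP_j / (TP_j + FN_j)`
- Chance-corrected concordance: `CCC_j = (Sens_j − 1/C) / (1 − 1/C)`,
  reported as the unweighted mean over causes with reference deaths
- Overall agreement: fraction of deaths where the top cause matches, and a
  top-3 variant (reference cause among the coder's three highest-ranked
  causes, ignoring its indeterminate cutoff; undefined for single-cause
  coders)
- Cohen's kappa: `κ = (p_o − p_e) / (1 − p_e)` with observed agreement
  `p_o` and chance agreement `p_e` from the marginals, plus an agreement
  band label (None / Minimal / Weak / Moderate / Strong / Almost Perfect)

**Population level**, from the cause-specific mortality fractions (CSMFs)

- CSMF accuracy: `1 − Σ_j |CSMF_j^true − CSMF_j^pred| / (2 (1 − min_j CSMF_j^true))`
- its chance-corrected transform `(acc − 0.632) / (1 − 0.632)`
- Spearman rank correlation of the cause rankings (rank 1 = largest CSMF)

Everything is reported per coder for a standard stratum set: total, four
age groups (neonate 0–27 days, child 28 days–<12 y, adult 12–<50 y, elder
50+ y), both sexes, and in/out of health facility. A synthetic-cohort
generator with known confusion structure (`vaconcord.simulate`) makes the
whole battery testable end to end.

## Worked example

```python
import vaconcord as vc

# a study-shaped synthetic cohort: 5386 deaths, three coders
cohort = vc.generate(vc.default_spec(n=5386, seed=17))
results = vc.AgreementEvaluation(cohort).fit()
print(results.summary())
```

```
Agreement evaluation (reference vs automated coders)
records in: 5386   reference-undetermined excluded: 828   analysed: 4558

stratum         coder            n  OA top1%  OA top3%   kappa           band    CCC  CSMFacc    rho
total           interva5      4558      51.6      87.4    0.47           Weak   0.40     0.85   0.91
total           insilicova    4558      56.1      86.7    0.51           Weak   0.44     0.89   0.90
total           tariff2       4558      50.9         .    0.46           Weak   0.38     0.77   0.83
...
```

Reading the total-sample rows: the coders place the reference cause first
for 51–56% of deaths (top-1 overall agreement), rising to ~87% when any of
the top three ranked causes may match — `tariff2` emits a single cause per
death, so its top-3 cell is undefined (`.`), never zero. Kappa around 0.5
("Weak") says individual-level agreement beyond chance is modest, while
CSMF accuracy of 0.77–0.89 and rank correlations around 0.9 say the coders
reproduce the population's cause composition far better than they classify
individual deaths — the typical pattern for automated VA coding.

The same pipeline runs from the shell and composes:

```bash
vaconcord simulate --seed 17 --n 5386 --out cohort.csv
vaconcord evaluate --config run.yaml     # names cohort, cause list, output dir
vaconcord map-causes --in raw.csv --map icd2va.csv --cause-list analysis25.csv --out mapped.csv
```

Outputs: a wide report CSV (one row per stratum × coder, display-rounded),
a tidy long CSV and JSON at full precision, per-cause PPV/sensitivity/CCC
tables, CSMF comparison tables (descriptive mode including undetermined,
and post-exclusion agreement mode), the redistribution of
reference-undetermined deaths over coder causes, and per-coder confusion
tables.

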