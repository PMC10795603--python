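# Methods

## Problem setting

A verbal autopsy (VA) validation study yields one row per death with a
reference cause (physician-coded VA) and one or more automated coders'
assignments. The package quantifies agreement between each automated coder
and the reference on a collapsed analysis cause list, stratified by age
group, sex and place of death. Two levels are deliberately separated:
individual-level metrics ask "did the coder get *this* death right?",
population-level metrics ask "does the coder reproduce the cause
composition of the population?". Automated coders routinely do much better
at the second than the first, and the report is designed to show both.

## Cause list and mapping

The analysis list is an ordered set of substantive causes plus at most one
*undetermined* category. `C` — the cause count entering the
chance-correction terms — counts substantive causes only (the default list
has `C = 25`). Mappings (e.g. ICD-10 → WHO VA list → analysis list) are
many-to-one tables; composition is supported so a chain of tables collapses
to one lookup. Unmapped codes are a hard error by default; an explicit
option routes them to undetermined with a logged warning, because silent
coercion hides gaps in user-supplied mapping tables.

## Filtering and stratification conventions

- Reference-undetermined deaths carry no information about coder
  performance, so they are removed before any agreement metric. Their
  *redistribution* — where each coder sends those deaths — is reported
  separately, as is the descriptive CSMF comparison computed before the
  exclusion with undetermined included.
- Coder-side undetermined is retained as an extra confusion-table column:
  it counts as disagreement with every substantive reference cause and
  enters the kappa marginals, but has no PPV/sensitivity/CCC of its own.
- Age groups: neonate 0–27 completed days, child 28 days to under 12
  years, adult 12 to under 50, elder 50+. Ages are stored with their unit;
  1 year = 365.25 days. The four groups tile the age axis, so the stage
  ledger `rows_in = rows_excluded + Σ age-stratum rows` is asserted on
  every run.
- Records with unknown sex or place stay in the total stratum and drop out
  only of the corresponding sex/place strata, with counts logged.

## Metric conventions

- **Proportion CIs** (PPV, sensitivity, overall agreement): Wald interval
  truncated to [0, 1], per the simple-proportion convention; Wilson is
  available by option. Undefined denominators (a cause never predicted, a
  cause with no reference deaths) yield explicit nulls with reason codes,
  never zeros — this distinguishes a coder that *cannot* emit a cause from
  one that always misses it.
- **CCC aggregation**: the single CCC per coder/stratum is the unweighted
  mean over causes with ≥ 1 reference death. Unweighted is the common
  choice in the VA-metrics literature because it stops a dominant cause
  from masking failure on rare ones; the per-cause vector is always also
  emitted.
- **Kappa**: computed over the union of reference and coder categories
  (coder undetermined has a zero reference row). The CI uses the
  large-sample Fleiss–Cohen–Everitt variance; the test suite cross-checks
  both value and variance against statsmodels. The interpretation bands are
  published with gaps at the second decimal (.20 | .21, .39 | .40, ...);
  they are implemented as contiguous half-open intervals with cut points at
  the gap midpoints (0.205, 0.395, 0.595, 0.795, 0.905) so every value in
  [−1, 1] gets exactly one label; the convention is recorded in the report
  metadata.
- **Top-3 agreement** uses the ranked causes *ignoring* the coder's
  indeterminate cutoff. Coders that produce a single cause per record are
  rejected for this metric (`UnsupportedCoderError` / a null cell with
  reason) rather than silently scored at depth 1.
- **CSMF accuracy in agreement mode** runs on the post-exclusion cohort
  with the coder-side undetermined kept as an extra component (its
  reference fraction is 0 there). Including it penalises coders that park
  mass on undetermined, which is the behaviour being measured; descriptive
  mode (pre-exclusion, undetermined included for both sides) is reported
  separately, and the mode is stamped in the output metadata.
- **Spearman rho** ranks substantive causes only (rank 1 = largest CSMF,
  ties averaged) and is the Pearson correlation of the rank vectors. The
  CI uses Fisher's z with rank-correlation variance 1.06/(C−3). A constant
  rank vector (all CSMFs equal) gives an undefined result, not 0.
- Display rounding (percentages to 1 decimal, proportions to 2) is applied
  only in the wide report and `summary()`; tidy CSV and JSON always carry
  full precision, so rounding never destroys testability.

## Synthetic cohort generator

The generator emulates the structure of a national VA validation sample:

- **Strata.** Deaths are drawn from the product of the age, sex and place
  margins of a 5386-death sample (102/204/2018/3062 by age; 2579 F /
  2807 M; 2926 in / 2460 out of facility). The defaults treat the three
  margins as independent, which is the simplest distribution consistent
  with the published marginal counts.
- **True causes.** Each stratum has a CSMF over the 25 substantive causes.
  The all-ages baseline is anchored to published fractions (HIV/AIDS 0.22;
  broad groups: HIV/TB 28.1%, other infectious/maternal/perinatal/
  nutritional 8.8%, non-communicable 34.6%, injuries 12.6%) renormalised to
  the substantive universe; age and sex profiles are obtained by
  multiplicative tilts (e.g. maternal causes zeroed for males and removed
  outside 12–49 y, infections up-weighted in children, non-communicable
  causes in elders) and renormalisation. Neonates are concentrated on
  perinatal causes (0.92) with a thin scatter of infections — concentrated
  rather than fully degenerate, since a stratum with literally one
  reference cause makes kappa 0/0-undefined. Stillbirth carries zero true
  mass, but coder confusion can still emit it.
- **Reference error** is modelled only as the undetermined mechanism
  (default probability 0.158 in every stratum, matching the published
  overall fraction; per-stratum values are a free parameter): the
  reference is the standard, so it gets no misclassification of its own.
- **Coder error** is a row-stochastic confusion matrix `M` per coder:
  true cause → distribution over assigned causes including an undetermined
  column. The three default coders mimic the published algorithm types: a
  deterministic propensity coder with a 10% indeterminate column and
  3-deep rankings; a probabilistic coder that always assigns (no
  undetermined) with slightly higher diagonals; and a single-cause score
  coder with an 18% indeterminate column and two structural gaps (causes
  it can never emit). Diagonals are shaped like the observed pattern —
  transport injuries ≈ 0.95, HIV high, pneumonia / other infectious /
  renal failure poor — and put overall expected agreement near 0.5.
- **Rankings and scores.** The ranked list is drawn by Gumbel top-k from
  the substantive part of `M[true]` — an exact without-replacement
  ordering whose first element follows the renormalised row — and
  synthetic propensity scores decrease down the list, anchored at the
  assigned cause's `M` probability with Gaussian noise (`score_noise`,
  default 0.08). Only the ordering and threshold behaviour of the scores
  can affect any metric, so their distributional family is a free choice.
- **Indeterminate mechanisms.** By default the indeterminate mass lives in
  `M`'s undetermined column (`indeterminate_threshold = 0`), which keeps
  the closed-form expectations exact. Setting a positive threshold instead
  relabels low-score top causes as undetermined (a likelihood-cutoff
  analogue, e.g. 0.4); the expectations then become approximate.

`expected_metrics` returns the analytic values implied by a spec — per-cause
sensitivity = diag(M), coder CSMF = pᵀM, overall agreement = Σ p_j M_jj,
kappa from those marginals, CSMF accuracy of pᵀM vs p — computed on the
post-exclusion population (strata with higher undetermined fractions
contribute proportionally less). These are the oracles the recovery tests
check against, within 3 Monte-Carlo standard errors at n = 5000.

What passing these tests shows — and does not. The generator reproduces
the stratified confusion-mixture structure the metrics assume, so the
tests validate the estimators, the exclusion logic and the report
plumbing. It does not simulate symptoms, interview quality or narrative
text, so nothing here validates any actual coding algorithm; real CCVA
errors are correlated with symptom patterns in ways a fixed confusion
matrix cannot express.

## Numerical and degenerate-input choices

- CSMF accuracy is clipped only for floating-point excursions beyond
  [0, 1]; a degenerate reference (all mass on one cause) makes the
  denominator 0 and is rejected.
- Kappa with `p_e = 1` (single category on both sides) is undefined and
  reported as a null with reason, as are empty strata, empty denominators
  and single-cause coders at top-3.
- All randomness flows from one `numpy` Generator seeded by the spec;
  identical spec + seed reproduces cohorts and reports byte-for-byte.
- Problem sizes in the test suite: the oracle-equivalence battery uses
  1000 random cohorts of 5–40 deaths over 3 causes; recovery tests use one
  cohort of 5000 deaths over the 25-cause list — large enough for 3-SE
  Monte-Carlo bands to be meaningful, small enough to keep the suite quick.

## Known limitations

- PCVA is treated as the reference standard; an optional reference
  confusion matrix for robustness experiments exists in the design but the
  default (and the metrics' interpretation) assumes reference correctness
  up to the undetermined mechanism.
- The Wald intervals can be anti-conservative for proportions near 0 or 1
  at small n; use the Wilson option there.
- The kappa CI is asymptotic; no exact or bootstrap interval is provided.
- No uncertainty is attached to CCC or CSMF accuracy (no bootstrap /
  Dirichlet posteriors), matching common reporting practice for these
  metrics.
- Weighted kappa, multi-rater (Fleiss) kappa and partial/hierarchical
  cause credit are out of scope.
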