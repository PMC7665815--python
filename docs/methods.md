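# Methods

## Scope and model

`lirads_dta` reproduces a single-center diagnostic-accuracy study of
LI-RADS v2018 on gadoxetate disodium-enhanced liver MRI: 792 untreated
hepatic observations (one analyzed lesion per patient; tumor-in-vein
excluded upstream) with a reference diagnosis of HCC (n = 508), non-HCC
malignancy (n = 55) or benign lesion (n = 229).  Three components carry the
science:

1. a deterministic **categorization engine** implementing the v2018
   decision rules;
2. six **category-adjustment conditions** that upgrade or demote
   observations relative to the baseline categorization;
3. **paired diagnostic-accuracy statistics** scoring each rule's LR-5 (or
   LR-4/LR-5) positivity against HCC truth.

### Categorization engine

Evaluation order for one observation: benignity gates (definitely benign
→ LR-1, probably benign → LR-2); targetoid gate (rim arterial-phase
hyperenhancement or any other targetoid feature → LR-M); the v2018
major-feature table; ancillary-feature adjustment; optional reader
override.

The major-feature table uses effective APHE (absent/nonrim), size, and the
count of additional major features (nonperipheral washout, enhancing
capsule, threshold growth):

| effective APHE | size | features | category |
|---|---|---|---|
| absent | < 20 mm | 0–1 / ≥2 | LR-3 / LR-4 |
| absent | ≥ 20 mm | 0 / ≥1 | LR-3 / LR-4 |
| nonrim | < 10 mm | 0 / ≥1 | LR-3 / LR-4 |
| nonrim | 10–19 mm | 0 / capsule only / washout or growth | LR-3 / LR-4 / LR-5 |
| nonrim | ≥ 20 mm | 0 / ≥1 | LR-4 / LR-5 |

Size bins are half-open (<10, [10, 20), ≥20 mm): 20 mm falls in the ≥20
row.  Threshold growth under v2018 is ≥50% size increase within ≤6 months
(boundaries inclusive); a ≥100% increase over >6 months and a new ≥10 mm
nodule within 24 months are subthreshold (they were threshold growth under
v2017, which is the engine's other growth dialect).  Ancillary adjustment:
≥1 malignancy AF and no benignity AF upgrades one category capped at LR-4
(LR-5 is never reachable through AFs); ≥1 benignity AF and no malignancy
AF downgrades one category; both present, no change.  An LR-3 → LR-4
ancillary upgrade is flagged (`upgraded_from_lr3`) because such
observations are ineligible for the AF-based upgrade conditions.

A second, literal transcription of the same table (`table_cell_oracle`, a
30-cell lookup) exists only so tests can compare the rule logic against an
independent rendering over the exhaustive feature grid.

### Adjustment conditions

Each condition is evaluated independently from the default baseline, never
stacked:

- **C1 / C2** (flag-based): baseline LR-4 observations with ≥1 qualifying
  AF (C1: any malignancy AF; C2: HCC-specific AFs only — nonenhancing
  capsule, nodule-in-nodule, mosaic architecture, blood products,
  intralesional fat), no benignity AF and no LR-3 provenance become LR-5.
- **C3**: recompute with APHE readable from the arterial subtraction
  image.  A GLOBAL subtraction pattern counts as nonrim APHE and overrides
  both an ABSENT and a RIM ordinary reading (so a falsely targetoid
  observation can re-enter the major-feature pathway); a RIM subtraction
  pattern never rescues anything.
- **C4**: recompute with washout masked whenever effective APHE is absent.
  The three reader-overridden LR-5 observations whose override is
  annotated washout-dependent are demoted one category to LR-4.
- **C5**: recompute with washout defined as portal-venous washout OR
  transitional-phase hypointensity.  When TP hypointensity is consumed as
  washout, the TP-hypointensity ancillary feature is removed for that
  evaluation so one finding is not counted twice.
- **C6**: recompute under the v2017 growth dialect; a growth record
  promoted to threshold similarly sheds its subthreshold-growth AF.

Recomputed conditions are clamped to the direction they are defined to
act: C3/C5/C6 extend the evidence for malignancy features and never lower
a category, C4 only removes a feature and never raises one, and no
condition re-opens observations already resolved as LR-1/LR-2.  The clamp
matters in corner cases the cohort model can produce but the engine's
blank-slate recomputation would mishandle — e.g. dropping the consumed TP
ancillary feature under C5 can leave a benign-only AF balance that would
otherwise downgrade an observation as a side effect of a
washout-extending condition.

### Statistics

Sensitivity, specificity, PPV, NPV and accuracy are ratios of confusion
counts with exact Clopper-Pearson 95% intervals (beta-quantile form;
closed at 0 and 1).  The PPV/NPV interval method in the original software
is unknowable; Clopper-Pearson is applied uniformly here and PPV/NPV
intervals are therefore not reproduction targets.  Paired rules are
compared with the exact two-sided McNemar test on discordant pairs,
p = min(1, 2·P(X ≤ min(b, c))) with X ~ Binomial(b+c, ½) and p = 1 when
b + c = 0; an asymptotic variant is available but not the default.  A
binary rule's ROC has two operating points, so its trapezoidal AUC equals
(sensitivity + specificity)/2; AUCs of two rules on the same subjects are
compared with the DeLong placement-value covariance estimator computed on
the 0/1 scores (ties half-counted, which is exactly the two-point ROC),
z = ΔAUC/√var, two-sided normal p.  P-values display as three decimals
with `<0.001` / `>0.999` end caps; percentages display half-up to one
decimal, with full precision retained in the JSON sidecar.

## Reference cohort reconstruction

No per-observation data are deposited, so the cohort is reconstructed
deterministically from the published counts.  It is assembled from ~38
named strata — groups of identical feature vectors — each designed to land
in one baseline category and respond to a known subset of conditions.
Constraints come in two tiers:

- **HARD** (must hold exactly): class totals; the baseline distribution
  116 LR-1, 52 LR-2, 63 LR-3, 73 LR-M, 117 LR-4 (107 HCC), 371 LR-5
  (365 HCC); and each condition's LR-5 true-positive/true-negative pair
  (C1 448/270, C2 401/277, C3 378/278, C4 362/278, C5 384/275,
  C6 380/278).
- **SOFT** (narrative; logged if violated): 81 no-APHE HCCs of which 77
  with portal-venous washout and 16 with global subtraction enhancement;
  76 HCCs without washout of which 39 TP-hypointense (20 LR-4, 16 LR-5,
  3 LR-M); 34 subthreshold-growth observations (30 HCC; 26 LR-4, 8 LR-5);
  3 washout-dependent demotions under C4.

Where the source's narrative and its accuracy table disagree (LR-4/LR-5
split 118/370 vs 117/371; eligible C1 upgrades 83 vs 91; C2 36 vs 37;
C3 recategorizations 14 vs a net of 13), the accuracy table wins — its
cells are the reproduction surface — and the narrative values are kept as
SOFT constraints that report a logged deviation rather than disappearing.
`validate_constraints` re-derives every count by running the engine and
all six conditions; expected values live only in the versioned
`resources/constraints.yaml`, never in the evaluation path.

Choices the published counts do not pin down, made once and documented:

- The six baseline LR-5 false positives split 4 non-HCC malignancy /
  2 benign; the ten LR-4 non-HCC observations split 6 / 4.
- Three baseline LR-5 observations cannot be derived from the strict
  v2018 table (they lack APHE); they are encoded as reader overrides
  annotated washout-dependent, which is also the mechanism that lets C4
  demote exactly three observations.
- One of those three carries a GLOBAL subtraction pattern so the
  16 subtraction-enhancing no-APHE HCCs coexist with the 13 net C3
  upgrades (12 LR-4 → LR-5 plus one LR-M → LR-5); under C3 its override
  keeps it LR-5, producing no move.
- "No APHE" in the narrative constraints means an ABSENT ordinary
  arterial reading; rim-APHE observations are not counted among the 81.
- Unconstrained cells (e.g. how LR-3 and LR-M split across non-HCC
  classes) use a fixed documented allocation; any allocation satisfying
  the HARD set would do.
- HCC sizes honor the printed distribution (5 under 10 mm, 90 at
  10–19 mm, 413 at ≥20 mm); sizes otherwise carry no information beyond
  their bin.

The cohort is bit-identical across runs and platforms: no randomness,
stable stratum and record ordering.

## Simulator

`simulate_cohort` draws arbitrary cohorts from a diagnosis-conditional
feature model (class prevalences 508/55/229 by default; per-class
probabilities for APHE pattern, subtraction rescue, washout, TP/HBP
hypointensity, capsule, growth-record form, per-feature AF inclusion, and
the benignity gates).  Defaults mirror the study's marginals where stated
— 84% of HCCs show APHE, 85% portal-venous washout, about one in five
no-APHE HCCs lights up on subtraction — and otherwise use values a liver
radiologist would call unremarkable.  Features are drawn independently
within class, so the simulator reproduces marginal frequencies, not the
correlation structure of real lesions (a lesion's washout and capsule
status are not independent in life); passing property tests on simulated
cohorts therefore demonstrates the rule system's invariants (direction of
each condition, nesting of C1/C2, audit conservation), not clinical
performance.  Validity constraints are enforced by construction: a
recorded ancillary feature always has its underlying finding present.

## Numerical and procedural choices

- Exact interval via `scipy.stats.beta.ppf`; the test-suite oracle solves
  the binomial tail by bisection instead.
- Exact McNemar via the binomial CDF; cross-checked in tests against
  statsmodels' exact implementation.  DeLong is implemented directly (no
  installed package exposes the paired form) and cross-checked against a
  nested-loop transcription of the covariance formula.
- Identical rules short-circuit to ΔAUC = 0, p = 1; a non-positive
  variance estimate with a nonzero ΔAUC yields an infinite z and p = 0.
- Zero denominators flag the affected metric as undefined (NaN) rather
  than failing the report.
- Rounding for display is decimal half-up (so 0.0078125 prints as 0.008
  and 71.85 % as 71.9 %); re-running the pipeline on identical input
  produces byte-identical report files.
- Problem sizes in the test suite: the 792-observation reference cohort
  throughout; property tests use one seeded 2,000-observation simulated
  cohort, interval coverage uses 2,000 binomial replicates at n = 50, and
  parameter recovery one 10,000-observation cohort — ample for 3-standard-
  error checks while keeping the suite fast.

## Known limitations

- The engine covers untreated observations without tumor-in-vein; LR-TIV,
  treatment-response categories and CT-specific criteria are out of scope.
- The reconstructed cohort is one member of the family of cohorts
  consistent with the published counts; per-observation agreement with the
  original data is neither claimed nor checkable.
- The published AUC for the HCC-specific-AF condition (0.886) contradicts
  its own printed sensitivity/specificity row, which implies
  (0.789 + 0.975)/2 = 0.882; this package reports the arithmetically
  consistent value.
- PPV/NPV interval methods may differ from the original software (see
  above).
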