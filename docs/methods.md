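# Methods

This note documents the statistical procedures implemented in `rppasig`,
the assumptions behind them, the synthetic-data generator used to verify
them, and the numerical and design choices that were genuinely open.

## Data model

The pipeline operates on three tabular objects:

* **Clinical table** — one row per patient: hormone-receptor (`hr`) and HER2
  status (`pos`/`neg`), the derived receptor subtype (HR+HER2−, TN,
  HR+HER2+, HR−HER2+; TN = HR−HER2−), treatment arm, binary pCR, optional
  DRFS time (years) and event indicator, and the array batch label. The
  subtype is a pure function of (hr, her2); DRFS time and event must be
  jointly present; arm labels must come from a declared arm list.
* **Spot table** — long-format triplicate spot intensities per
  (patient, array, analyte): `primary`, `negative_control` and
  `total_protein` spot types, replicate indices 1–3, nonnegative finite
  intensities in arbitrary fluorescence units. Exactly three primary
  replicates per (patient, array, analyte) are required.
* **Endpoint matrix** — patients × analytes of quantified (later
  z-scored) values. `NaN` marks cells masked because an analyte was not
  measured for a patient/array; masked cells are never imputed — each
  downstream analysis drops them per-analysis. Dash glyphs in phospho-site
  names (unicode minus, en/em dash) are normalized to the ASCII hyphen at
  import, since external exports mix them. Patient and analyte names are
  case-sensitive exact keys.

File dialects: clinical CSV (`patient_id, hr, her2, arm, pcr, drfs_time,
drfs_event, array_id[, mp, rps5]`), spot TSV (`patient_id, array_id,
analyte, spot_type, replicate_index, intensity`), wide matrix TSV (first
column `patient_id`, missing cells `NA`). All readers/writers round-trip to
at least 1e−12 relative precision. A column-name schema map on the clinical
reader absorbs external export vocabularies.

## Quantification

Per sample and endpoint: (1) subtract the negative-control spot intensity
from the primary spot intensity, pairing spots by replicate index; (2)
average the three net intensities; (3) divide by the sample's total-protein
value, itself the mean of the three Sypro replicate spots. Pairing by
replicate index and mean-level subtraction give identical averages; the
pairing is stated for definiteness. Negative net signals are **retained**:
the downstream standardization is location-scale based and flooring at zero
would bias low-expressing samples. No log transform is applied at this
stage; harmonization consumes the ratio scale. A non-positive total-protein
value is a degenerate-sample error naming the patient. When an analyte has
no dedicated negative-control spots, the patient's negative-control
replicates averaged over analytes serve as the background.

## Batch harmonization

Arrays are accrued sequentially, so array and calendar time are confounded
with case mix; per-(array, analyte) additive and multiplicative effects are
removed by standardizing each array against a common reference population
before combining:

1. draw B subsamples of the array's patients, each holding the receptor
   subtype mix at fixed reference proportions (0.384 / 0.368 / 0.158 / 0.09);
2. per endpoint, compute μ = mean of the B subsample means and σ = mean of
   the B subsample SDs (n−1 denominator);
3. z-score the endpoint as (x − μ)/σ.

Defaults and rationale:

* **B = 5000** subsamples.
* **Subsample size** is not dictated by the procedure's description; the
  default is 80% of the array's patients, drawn **without replacement**
  within subtype strata — subsetting at a fixed subtype balance is the
  natural reading of "sampling, maintaining a balance", and at B = 5000 the
  resulting moments are insensitive to the exact fraction.
* **Stratum sizes** follow largest-remainder rounding of `m · proportions`,
  capped at the stratum population; remainder ties break by subtype order.
  A required stratum with no patients on an array is an error naming the
  array and subtype.
* The reference proportions are fixed constants, not recomputed from any
  subset of the data.
* **σ floor**: degenerate (near-constant) endpoints have σ floored at 1e−8
  with a logged warning; they are flagged, never dropped.
* Subsampling is per array; each array's sampling stream derives
  deterministically from the run seed, so a fixed seed gives a bit-identical
  harmonization model.

Two exact properties anchor the implementation: with empirical proportions
and subsample fraction 1 the procedure collapses to plain per-array column
z-scoring, and any per-(array, analyte) affine transform `a·x + c` (a > 0)
of the raw endpoints leaves the harmonized values invariant when the same
subsamples are drawn.

## Association screens

Biomarkers are analyzed individually in adjusted logistic models:
population-wide `pCR ~ biomarker + HR + HER2 + arm`; within arms
`pCR ~ biomarker + HR + HER2` with HR/HER2 included only when both levels
are present in the arm; within subtypes `pCR ~ biomarker + arm`. The test is
the likelihood-ratio statistic of the biomarker term against the
covariate-only model, referred to χ²(1). BH adjustment is applied within
each screen family (one family per scope); `significant` = BH p < 0.05,
`nominal` = raw p < 0.05.

Fitting uses iteratively reweighted least squares with a deviance-based
stopping rule (R `glm` behavior). Under quasi-separation in a *nuisance*
dummy (e.g. a tiny arm whose patients all respond) the log-likelihood
plateaus at its finite limit and the biomarker LR statistic remains
well-defined; only a diverging biomarker coefficient or true
non-convergence flags a record, and flagged records are excluded from BH
families with a logged warning. Scopes with fewer than 10 patients or a
single-class response are skipped. Analytes need ≥80% unmasked coverage in
the scope to be tested.

Between-group differential expression (e.g. one cluster versus the rest)
uses the analogous Gaussian linear-model likelihood ratio of the group term,
`LR = n · log(RSS_reduced / RSS_full)` with df = number of group dummies,
BH within the screen.

## Clustering

Patient-wise distance is `1 − Pearson r` over the analytes two patients
share (pairwise-complete under masks), with complete linkage. The `1 − r`
convention (range [0, 2]) is required for the fixed cut height 1.54 to be
meaningful; `(1 − r)/2` would place it off-scale. A patient must share at
least 30 analytes with every other patient or is excluded with a warning;
a zero-variance profile is an error naming the patient.

The linkage is scipy's complete-linkage agglomeration; on tie-free inputs it
coincides with the textbook O(n³) procedure (verified against an exhaustive
oracle in the tests). The dendrogram cut keeps merges with height strictly
below the threshold; clusters are numbered 1..K in dendrogram (leaf-order)
appearance. A cluster can be refined by cutting its subtree into its k
top-level branches; sub-labels `<id>a`, `<id>b`, … follow leaf order. This
operationalizes the published post-hoc "coherent subgroup" split as a
deterministic k = 2 subtree cut. Analyte-wise clustering for display reuses
the same operations on the transposed matrix and carries no analytical
contract.

## Survival

Kaplan-Meier product-limit curves describe DRFS; Cox proportional-hazards
models with **Efron** tie handling estimate hazard ratios, with Wald 95%
intervals and likelihood-ratio p values (the LR choice matches the
association module; Wald p is retained alongside, selectable by a logged
flag). Times are in years; administrative censoring is the caller's (or the
generator's) responsibility. A monotone partial likelihood — no events in
one exposure group — yields a *flagged* fit with an infinite confidence
bound instead of a crash; flagged fits never enter BH families. The
per-cluster analysis fits pCR as the exposure within each cluster; the
analyte screen fits each z-scored analyte within each cluster's
non-responders, adjusting for HR and HER2, with BH per cluster. Clusters
with fewer than 10 non-responders or 3 events are skipped. The partial-
likelihood optimizer runs at 1e−9 step precision so small-sample
coefficients agree with a grid oracle to 1e−4.

## HARPS

Cut points for phospho-EGFR Y1173 and phospho-ERBB2 Y1248 are derived
independently by Youden-index ROC against pCR in the derivation cohort
(default filter: TN subtype, neratinib arm; at least 10 patients and both
response classes required), on the **harmonized** scale — the signature is
extrapolated to the full normalized TN set, so cuts must live on that scale.
Candidate thresholds are the midpoints between consecutive distinct values
plus ±∞; positivity is `value ≥ cut`; ties in J break toward the lowest
cut. The combination rule is the AND of the two single-marker positives
(operationalizing co-activation); the rule identifier is stored in the
serialized model so alternative rules can be added without breaking the
format. Patients with a masked marker get a missing status, logged.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Cohort**: multinomial subtypes at the reference proportions; arm
  allocation from static weights restricted to each patient's HER2-eligible
  arms (HER2-targeted arms take HER2+ only; PARP/immune arms HER2− only);
  arrays assigned by contiguous thirds in accrual order, mimicking
  sequential accrual.
* **Latent signaling**: per patient × analyte a standardized value
  `z = √ρ·u_block + √(1−ρ)·ε` (pathway blocks of 10 analytes, ρ = 0.5 by
  default) plus subtype mean offsets (HER2+ subtypes express the two HER
  phospho-markers ~1 SD higher).
* **Response**: `pCR ~ Bernoulli(expit(baseline(subtype) + Σ β_k z_k))`.
  Baseline rates 0.18 / 0.40 / 0.38 / 0.62 for HR+HER2− / TN / HR+HER2+ /
  HR−HER2+ (the HR+HER2+ value is the package's own choice, between the TN
  and HR−HER2+ rates, consistent with HER2-targeted response). Five planted
  analytes carry |β| = 0.6 on the logit: the two HARPS markers (+0.6 each,
  pathway block 0) and three analytes at the starts of distinct later
  blocks (−0.6, +0.6, −0.6) — block starts so that within-block correlation
  cannot cancel a planted marginal effect against an oppositely signed
  block-mate.
* **Survival**: exponential DRFS with hazard `λ0 · HR_pCR^pcr`
  (λ0 = 0.06/year, HR_pCR = 0.25), administratively censored at 5 years —
  5-year DRFS ≈ 0.74 for non-responders and ≈ 0.93 for responders, in the
  range reported for neoadjuvant cohorts.
* **Intensities**: `I = s_au · (exp(σ_z · z) · a_batch + c_batch) · tp + bg`
  with σ_z = 0.35 (log-normal intensities: fluorescence is positive and
  right-skewed), intensity scale 500 a.u., multiplicative batch factor
  `a ~ exp(N(0, 0.2))` and additive offset `c ~ N(1.0, 0.5)` per
  (array, analyte), per-patient total-protein loading `tp ~ exp(N(0, 0.3))`,
  background 150 a.u., and 3% multiplicative replicate CV on every spot.
  The noise scales were set by a noise-budget analysis: replicate noise is
  proportional to the *total* spot intensity (signal + batch pedestal +
  background), and these defaults keep the per-analyte correlation between
  harmonized values and latent truth above 0.9 at the default conditions.
  A nonnegativity clip guards the intensity floor (~0.002% of spots at the
  defaults).
* **HARPS derivation cohort**: a dedicated TN generator plants a step
  response at z = 0.7 on *both* markers by making the two markers
  concordant — marker 2 is drawn truncated-normal on the same side of the
  cut as marker 1, so their positivity indicators agree (co-activation) and
  each marker individually separates responders. This makes "the recovered
  cut brackets the planted one at data resolution" a well-defined property;
  an AND- or OR-structured response instead leaves the single-marker Youden
  estimate biased or random-walk noisy. Optional label-flip noise is
  available (default 0).

What the generator does **not** emulate: adaptive randomization (weights
are static), analyte-specific antibody effects, spatial array artifacts,
non-exponential hazards, informative censoring, or missing-at-random spot
dropout. Passing tests therefore demonstrate correctness of the procedures
under the assumed structure, not robustness to violations of it.

All randomness flows from a single run seed through deterministically
derived per-stage streams; a fixed seed makes the generator, the
harmonization model and the full pipeline byte-reproducible.

## Verification problem sizes

The test suite verifies the primitive procedures against independent
oracles (naive O(n³) agglomeration on 8-point instances, exhaustive Youden
enumeration, the literal BH step-up, hand product-limit curves on all
≤6-subject cases with ≤1 tie, 1-D grid partial-likelihood maximization on
4-subject datasets) and the end-to-end contracts at the default study scale:
736 × 139 × 3 arrays with B = 5000 for harmonization recovery and screen
power, 200 independent null analytes (B = 500) for the screen's type-I
error, n = 2000 for survival parameter recovery, n = 150 for signature cut
recovery, and a 120-patient pipeline for byte-level determinism. The
acceptance script (`scripts/acceptance.py`) re-runs all of these from a
single seed and reports the measured quantities.

## Known limitations

* The balanced-subsample size is a design choice (80% without replacement);
  the published description fixes only B and the subtype balance.
* Whether the original sub-split of the large mixed cluster is exactly the
  k = 2 subtree cut is not stated in the source material; the implementation
  documents its split as a deterministic operationalization.
* The analyte-DRFS screen offers LR or Wald p values behind a logged flag;
  the two agree asymptotically but differ in small clusters.
* GEO SOFT / series-matrix files are not parsed natively; deposited data
  enter through the documented plain-matrix + clinical-CSV path.
* On synthetic data the default dendrogram cut yields few clusters — the
  ten-cluster signaling architecture is a property of the real cohort's
  correlated pathway structure, which the block-correlation model only
  sketches.
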