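# Methods

## Score definition

The phenotype risk score for patient *i* is

    PheRS_i = Σ_p  x_ip · w_p,        w_p = log(1 / f_p),

where x_ip ∈ {0, 1} indicates lifetime presence of phenotype feature *p*
(at least one of the feature's version-qualified ICD codes anywhere in the
patient's record — no time window, because the presence rule is a lifetime
occurrence rule) and f_p is the feature's frequency in the training
population. Frequencies are continuity-corrected with a symmetric
pseudocount a:

    f_p = (c_p + a) / (n_train + 2a),   a = 0.5 by default.

This keeps weights finite for features never observed in training, which
matters because in an expert-curated map the rarest features are typically
the most disease-specific; dropping them would discard exactly the signal
the curation added. With a = 0 a zero-count feature is a hard error rather
than a silent drop. The logarithm is natural by default and the base is
configurable; changing the base rescales all scores by a constant, so
every rank-based quantity downstream (Wilcoxon, AUC, precision-at-k) is
invariant to it.

Variants. `negative_weights` adds `log(1 − f_p)` for every absent,
non-excluded feature, a non-positive term that penalises clean records;
it is the natural frequency-based absence penalty consistent with
"penalise absence" semantics, requires f_p < 1, and is documented as an
interpretation rather than bit-compatibility with any external
implementation. `precomputed` applies an externally supplied weight table
with the standard sum; a table without frequencies simply cannot be used
with `negative_weights`, and the error says so. Excluded features (see
stratification) contribute nothing under any variant.

## Cohort roles and leakage control

Roles come from genotype status alone: carriers are cases, confirmed
non-carriers (the only patients whose non-carrier status is actually
known) are controls, and everyone else is the training cohort. Weights
are therefore never fitted on the labelled test set. Two further leakage
controls exist: disease-diagnosis codes (a seed code and all its catalog
descendants) can be removed from the map before any scoring, and a
feature used to define the deployment stratum (e.g. heart failure) can be
excluded from the score while still being required in the patient's
history. Tests verify both are leakproof: removing an excluded feature's
codes from the raw event stream changes no score.

Hierarchy expansion uses a string-prefix rule on normalised codes within
one ICD version, evaluated against a user-supplied code catalog (the set
of codes existing in the user's extract). This reproduces the dot
hierarchy of ICD without bundling licensed tabular data; no ICD-9↔10
crosswalk is attempted, and codes are otherwise opaque identifiers.

Stratification filters — minimum age at the last recorded diagnosis,
verbatim race/ethnicity labels, required feature history — are set
intersections, hence idempotent and order-independent (tested). Age is
calendar-year arithmetic (`year(last diagnosis) − birth_year`) because
only birth year is ingested; patients with no diagnoses have undefined
age and fail any age stratum rather than erroring, since genotyped
patients without ICD data are a real occurrence. Race/ethnicity matching
is exact and case-sensitive on the verbatim EHR value: label
normalisation policies differ across systems and should be the caller's
explicit choice.

## Evaluation

* **Wilcoxon rank-sum**, two-sided by default (sidedness configurable in
  direction of use): exact null distribution when the pooled sample has
  ≤ 12 observations and no ties, otherwise the tie-corrected normal
  approximation with continuity correction (via scipy). A pooled sample
  with zero variance returns p = 1.
* **AUC** by the Mann–Whitney rank formula, ties worth one half;
  identical to brute-force pair counting (tested to 1e-12).
* **Precision-at-k** with deterministic tie handling at the k-boundary.
  With A the patients strictly above the k-th order statistic and T the
  tie group at it, m = k − |A| slots are filled from T. The default
  `expected` policy returns (cases(A) + m·cases(T)/|T|)/k, which equals
  the average over all tie-break orderings (tested by enumeration) and
  needs no random seed; `pessimistic`/`optimistic` bracket it.
* The default k grid is 10…100 by 10, 200…1000 by 100, then three points
  per decade (10^(1/3) spacing) above 1000, always terminated by the
  cohort size n; at k = n precision equals the prevalence exactly, which
  is also the random-prioritization baseline reported alongside every
  curve.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with each
patient drawn independently:

* carrier status ~ Bernoulli(π);
* integer age from a normal(age_mean, age_sd) truncated to [18, 100],
  converted to birth year via a fixed reference year (2024) so that
  age-at-last-diagnosis round-trips through the ingestion layer;
* feature presence ~ Bernoulli with odds = baseline odds × OR_p for
  carriers at or above the penetrance onset age (default 60), baseline
  odds otherwise. The hard age gate is the simplest model of late-onset,
  incomplete penetrance — below onset, carriers are statistically
  indistinguishable from non-carriers (tested); a logistic ramp
  (`age_gating="logistic"`, width `age_ramp_years`) is available when a
  smooth onset is wanted;
* each present feature emits 1 + Poisson(λ) diagnosis events (λ = 1.5 in
  the preset) with codes uniform over the feature's code group and dates
  uniform over the patient's adult years, so normalisation, duplicate
  handling and the presence rule are exercised end to end;
* non-carriers are labelled `noncarrier_confirmed` with a configurable
  fraction (0.5 in the preset — roughly the share of a biobank with
  sequencing-confirmed genotypes), the rest `unknown`, which downstream
  becomes the training cohort;
* race/ethnicity and sex labels are sampled from configurable categorical
  distributions purely so stratification code paths run; no demographic
  realism is claimed.

Everything is driven by one `numpy` generator, so cohorts are bit-identical
given the seed.

The bundled preset (`attrv_like_preset`) is a **synthetic** stand-in for
an expert-curated cardiac-amyloidosis-type map: 21 features over 292
fabricated codes (`SYN####`, no real ICD semantics), carrier prevalence
π = 0.013, onset 60, default cohort size 35,000. Baseline feature
frequencies span 0.002–0.12 (order-of-magnitude realistic adult
health-system lifetime frequencies: heart failure 0.12 at the common end,
vitreous opacities and restrictive cardiomyopathy 0.002 at the specific
end) and carrier odds ratios span 3–8, with the common features given the
smaller effects. One feature (`heart_failure`) is flagged for the
stratified deployment analysis.

What the simulator does *not* model: longitudinal disease progression,
coding-intensity/utilisation confounding, correlated comorbidity
structure, or missingness beyond patients whose features are all absent.
Passing tests on these cohorts therefore demonstrate correctness of the
machinery and recoverability of a known signal — not expected performance
on real EHR data, where feature correlation and documentation bias can
only degrade the score.

## Problem sizes and numerical choices

Statistical tests run at sizes chosen to make their bounds meaningful:
binomial-calibration checks at n = 20,000 (3-SD bounds), null calibration
of the rank-sum test and AUC over 1000 replicate zero-effect cohorts of
300 patients with π raised to 0.10 so every replicate has cases, signal
recovery on five 35,000-patient preset cohorts, and weight recovery at
n_train = 50,000 averaged over five seeds — at that size the sampling SD
of a weight at f* = 0.01 is ≈ 0.044, so the 0.05 recovery bound is a
property of the batch mean rather than a per-seed coin flip.

Degenerate inputs are defined, not patched: π = 0 yields a cohort with no
cases (evaluation then refuses cleanly), an all-absent patient scores
exactly 0 under the standard variant, a frequency-1 feature has weight 0,
and a scoring request for a feature lacking a weight is an error unless
the feature is explicitly excluded. Feature maps are strictly
code-disjoint by default (a code in two features usually indicates a
curation slip); overlap can be allowed explicitly and is logged.

## Known limitations

* Presence is lifetime and binary; recency, counts and severity are
  deliberately out of scope of the weighting scheme.
* The hierarchy rule is purely lexical within an ICD version; codes whose
  hierarchy is not prefix-shaped in the user's extract need explicit
  enumeration in the catalog.
* The negative-weights absence term is one defensible choice among
  several; scores from other implementations of absence penalties are not
  expected to match numerically.
* Calendar-year age can be off by up to one year relative to exact
  birthdates; strata boundaries inherit that granularity.
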