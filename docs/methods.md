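# Methods

`homeclass` implements a complete, testable version of a workflow used to
classify homelessness from linked state administrative records and to use the
resulting risk scores to compare fatal opioid-overdose rates between homeless
and non-homeless groups. Because real linked warehouses of this kind are not
public, the package pairs the analysis code with a synthetic-data generator
that embeds a known ground truth, so every stage — case definition, cohort
restriction, model fitting, evaluation, weighted rate estimation — can be
validated end to end.

## The study design being modelled

The observed outcome is a *known case of homelessness*: a person flagged by at
least one of four administrative indicators over a five-year window —

1. an insurance claim (APCD) or acute-care discharge (Case Mix) with an ICD-9
   V60-family or ICD-10 Z590 housing-circumstances code;
2. a monthly mental-health-agency (DMH) housing-status record of housing loss;
3. an ambulance narrative (MATRIS) containing "homeless" or "shelter";
4. a prescription-monitoring (PMP) patient address matching an emergency
   shelter.

These indicators are treated as definitive but incomplete: they capture only a
minority of people who truly experience homelessness. The classification model
is a main-effects binary logistic regression of the known-case flag on binary
predictor features. Because known cases are rare (&lt;1%), the development
sample is rebalanced by 1:1 downsampling of the majority class before fitting;
the model is then applied, without intercept correction, to an untouched
validation sample. Performance is summarised by rank-based AUC, sensitivity,
specificity, balanced accuracy (their mean), PPV, NPV, the lift of PPV over
outcome prevalence, and 1/PPV (false positives per true positive), with the
prediction rule "probability ≥ 0.5 is homeless".

Fatal opioid overdoses are deaths whose underlying cause is a poisoning
category (X40–X49, X60–X69, X85–X90, Y10–Y19, Y35.2) with an opioid T-code
(T40.0–.4, .6) among the multiple causes; records with no ICD code yet are
classified by a keyword search of the literal cause-of-death text (the keyword
list is configurable; the default covers common opioid terms). Risk scores are
turned into fractional group counts by summing scores (homeless mass) and
complements 1 − s (non-homeless mass); "the inverse of the risk score" is read
as the complement, since a reciprocal would not produce person counts. Rates
are per 100,000 persons; rate ratios carry log-normal 95% CIs,
exp(ln RR ± 1.959964·√(1/d₁ + 1/d₀)). This CI form reproduces all three
published rate-ratio intervals exactly at one decimal, which is the evidence
for interpreting "standard techniques" this way.

Two weighting conventions are provided. The default, `full_sum`, sums s and
1 − s over *all* persons, so group sizes partition the sample exactly — this
matches the published group sizes for both weighted approaches, which sum
exactly to the validation n. The literal two-step description
(`threshold_restricted`: homeless mass only from s ≥ 0.5, non-homeless mass
only from s &lt; 0.5) is available by flag. The two agree exactly for binary
scores. The published principal-analysis row itself is not exactly
reproducible from its printed margins (its group sizes sum to n − 541); we
document rather than emulate that discrepancy.

### Fixed numerical conventions

- Stratified 75/25 split with **round-half-up** per-stratum allocation; this
  is the only rounding rule consistent with the published development-sample
  size (0.75 × 41,457 = 31,092.75 → 31,093 and 0.75 × 5,009,182 = 3,756,886.5
  → 3,756,887, totalling 3,787,980).
- Threshold comparisons are inclusive (p ≥ 0.5 flags) everywhere, including
  the death-weighting step.
- ICD normalisation: uppercase, strip periods/whitespace. The V60 criterion is
  a *prefix* match (the whole category), Z590 an exact match; an exact-V60
  mode exists behind a flag.
- Keyword matching is case-insensitive substring (so "sheltered" matches); a
  word-boundary mode exists behind a flag. Address matching is exact after
  normalisation (uppercase, strip punctuation, collapse whitespace).
- IRLS: Newton steps with step-halving (log-likelihood is monotone
  non-decreasing), convergence when the max absolute coefficient change is
  below 1e-8, cap 100 iterations. On detected (quasi-)separation the fit is
  repeated once with a ridge of 1e-6 and flagged on the results object —
  an implementation necessity for downsampled rare-event fits.
- AUC uses midranks (`scipy.stats.rankdata`), i.e. the Mann–Whitney statistic
  with ties counted ½; it is cross-checked against a brute-force pair-counting
  oracle.
- Metrics with zero denominators are reported as explicitly undefined
  (`None`), never silently zero.

## The synthetic generator

`SimulationConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| `true_prevalence` | 0.046 | five-year general-population prevalence of homelessness |
| `capture_sensitivity` | 0.10 / 0.094 / 0.0013 / 0.014 / 0.029 (APCD, Case Mix, DMH, MATRIS, PMP) | per-source known-case counts scale like the published per-source counts, and the union lands near 0.82% observed prevalence |
| `engagement_prob` | 0.26 | inter-source overlap; see below |
| `baseline_overdose_prob` | 4.5e-4 | five-year fatal opioid-overdose probability for non-homeless insured adults (~90/100k per five years, an opioid-epidemic-era state level) |
| `true_rate_ratio` | 20.0 | embedded homeless vs non-homeless overdose risk ratio, the quantity the weighted estimators try to recover |
| `membership_prob` | APCD 1.0; Case Mix 0.55; PMP 0.75; MATRIS 0.12; DMH 0.004 | claims database is the universe; most insured people have hospital/prescription contact; ambulance and state mental-health contact are uncommon |
| `background_death_prob` | 0.012 | non-overdose five-year mortality, so death records contain realistic negatives (including non-opioid poisonings and pending-code records) |
| predictors | 20 binary indicators, 4 per group | see below |

Capture is mediated by a latent *service engagement* factor: a truly homeless
person is engaged with probability φ = 0.26, and only engaged persons can be
captured, independently per source with probability s/φ. Marginal capture
rates equal the configured sensitivities, while the shared factor produces the
positive overlap real linked data show. Fully independent capture (φ = 1)
cannot simultaneously produce the observed union (~0.82%) and a multi-source
share near one third — under independence with these marginals the
multi-source share would be ~8% and the union ~1.0%. With φ = 0.26 the
generator yields ~0.80% observed prevalence and ~32% multi-source share,
both matching the reference study. φ is exposed so users can explore other
overlap regimes.

Predictors are independent Bernoulli indicators given true status:
baseline rates 0.0018–0.12 in the non-homeless group, log-odds shifts
1.0–5.2 among the truly homeless. They emulate sparse administrative
indicator variables (substance-use, mental-health, service-contact flags).
The effects are deliberately strong — stronger than typical published
odds ratios for single indicators — because in this synthetic world *all*
excess overdose risk flows through the latent status. Recovering the embedded
rate ratio through a thresholded classifier therefore requires near-perfect
specificity against the latent truth (the default operating point is
sensitivity ≈ 0.95 and false-positive rate ≈ 0.0015 against truth, AUC ≈ 0.98
against observed labels, ~4.6% of the validation sample flagged). With
moderate effects the classifier still looks excellent against observed labels,
but false positives — who in real data share the risk factors driving
overdose, and here do not — dilute the flagged group and attenuate the
estimated rate ratio to roughly 12–14, far below the embedded 20. This is a
real epidemiological phenomenon (differential-misclassification bias), and
users can reproduce it by weakening `predictor_spec`.

What the generator does **not** emulate: record duplication and linkage
error (IDs arrive pre-linked and unique), temporal structure (the five-year
window is collapsed; "ever" indicators only), realistic ICD code frequencies
beyond planted-vs-background pools, correlation between predictors beyond
the latent status, and correlation between overdose risk and predictors
given status. Passing tests therefore demonstrate the correctness of the
*pipeline* under a known data-generating process, not the real-world
performance of any particular predictor set.

## Monte-Carlo studies and problem sizes

The package's replication studies use sizes chosen to keep a full run on one
CPU in minutes while leaving Monte-Carlo noise well inside the asserted
bands: generator calibration at n = 500,000; the null-signal AUC check
(all predictor effects zero → validation AUC within 0.48–0.52) at
n = 200,000; and the rate-ratio recovery study at 200 independent replicates
of n = 500,000 (about 3 s per replicate), asserting ≥ 90% CI coverage of the
embedded ratio. Replicate seeds derive from one master seed via
`numpy.random.SeedSequence`; every stage is deterministic given its seeds,
and equal configurations produce byte-identical outputs.

## Known limitations

- Downsampled-model probabilities are intentionally left uncalibrated
  (no intercept correction), mirroring the modelled workflow; weighted
  "approach 1" counts are therefore inflated and its rate ratio biased low.
  This is visible in both the reference numbers and the synthetic runs.
- The threshold estimator of the rate ratio is consistent only as
  classification against latent truth becomes perfect; its residual
  attenuation (~5% at defaults) is part of the modelled design, not a bug.
- The literal-text fallback keyword list for pending death records is a
  configurable guess; no authoritative list exists.
- Demographic reconciliation uses whole-row source precedence
  (claims → mental health → vital records → others by default); field-level
  merging is out of scope.
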