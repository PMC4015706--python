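# Methods notes

This note records the modelling choices behind `linkbias`, the
assumptions they encode, and what the simulation results do and do not
demonstrate about real linked data.

## Estimands

The outcome is PICU-acquired bloodstream infection (BSI): a positive
blood culture dated between 2 days after PICU admission and 2 days
after discharge, both ends inclusive, at most one event per admission.
The window is applied inclusively at both ends as a symmetric
convention. Two estimands are computed per linked dataset:

* **Crude rate** — events × 1000 / bed-days, with a Poisson standard
  error `√n × 1000 / bed-days` treating the denominator as fixed, and a
  Wald 95% interval truncated below at zero.
* **Adjusted between-hospital difference** — from a log-link Poisson
  regression of the event indicator on hospital and covariates with a
  log bed-days offset. The two adjusted rates are obtained by marginal
  standardisation (predicting every record under each hospital and
  dividing predicted events by total bed-days); the difference's
  standard error comes from the delta method on the coefficient
  covariance. An identity-link Poisson fit would be a defensible
  alternative; the log-link/standardisation route was chosen because it
  is robust to empty covariate cells and keeps predictions positive.
  Non-convergent or separated fits (e.g. zero events in one hospital)
  are flagged and excluded from replicate summaries rather than
  silently dropped or patched.

Percent bias is `100 × (estimate − gold) / gold`, reported to one
decimal; for multiply imputed analyses the count entering the bias is
the mean count across imputations and the difference is the
Rubin-pooled point estimate.

## Synthetic data: what it emulates

The generator produces an admissions file and a microbiology file of
10,000 records each by default. Identifiers are sampled from
parameterised population distributions: sex Bernoulli(0.5), date of
birth uniform over 1995–2010, and Soundex codes from a fixed 500-code
list with Zipf-like rank weights (exponent 0.7, collision probability
Σp² ≈ 0.006 — two random records share a code about once in 160
draws, comparable to surname-code diversity in a UK hospital
population). A set fraction of microbiology records (the match rate:
10, 50 or 70%) copies the identifiers of a distinct admission and gets
a specimen date inside that admission's BSI window; the rest get
independent identifiers and dates.

Two deliberate idealisations:

* **Perfect gold-standard discriminability.** Admission identifier
  5-tuples are de-duplicated, and unmatched microbiology records are
  redrawn until they collide with no admission tuple. Error-free files
  are therefore perfectly linkable, and every linkage ambiguity is
  attributable to injected error. Real populations contain genuine
  coincidences (twins, shared birthdays and surnames); their effect
  here is carried entirely by the error process.
* **Outcome risk flows through observed covariates.** Which admissions
  acquire a BSI is decided by weighted sampling with log-weights
  +1.2 for renal support, +0.5 for unplanned admission, +0.8/+0.4 for
  infants (<1 month / 1–11 months), +0.08 per bed-day above the mean
  stay, and +0.35 for hospital 2. The covariate effects make the
  imputation likelihood genuinely informative, as the corresponding
  predictors are in real PICU data, and the hospital effect yields a
  non-zero true between-hospital difference (rate ratio ≈ 1.4,
  mirroring the two-PICU contrast the package is designed around).
  Stays are 1 + Poisson(4.5) days, giving ≈ 5.5 mean bed-days per
  admission, consistent with a bed-day total of ~55,000 per 10,000
  admissions.

The `quarter_year` covariate is the calendar quarter of admission
(4 levels) rather than every year×quarter cell; the full interaction
would create sparse cells at reduced simulation scale without changing
the mechanics being studied.

**Error injection.** A fraction `error_rate` of microbiology records
(in expectation) has one uniformly chosen identifier field replaced by
a different draw from the population distribution (dates are kept
calendar-valid); an independent fraction `missing_rate` (default equal
to `error_rate`) has one field blanked. Value error is applied before
missingness, so a record can receive both. Under non-random mechanisms
the per-record selection probability is `ratio·k` for the high-error
group (hospital 1, or true matches) and `k` otherwise, with `k` solved
so the expected overall fraction is preserved; the run aborts if the
scaled probability exceeds 1. One corrupted field per selected record
is the minimal reading of record-level error; whole-date corruption
would be a harsher alternative and produces deeper pattern damage.

## Linkage machinery

* **Agreement patterns** are 5-state-coded strings (agree / disagree /
  missing per field). Missingness is a third state, never coerced to
  disagreement, because value error and missingness are injected
  separately and carry different evidence about match status.
* **m/u estimation** uses all true-match pairs and a 50,000-pair random
  sample of non-match pairs, so `u` reflects the full cross product
  rather than the blocked subset. Estimates are clipped to
  `[1e-4, 1 − 1e-4]` to keep weights finite when a field agrees or
  disagrees universally.
* **Blocking.** The default candidate rule admits pairs agreeing on the
  full date of birth OR on (Soundex AND sex). The predicate is a
  function of the agreement pattern alone, which has two useful
  consequences: joint pattern counts over blocked pairs equal the
  full-cross-product counts for every admissible pattern, and the rule
  is provably harmless to classification whenever the weight threshold
  exceeds the maximum weight attainable by an excluded pattern. A
  `blocking="none"` escape hatch materialises the full cross product
  for small instances and oracle checks.
* **Joint match probabilities** `P(M | γ)` are direct proportions of
  true matches among candidate pairs sharing pattern γ. Patterns never
  observed during estimation fall back to independence Bayes
  (`R = prior-odds × 2^weight`, `P = R/(1+R)`), keeping the map total.
* **Greedy highest-weight assignment** processes pairs in a fixed
  deterministic order (descending weight, then earliest specimen date,
  earliest admission date, smallest keys) and accepts a pair when both
  records are unclaimed and the weight is ≥ the threshold ("exceeds"
  is implemented as ≥ because candidate thresholds sit at observed
  weights). Because each decision depends only on earlier decisions,
  the accepted set at threshold t is the weight-filtered prefix of one
  full scan — the threshold scan therefore runs the greedy pass once
  and evaluates all ~243 candidate thresholds vectorially. The 10%
  tuning subset is drawn at the microbiology-record level, stratified
  by true match status, which stabilises the error curves at low match
  rates.

## PII specifics

Cut-offs `p_upper = 0.9` and `p_lower = 0.2` are strict inequalities;
a best candidate at exactly 0.9 or 0.2 is equivocal. Candidates
outside `[p_lower, p_upper]` are dropped before the max-probability
prior (a keep-all variant would only matter when a sub-0.2 candidate
exceeds all retained ones, which cannot happen for the maximum). MPD
acceptance uses ≥ the threshold, so threshold 0 reduces PII to a
deterministic maximum-posterior classifier and threshold 1 routes
every equivocal record through likelihood-based multiple imputation.
The likelihood is a main-effects logistic regression; if the MLE
separates or fails to converge, a ridge-penalised Newton fit
(penalty 1e-3) replaces it with a warning. Multiple imputation is
*proper* by default: each imputation draws coefficients from the
asymptotic normal posterior before the Bernoulli draw, so
between-imputation variance is not understated (`improper_mi=True`
disables the draw for comparison). Rubin pooling uses
`T = W + (1 + 1/m)B` with degrees of freedom
`(m−1)(1 + W/((1+1/m)B))²`, infinite when B = 0.

## Problem sizes

The bundled evaluation runs each scenario at 2,000 records with 25
replicate corrupted files — large enough that per-replicate match
counts (200–1,400) give stable sign and ordering of mean bias, small
enough to keep a full multi-scenario replay in tens of seconds. The
zero-error recovery check runs at the full 10,000 × 10,000 design
size. Scenario and replicate seeds are derived from a single master
seed, so every file, threshold and imputation is reproducible.

## Known limitations

* With perfectly discriminative gold files and the two-point MPD, PII
  has no overcount channel: no false unequivocal links exist, and an
  equivocal record's MPD favours BSI = 1 only when
  `prior × likelihood > (1 − prior)(1 − likelihood)`, which at ~10%
  outcome prevalence requires priors near 0.9. At a 10% match rate,
  single-field-corrupted true matches are swamped by chance
  date-of-birth collisions in the pattern counts (their `P(M|γ)` often
  falls below 0.2), so PII tends to undercount, while the
  highest-weight method's subset-tuned threshold partially cancels
  false against missed matches. Which method is less biased in a given
  replicate therefore depends on the identifier discriminability and
  match rate; users should compare both on synthetic data matched to
  their own setting rather than assume a uniform ordering.
* The error model enters "completely different" values; typographic or
  phonetic near-miss errors, which Soundex partially absorbs, are out
  of scope, as are NHS numbers, postcodes, duplicate-person structure
  and repeat-culture clustering.
* m/u and match probabilities are estimated from full truth — a
  best-case scenario. Real linkage would estimate them from a subset
  or via EM, adding error the simulation does not model.
* Passing simulations here demonstrate internal consistency of the
  machinery and the direction of bias under the modelled error
  mechanisms; they do not certify bias magnitudes for any particular
  real data source.
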