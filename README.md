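# linkbias

Quantifying the bias that record-linkage error introduces into
epidemiological estimates, and comparing two ways of handling it.

## The problem

Hospital admission databases and laboratory surveillance files rarely
share a reliable unique identifier. When a paediatric-intensive-care
(PICU) admission file is linked to positive-blood-culture records to
estimate rates of PICU-acquired bloodstream infection (BSI), linkage
must fall back on a handful of partially identifying fields — here sex,
the Soundex phonetic code of the surname, and the day, month and year
of birth. Mis-recorded or missing identifier values then produce
*false-matches* and *missed-matches*, and both distort the quantities
analysts actually care about: the infection rate per 1000 bed-days and
the adjusted rate difference between hospitals. When the errors are
concentrated in one hospital's records, or in the records of infected
children, the distortion is systematic rather than random.

`linkbias` simulates this whole situation with a known gold standard:
it generates paired admission/microbiology files, injects identifier
error at controlled rates (uniformly, concentrated 5-fold on one
hospital, or concentrated 5-fold on true-match records), links the
files with two classification methods, and measures the percent bias of
each method's estimates against the simulated truth.

## The methods

**Highest-weight (HW) classification.** Each candidate record pair gets
a Fellegi–Sunter match weight

    w = Σ_i  log2(m_i / u_i)            over agreeing fields
      + Σ_i  log2((1 − m_i)/(1 − u_i))  over disagreeing fields

where `m_i = P(agree on field i | match)` and
`u_i = P(agree on field i | non-match)` are estimated directly from
pairs of known true status (missing comparisons contribute zero).
Pairs are accepted greedily in descending weight order, one link per
record on each side, provided the weight reaches a threshold chosen on
a 10% truth subset to minimise either the sum of errors
(false + missed) or their net effect |false − missed|.

**Prior-informed imputation (PII).** Instead of committing to a single
linked record, PII transfers uncertainty into the analysis. Match
probabilities `P(M | γ)` are estimated *jointly* per agreement pattern
γ (no independence assumption across identifiers). Admissions whose
best candidate has probability > 0.9 are unequivocal links (BSI = 1);
below 0.2, unequivocal non-links (BSI = 0). For the equivocal remainder
a two-point prior (`P(BSI=1)` = max candidate probability) is combined
with a logistic-regression likelihood `P(BSI=1 | covariates)` fitted on
the unequivocal records; the normalised product is the modified
probability distribution (MPD). If the larger MPD mass reaches the MPD
threshold (0.1 or 0.9 in the study design), its value is accepted;
otherwise the flag is multiply imputed from the likelihood alone.
Five completed datasets are analysed separately and pooled with
Rubin's rules (T = W + (1 + 1/m)·B).

## Worked example

```python
import numpy as np
import linkbias as lb

cfg = lb.ScenarioConfig(name="demo", n_admissions=2000, n_micro=2000,
                        match_rate=0.10, error_rate=0.10, seed=1)
adm, mic_gold, truth = lb.generate_gold_standard(cfg)
mic = lb.inject_errors(mic_gold, cfg, truth, np.random.default_rng(1))

rng = np.random.default_rng(2)
est = lb.build_estimation_pairs(adm, mic, truth, rng)
fp = lb.estimate_field_probabilities(est)
cand = lb.generate_candidate_pairs(adm, mic, truth=truth)
jmp = lb.estimate_joint_match_probabilities(cand.df, fp)
cand = lb.attach_scores(cand, fp, jmp)

threshold, scan = lb.select_threshold(cand, truth, criterion="sum", rng=rng)
decisions = lb.classify_highest_weight(cand, threshold)
```

Counting events (one per admission) and pooling five PII imputations
with Rubin's rules, the example prints:

```
gold standard: 200 infections, rate 18.14 per 1000 bed-days
HW threshold 20.28: 164 links (0 false, 36 missed), rate 14.88, count bias -18.0%
PII (MPD 0.1): counts [176, 176, 176, 176, 176], pooled rate 15.96 (95% CI 13.61-18.32), count bias -12.0%
```

Reading: 10% identifier error plus 10% missingness destroyed the
linkability of 36 of the 200 truly matched culture records for HW at
its (conservatively chosen) threshold, so the infection rate is
underestimated by 18%. PII recovers part of that loss through its
probability-based partition, at the price of a wider pooled interval
that honestly reflects linkage uncertainty.

The same pipeline is available from a shell:

```bash
linkbias simulate --table1 --out scenarios/          # 12 scenario suite
linkbias evaluate --table1 --n-records 2000 --replicates 5 --out report.csv
```

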