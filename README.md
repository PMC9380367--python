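# mraqc

Quality control for **medical record abstraction** (MRA) in multi-site
clinical research studies.

When study data are abstracted by hand from electronic health records,
transcription error is the dominant data-quality risk, and plausible-but-wrong
values slip past range checks. The standard countermeasure is *double
abstraction*: a second, independent abstractor re-enters a sample of cases,
an automated comparison flags every inconsistency (a *discrepancy*), and each
discrepancy is adjudicated against the medical record (the gold standard) —
it is a *true error* exactly when the primary abstractor's entry disagrees
with the chart, whatever the QC abstractor wrote.

`mraqc` implements that whole control loop as a reusable engine, for data
coordinating centers and informatics teams running chart-review studies:

- **Discrepancy engine** — field-level comparison of primary vs QC
  abstraction after canonical normalization (case folding, numeric and date
  parsing with a configurable day/month dialect), plus true-error
  adjudication against gold values.
- **Error-rate statistics** — the error rate is

  ```
  error rate = (number of errors detected) / (number of fields collected)
  ```

  reported against two denominators: *all fields* defined for a case's type
  (optimistic) and only the fields the primary abstractor *populated*
  (conservative). Crude Wald and Wilson 95% CIs; a cluster-adjusted marginal
  rate from an intercept-only binomial GEE (exchangeable working
  correlation, sandwich variance, CI back-transformed from the logit scale);
  pooled two-proportion z tests for rate differences; OLS trend of per-event
  error rates over successive QC events.
- **QC scheduler** — the monitoring cadence (initial event on the first
  3 cases, one randomly selected case per 25 thereafter), seeded random case
  selection, the acceptance threshold (default: error rate no greater than
  4.93%, i.e. under 500 errors per 10,000 fields), and the site state
  machine: fail → repeat on 3 stratified-random cases (2 of the site's
  prominent case type, 1 of the other) → fail again → retrain and re-QC.
- **Simulator** — a synthetic multi-site study generator with per-field
  ground truth: configurable caseloads, pharmacologic (P, 312 fields) vs
  non-pharmacologic (NP, 172 fields) case mix, populated-field patterns,
  injected abstraction errors with site effects and a per-event learning
  effect.
- **CLI** — `mraqc simulate | schedule | compare | adjudicate | stats |
  trend | run`, all emitting JSON; `mraqc run` exits 0/2/3 for
  pass/repeat/retrain so shell pipelines can branch on the decision.

## Worked example

The built-in reference study fixture reconstructs the margins of a published
215-case QC dataset (85 P + 130 NP cases; 10,425 + 8,418 populated fields;
273 + 300 injected true errors) and pushes it through the full pipeline:

```python
import mraqc as m

study = m.reference_margins_study(seed=0)
report, state = m.run_full_qc_cycle(
    study.dataset, m.QCPolicy(), m.SiteQCState(site_id="all-sites")
)
print(report.result.n_true_errors, report.decision.value)
for est in report.estimates:
    print(est.to_dict())
```

prints (abridged):

```
573 pass
{'k': 573, 'n': 48880, 'denominator_kind': 'all_field',
 'rate_percent': 1.17, 'per_10k': 117, ...}
{'k': 573, 'n': 18843, 'denominator_kind': 'populated_field',
 'rate_percent': 3.04, 'per_10k': 304,
 'ci_low': 0.02805..., 'ci_high': 0.03295..., 'method': 'crude_wilson'}
```

Reading: the comparison found 573 true errors over 48,880 applicable fields
(1.17%, the optimistic all-field rate) and 18,843 populated fields (3.04%,
95% CI [2.81%, 3.30%], the conservative rate) — comfortably under the 4.93%
acceptance threshold, so the event **passes** and data collection resumes.
Stratified by case type the populated-field rates are 2.62% (P) and 3.56%
(NP), a difference of 0.95 percentage points (pooled z test, p = 0.0002).

Scheduling workload, from the shell:

```bash
$ mraqc schedule --cases 25
# → QC1 (3 cases) + QC25 (1 case): total_qc_cases = 4
$ mraqc schedule --cases 100 --repeats 2
# → 7 scheduled + 6 repeat cases: total_qc_cases = 13
```

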