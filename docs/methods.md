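# Methods

## The QC process being modelled

A multi-site chart-review study collects data by medical record abstraction
(MRA): coordinators transcribe values from the electronic health record into
an electronic data capture (EDC) system. Quality is controlled continuously:
selected cases are independently re-abstracted by a second coordinator, an
automated comparison lists every field on which the two entries differ
(*discrepancies*), and each discrepancy is adjudicated against the chart.
A discrepancy is a *true error* iff the primary abstractor's entry disagrees
with the chart; if the primary entry matches the chart the discrepancy is not
an error, even when the QC abstractor's entry is wrong. Error rates are then
compared with a pre-set acceptance threshold, and sites that exceed it repeat
QC (and, on a second failure, retrain).

`mraqc` implements the comparison/adjudication engine, the rate estimation,
the scheduling state machine, and a simulator that generates whole studies
with known injected errors.

## Comparison and adjudication

Values are normalized before comparison: text and coded values are trimmed
and case-folded; numerics are parsed as decimals, so trailing zeros are
insignificant ("2.50" ≡ "2.5") and comparison is exact — abstracted data are
transcribed, not measured, so no numeric tolerance is applied; dates are
parsed to calendar dates with a per-dataset day/month dialect (`MDY`
default, `DMY`/`YMD` available; ISO year-first is always accepted).
Unparseable numerics/dates are never dropped: they become flagged values
that compare as trimmed raw text and are visible in reports.

The comparator is maximally sensitive: any inconsistency counts, including
one abstractor populating a field the other left blank (tagged `one_sided`
so tallies with and without such discrepancies can both be produced).
Both-absent is agreement. Fields absent from *both* abstractions are
invisible to the comparator even if the chart holds a value — a known
sensitivity limit of double abstraction, inherent to comparing two
abstractions rather than auditing the chart directly.

Adjudication compares only the primary entry with the gold value (both
absent = match). Re-adjudication of a resolved discrepancy is an error;
an event cannot be summarized while any discrepancy is unresolved.

## Error rates

With `k` true errors over `n` fields, the rate is `k/n` against either
denominator:

- **all-field**: Σ over QC'd cases of the number of fields *applicable to
  that case's type* (not the union form for every case — a non-pharmacologic
  case contributes 172, not 312);
- **populated-field**: the number of fields the *primary* abstractor
  populated, the conservative denominator.

Crude intervals: Wald (`p ± z·√(p(1−p)/n)`, truncated to [0, 1]) and Wilson
score. The Wald interval degenerates to zero width at k ∈ {0, n}; the
package warns and recommends Wilson, which stays informative at the
boundary. Both are exposed because published crude intervals for rates of
this size are reproduced more closely by the score form even when the normal
approximation is named: on the 573/18,843 reference total, Wilson gives
[2.81%, 3.30%] where the textbook Wald formula gives [2.80%, 3.29%].

Known non-reproducibility in the reference arithmetic: the published crude
all-field rates by case type (1.06/1.45/1.24%) do not equal
true errors ÷ all-field totals, which give 1.03/1.34/1.17% (the latter
matching the published *adjusted* all-field column). This package always
reports the ratio as defined above and makes no attempt to chase those
printed cells; the same applies to the rate-difference Δ on the all-field
scale (0.31 pp from the ratios).

### Cluster-adjusted rate

Sites, not fields, are the independent units: abstractors work per site, so
field-level outcomes are correlated within site. The adjusted rate is the
marginal mean from an intercept-only binomial GEE with logit link and
exchangeable working correlation. Field-level outcomes are aggregated to
per-cluster pairs (k_i, n_i) before fitting — exactly equivalent for an
intercept-only model and far cheaper than tens of thousands of Bernoulli
rows, because the inverse of an exchangeable correlation matrix has constant
row sums. The estimate collapses to a weighted ratio

    μ̂ = Σ w_i k_i / Σ w_i n_i,   w_i = 1 / (1 + (n_i − 1)·α̂),

with α̂ the usual moment estimator built from within-cluster sums of
pairwise Pearson-residual products (computable from the aggregates alone),
iterated to relative coefficient change < 1e-8 (max 50 iterations;
non-convergence raises with diagnostics). The variance is the cluster-robust
sandwich; the 95% CI is formed on the logit scale and back-transformed,
hence asymmetric — matching the shape of published adjusted intervals,
whereas crude intervals stay on the proportion scale. The cluster unit
defaults to site and is the caller's choice of aggregation.

Identities and checks: with one observation per cluster the working
correlation is irrelevant and μ̂ equals the crude k/n exactly; with equal
clusters and no intra-cluster correlation the robust SE approaches the
binomial SE. If every outcome sits on one boundary (k = 0 or k = N overall)
the point estimate is reported at the boundary and the interval comes from a
continuity-offset refit (half an error added to the smallest cluster), with
a warning. A test cross-checks the solver against statsmodels' GEE on the
expanded 0/1 rows; small differences in the two moment conventions for α
leave sub-percent differences in the weights, so the cross-check uses a 2%
tolerance on the rate.

### Comparisons and trend

Rate differences use the pooled two-proportion z test, reported in
percentage points (on the reference per-type populated counts this gives
Δ = 0.95 pp, p = 0.0002). The error-rate trend over successive QC events is
unweighted OLS of per-event rates (percent) on event index — nothing in the
monitored design suggests weighting by per-event denominators — reporting
slope (pp per event), its 95% CI, p, and R². Percent values are rendered at
2 decimals and per-10,000 values as integers in reports.

## Scheduling and the state machine

Policy defaults: initial event on the first 3 cases (QC1), one randomly
selected case per 25 completed cases (QC25, QC50, ...), threshold 4.93%
applied to the populated-field rate, 3 cases per repeat event. Notes on the
genuinely open points:

- The threshold is stated both as 4.93% and as "under 500 per 10,000"
  (= 5.00%); the policy default follows 4.93% and the config makes the value
  explicit.
- A rate exactly equal to the threshold **passes** ("no greater than").
- The governing denominator is not pinned down by the source process;
  `populated_field` (conservative) is the default and it is configurable.
- Sites with fewer than 3 cases: QC1 covers all available cases
  (min(3, n)); a site with 0 cases has an empty schedule.
- Repeat selection: 2 cases of the site's modal case type + 1 of the other,
  drawn uniformly without replacement; a prominence tie is broken by a
  seeded coin flip; if the other type has no cases all 3 come from the modal
  type, preserving the sample size. Already-QC'd cases are assumed excluded
  from eligibility.
- Total workload is `min(3, n) + ⌊n/25⌋ + 3·(repeat events)`: 4 QC cases
  for a 25-case site, 8 for 125, 13 for 100 cases with two repeats, 9 for
  10 cases with two repeats.

State machine: collecting → awaiting_qc at a trigger; pass returns to
collecting; a failure moves awaiting_qc → repeat_qc; a failure from
repeat_qc moves to retraining, after which a fresh repeat-style event must
be passed before collection resumes. There is no path back to collecting
that does not pass an event. Retraining content itself is out of scope; the
engine only emits the decision flag. All random selection consumes a single
injected seeded generator, so full runs replay exactly.

## Simulator

The generator emulates the reference study design: 30 sites by default,
per-site caseloads uniform on a configured range (the real caseload
distribution is unpublished; 3–12 is a stand-in covering single-event and
multi-event sites), case types Bernoulli with P-probability 85/215, fields
per case from the dictionary (312 P / 172 NP), and per-type populated
fractions 10,425/26,520 (P) and 8,418/22,360 (NP) — the reference margins.
Populated-field patterns are drawn independently per field (no
field-correlation structure). Gold values are structurally, not clinically,
plausible: coded/text fields draw from small controlled vocabularies,
numerics are log-uniform with 3 significant digits, dates fall in the
2016-07-01 … 2017-06-30 study window.

Primary and QC entries start as copies of gold and are corrupted
independently per field. The corruption probability for a case abstracted
after `e` completed QC events at a site with effect `b` is

    p = expit( logit( clip(base + learning·e/100) ) + b ),  b ~ N(0, site_sd²),

i.e. the learning effect is specified in percentage points per completed
event on the probability scale (the natural units of the observed trend; a
−0.5 setting produces a −0.5 pp/event mean path exactly when site_sd = 0),
while site heterogeneity acts multiplicatively on the odds. Events completed
before case `j` follow the cadence: `[j > 3] + ⌊(j−1)/25⌋`. Error modes mix
wrong-value / wrongly-blank / wrongly-populated at 80/10/10 by default (no
published taxonomy exists): a populated field is corrupted with probability
`p` (wrong value vs blanked at 8:1), an absent field is spuriously populated
with probability `p/10`. Every wrong-value corruption is guaranteed to
differ from gold *after normalization*. The generator records every
corrupted slot per role, so downstream results can be checked against
ground truth: with a perfect QC abstractor the adjudicated true-error set
equals the injected primary set exactly; with a fallible QC abstractor it is
a subset (coincidental agreement can hide an error).

`reference_margins_study()` is the deterministic end-to-end fixture: it
forces exactly 85/130 cases, exactly 10,425/8,418 populated fields
(distributed as evenly as possible across cases) and exactly 273/300
wrong-value primary errors (drawn uniformly over the populated slots), with
a perfect QC copy — so the pipeline reproduces the populated-field crude
column (2.62/3.56/3.04%) from simulated data. Seeds change value content,
never margins.

What passing simulated tests does *not* show: real abstraction errors are
not independent across fields (an abstractor who misreads a medication block
errs on several related fields), real populated-field patterns are
structured by case complexity, and real per-event denominators are tiny
(1–3 cases) and pooled across sites. The simulator's homogeneous-field
independence makes rates concentrate faster than field-correlated errors
would, so interval-coverage results here are a best case for the
independence component, not a validation of the GEE against every real
correlation structure.

## Problem sizes used in validation

The Monte-Carlo checks use study-shaped sizes chosen once: GEE interval
coverage over 500 simulated 30-site studies (600 populated fields per site,
per-site rates Beta(3, 97): mean 3%, ICC ≈ 0.01), where the sandwich-based
interval covers the true marginal rate 92–98% of the time (small-m sandwich
variances run slightly liberal, a known property); trend recovery over 200
simulated 7-event studies with a built-in −0.5 pp/event learning effect and
~3,000 pooled populated fields per event, with the slope CI covering the
truth in well over 90% of replicates; and exact injected-vs-adjudicated
error-set equality on ~11,000-field studies. The entire suite runs in well
under a minute on one CPU.

## Limitations

- Adjudication trusts the supplied gold values; disagreement between
  adjudicators is out of scope.
- Repeating groups (e.g. medication rows) are modelled as flat per-field
  slots; partially populated groups have no special counting rule.
- No fuzzy or semantic matching of free text.
- The GEE is intercept-only by design (a marginal rate); covariate-adjusted
  error modelling is out of scope.
- The workload arithmetic covers QC case counts only, not person-time.
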