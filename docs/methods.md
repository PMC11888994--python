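# Methods

## Data model

A spontaneous-reporting-system (SRS) extract arrives as four CSV tables keyed
by an opaque case id: DEMO (sex, decade age band, reporting year), DRUG (one
row per reported drug: generic name, involvement category, start date, free-
text reason for use), HIST (primary disease) and REAC (one row per adverse
event: 8-digit MedDRA PT code, outcome, event date). The join is outer on
DEMO — one `CaseReport` per DEMO row, child lists possibly empty — and child
rows without a DEMO parent are counted and logged, never dropped silently.
Duplicate DEMO ids are an integrity error; no follow-up/version deduplication
beyond that is attempted.

Physical column headers are configuration (the default map accepts both the
Japanese PMDA headers and English transliterations), because the distributed
files have changed headers across quarters. Files default to Shift-JIS with
a UTF-8 fallback. Dates are kept as `(year, month?, day?)` triples with no
imputation: completeness is information the time-to-onset stage needs.
Drug-name matching is exact after trimming, whitespace collapsing and
case-folding; bracketed salt suffixes ("… hydrochloride hydrate",
"(genetical recombination)") are deliberately retained, since report item
labels keep salt forms.

## Cohort definition

A case enters the cohort when (a) the target drug appears with *suspect*
involvement (concomitant-only mentions never qualify) and (b) at least one
reaction PT code lies in the configured SMQ; the bundled
gastrointestinal-perforation SMQ has code 20000107 and 96 PTs. Extraction is
idempotent and annotates each case with its matching reactions.

Reasons for use are classified by an ordered, first-match-wins,
case-insensitive substring rule set (bundled as YAML, user-extensible):
blank → `no_entry`, unmatched → `other`. A case carries the union of the
categories over all suspect records of the target drug, so a multi-indication
case contributes one unit to *each* matching stratum; stratum counts may
therefore sum to more than the number of distinct cases. `no_entry` survives
only when no record has a classifiable reason.

Outcomes are dichotomized: death / with sequelae / not recovered → no
improvement; improved / recovered → improvement; unknown or blank → excluded.
When a case's reactions disagree, the worst classified outcome wins
(death > with sequelae > not recovered > improved > recovered); unknown is
ignored unless it is all there is. Worst-case resolution is the conservative
pharmacovigilance convention. Printed-percentage reproduction (demographics,
reporting ratios) uses half-up rounding to one decimal, which is what
published count/percentage pairs are consistent with.

## Time-to-onset

Onset is `earliest complete SMQ event date − earliest complete suspect start
date of the target drug`, in whole days, and must be ≥ 1: reports lacking a
complete date on either side are excluded (not imputed), and same-day events
are excluded because the lifetime model's support is positive. Where several
start or event dates exist, the earliest complete one is used
(first-exposure / time-to-first-onset convention).

Quartiles use linear interpolation of order statistics by default; the rule
is a parameter (any `numpy.quantile` method) because statistics products
disagree on it and the convention behind published medians is generally
unknowable.

Every extracted report is an observed event — SRS reports are events by
construction — so the two-parameter Weibull is fitted without censoring.
The MLE solves the profile score in the shape β by bracketed root finding
(Brent, |score| ≤ 1e-8 at the optimum), with the scale α then available in
closed form; an all-identical sample is rejected as degenerate (β unbounded)
and n ≥ 3 is required. Default 95% CIs are Wald intervals on (log α, log β)
from the analytic observed information, back-transformed — log-scale Wald
respects positivity and is symmetric-ish on the printed scale; profile-
likelihood intervals (likelihood-ratio inversion at χ²₁(0.95)) are available
via `ci_method="profile"`. Hazard typing from the shape CI: upper limit < 1
→ initial-failure, lower limit > 1 → wear-out, else constant. The estimator
is scale-equivariant (onset days × c multiplies α̂ by c, leaves β̂ alone),
which the tests assert, and is cross-checked against a dense grid-search
maximiser and against `scipy.stats.weibull_min.fit(floc=0)`.

## Survival comparison

Kaplan-Meier product-limit curves per stratum (lifelines), with ties handled
by the standard aggregated-increment formula; with no censoring the curve
equals 1 − empirical CDF exactly and ends at 0, which the tests assert.
Pairwise two-sample log-rank tests use the hypergeometric variance at each
distinct event time (χ², 1 df). Two identical constant samples have zero
variance everywhere and are reported as χ² = 0, p = 1. Pairwise p-values are
reported raw, matching the convention for a small number of planned
contrasts; a Bonferroni column is available by flag. No hazard-ratio (Cox)
estimation and no confidence bands: the comparison is the test itself.

## Association-rule mining

Transactions: one per case with a binnable onset; items are all suspect-drug
generic names (the target drug included as its own item, so rules with and
without it are both emitted) plus the case's indication labels; the
consequent is the 100-day bin containing the onset (1-100 … 1001-1095;
onsets beyond 1095 days drop the case from mining and are counted).

Frequent itemsets come from a level-wise apriori with the downward-closure
prune, exact by construction and verified against exhaustive enumeration on
small random instances. Default thresholds: min support and min confidence
5e-9 (effectively "count ≥ 1", the published configuration), `maxlen = 3`
bounding |lhs| + 1. Because published rule tables nonetheless contain longer
antecedents, `maxlen=None` (unbounded) and a separate `max_lhs` are provided.

Rules `X ⇒ bin` with non-empty X are scored by support P(X∪Y), coverage
P(X), confidence = support/coverage, lift = confidence/P(Y), count =
support·D, and

    χ² = D·(lift−1)²·(support·confidence) / ((confidence−support)·(lift−confidence)),

algebraically the Pearson χ² (1 df) of the rule's 2×2 table when D is the
transaction count (property-tested against `scipy.stats.chi2_contingency` on
random tables). Independence (lift = 1) gives 0; a contingency with
coverage = 1 or P(Y) = 1 makes the statistic undefined and the rule is kept
but flagged degenerate. `chi2_d` is configurable ("auto" = mined transaction
count, or an explicit integer) because published statistics are sometimes
computed with an externally fixed D — e.g. the extracted case count rather
than the mined transaction count. Reported rules are restricted to lift > 1;
χ² > 3.84 (5% level, 1 df) is an annotation, not a filter. Ordering is
deterministic: (bin, confidence desc, support desc, lexicographic lhs).
Measures are printed at 7 decimals with full precision retained internally.

## Synthetic data generator

The generator emulates a single-drug cohort extract: per case an indication
mixture draw (optionally a second indication with probability 0.2, matching
the ~20% excess of stratum memberships over cases in the reference cohort),
the target drug always suspect, combination agents drawn per-indication,
onset days from the *primary* indication's Weibull, event date = start +
onset, and a categorical outcome. Defaults are the reference study's
conditions: mixture weights from the published per-indication case counts,
per-indication (α, β) from the published Weibull table, sex/age margins from
the published demographics including their missingness, an outcome vector
giving 64.7% improvement among classified outcomes with 8% unknown, a 28%
partial-date fraction (1527 analyzable of 2112 extracted), and a 10%
non-query decoy reaction rate. Onset draws are discretized by ceiling (≥ 1),
preserving positivity at day resolution; note that ceiling compresses the
sub-day tail and biases β̂ upward by a few percent for β < 1 at these scales,
which is why MLE-recovery properties are asserted on continuous draws while
pipeline-recovery assertions use a 5% tolerance.

`ground_truth()` returns the planted quantities in machine-readable form:
per-stratum (α, β) and the closed-form median α(ln 2)^{1/β}, expected outcome
proportions and exclusion fractions, per-stratum and marginal bin
probabilities `F(hi) − F(lo−1)` (the ceiling-discretized cell masses), and
the implied lift of every `{indication} ⇒ bin` rule under single membership.

What the generator does **not** model: reporting biases, duplicate/follow-up
reports, secular trends, within-case dependence between drugs and outcome,
real free-text noise (reasons are drawn from a fixed phrase list), or
censoring. Passing tests therefore demonstrate correctness of the pipeline's
computations under the stated generative assumptions — not the
epidemiological validity of any signal in real SRS data, which remains
subject to the usual disproportionality caveats (no denominators, no
comparison group).

## Problem sizes and numerical choices

The test suite runs the full pipeline at 300–2000 synthetic cases, parameter
recovery at n = 5000 per stratum, log-rank power/type-I at 200 replicates of
500 per arm, the permutation oracle at 10,000 draws on small samples, and
the apriori-vs-enumeration property on ≤ 12-item universes — sizes chosen so
each property is sharply testable while the whole suite stays in the
half-minute range. Root finding uses Brent's method with expanding brackets
(xtol 1e-13 on β); quantile and CI conventions are parameters, not
constants; all randomness descends from explicit integer seeds, and the
pipeline threads one seed through generation and analysis so a run is
reproducible from its config alone.

## Known limitations

Only duplicate-id detection, no JADER version/follow-up reconciliation; no
MedDRA hierarchy traversal (the SMQ is a flat PT list, narrow/broad scopes
are not distinguished); reporting ratios need externally supplied
per-indication report totals (they are whole-database quantities); and the
keyword classifier is substring-based — reasonable for the bundled English
phrase lists, but real Japanese free text will need an extended rule file.
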