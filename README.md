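# jaderpv

Pharmacovigilance analysis of spontaneous adverse-event reports in the JADER
four-table dialect (DEMO, DRUG, HIST, REAC), built around one question: for a
given suspect drug, **when** does a given adverse event occur after treatment
start, how does that timing differ by indication, and which drug combinations
are associated with early or late onset?

The reference use case is bevacizumab-induced gastrointestinal perforation —
a rare but severe event in patients treated with the anti-VEGF antibody — but
every component is parameterised by drug name, MedDRA SMQ and keyword rule
set, so any drug/event pair in a JADER-shaped extract can be analysed.

## What it computes

1. **Cohort extraction.** The four tables are joined relationally on case id;
   cases are kept when the target drug appears with *suspect* involvement and
   at least one reaction's preferred-term (PT) code falls in a standardized
   MedDRA query (SMQ). The gastrointestinal-perforation SMQ (code 20000107,
   96 PTs) ships with the package. Free-text reasons for use are mapped to
   indication categories (colorectal, NSCLC, breast, malignant glioma,
   ovarian, cervical, hepatocellular, other, no entry) by ordered substring
   rules; outcomes are dichotomized into improvement vs no improvement.

2. **Time-to-onset (TTO).** Onset = days from the earliest complete start
   date of the suspect drug to the earliest complete SMQ event date (partial
   dates excluded, not imputed). Per indication stratum it reports the
   median and quartiles and the uncensored two-parameter Weibull MLE
   `f(t) = (β/α)(t/α)^(β-1) exp(-(t/α)^β)` with 95% Wald CIs on the
   log-parameter scale. The shape CI types the hazard: upper limit < 1 →
   initial-failure (decreasing hazard), lower limit > 1 → wear-out
   (increasing), otherwise constant.

3. **Survival comparison.** Kaplan-Meier onset curves per stratum (every
   report is an event; no censoring) and pairwise two-sample log-rank tests.

4. **Association-rule mining.** Each case becomes a transaction of its
   suspect-drug names plus indication labels, with a 100-day onset bin
   (1-100 … 1001-1095) as consequent. A level-wise apriori mines frequent
   itemsets; rules `X ⇒ bin` are scored with support, confidence, coverage,
   lift, count and a chi-squared statistic computed from the measures alone,

       χ² = D·(lift−1)²·(support·confidence) / ((confidence−support)(lift−confidence)),

   which equals the Pearson χ² (1 df) of the rule's 2×2 table; χ² > 3.84
   flags 5%-level significance, and only lift > 1 rules are reported.

5. **Synthetic data.** `jaderpv.synthetic_data` generates the four tables
   with known ground truth (per-indication Weibull onsets, outcome vector,
   partial-date and decoy-PT fractions), so the entire pipeline is testable
   without any database download.

## Worked example

```python
from jaderpv.pipeline import RunConfig, run_pipeline
from jaderpv.synthetic_data import SynthConfig

res = run_pipeline(RunConfig(synth=SynthConfig(n_cases=2000), seed=42))
print(res.manifest["stages"])
print(res.tables["tto_summary"][lambda t: t.stratum.isin(["all", "nsclc", "colorectal"])])
```

prints the stage manifest

```
{'rows_demo': 2000, ..., 'joined_cases': 2000, 'suspect_cases': 2000,
 'smq_cases': 1804, 'tto_cases': 1317, 'transactions': 1316, 'transactions_dropped': 488}
```

— 2000 generated cases, 1804 with an SMQ perforation term (the rest carry
decoy reactions), 1317 with complete dates on both ends — and the TTO table

```
   stratum    n  median   q1     q3   alpha  alpha_lo  alpha_hi  beta  beta_lo  beta_hi    hazard_class
       all 1317    81.0 30.0 175.00 124.646   116.738   133.090 0.869    0.833    0.906 initial_failure
colorectal  758    79.0 32.0 182.00 129.876   118.843   141.933 0.846    0.800    0.894 initial_failure
     nsclc  192    58.0 20.0 154.25  93.231    77.880   111.607 0.828    0.741    0.926 initial_failure
```

Onset in the NSCLC stratum is earlier than in colorectal cancer (generated
scale 78.6 vs 135 days), the shape CIs sit below 1 (early-onset-dominated,
decreasing hazard), and the log-rank table confirms the separation
(`colorectal` vs `nsclc`: χ² = 11.1, p = 0.0008). The same run from a shell:

```bash
jaderpv synth --n 2000 --seed 42 --out data/
jaderpv run --demo data/demo.csv --drug data/drug.csv \
            --hist data/hist.csv --reac data/reac.csv --out out/
```

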