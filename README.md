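# masldnlp

Rule-based NLP that converts free-text liver-biopsy pathology reports into
structured MASLD histology labels, plus the validation harness and
person-time incidence analysis needed to build and study biopsy-confirmed
MASLD cohorts from electronic health records.

Histopathology is the gold standard for diagnosing and staging metabolic
dysfunction–associated steatotic liver disease (MASLD) and its progressive
form, MASH, but pathology reports are free text and vary by pathologist,
hospital, and era. This package is for clinical NLP engineers and hepatology
epidemiologists who need to turn such reports into analyzable labels:

- **steatosis, lobular inflammation, hepatocyte ballooning** and a summative
  **steatohepatitis** assertion, each scored present/absent per report;
- **MASH CRN fibrosis stage** F0–F4, resolved from explicit stage statements
  ("stage 2 of 4", "F1-F2") and/or descriptive components (perisinusoidal →
  F1, perisinusoidal + periportal → F2, bridging → F3, nodularity/cirrhosis
  → F4), always taking the highest stage present;
- a report-level **MASLD category** (no steatosis, simple steatosis,
  MASH/F0–F3, cirrhosis) where MASH = steatohepatitis assertion, or the full
  triad (steatosis + lobular inflammation + ballooning), or — stage
  supersedes the triad — steatosis + stage F1–F3 + at least one MASH
  co-feature.

Scoring follows a fixed rubric: any pathologist assertion counts, omissions
are scored absent, diminutives ("minimal", "patchy", "borderline") still
count as presence, and portal inflammation never counts as lobular
inflammation. Negation is trigger-based in the NegEx style ("no", "without",
"negative for" scope forward to "but"/"however"/";"/"."; "not identified",
"is absent" scope backward), sentence-bounded. All lexicons and rules are
editable YAML; an external concept recognizer can be plugged in.

Because real report corpora carry protected health information, the package
ships a **synthetic corpus generator** that emulates report structure
(headers, gross description, diagnosis body, sign-out footers), era style
(descriptive fibrosis prose pre-2005 vs explicit CRN stage notation after),
negation phrasings, stage ranges, and contaminant reports (non-liver organs
mentioning "liver", fine-needle aspirations, hepatic tumor biopsies) — with
gold labels generated *before* the text, so validation is never circular.

The cohort module computes incidence rates per 1000 person-years with exact
Poisson (Garwood) or normal confidence intervals, absolute rate differences
with normal-approximation CIs, product-limit cumulative incidence curves, a
30-day landmark sensitivity filter, and a constant-hazard cohort simulator.

## Worked example

```python
import masldnlp as m

report = m.RawPathologyReport(
    report_id="r1", patient_id="p1", report_date="2015-06-01",
    hospital="General Hospital",
    text=(
        "Accession Number: S-2015-104\n"
        "Clinical Data: Fatty liver on ultrasound.\n"
        "Gross Description: A tan-brown core of tissue.\n"
        "Final Diagnosis:\n"
        "Liver, needle core biopsy:\n"
        "1. Moderate macrovesicular steatosis.\n"
        "2. Lobular inflammation is present.\n"
        "3. No ballooning is seen.\n"
        "4. Fibrosis stage 2 of 4.\n"
        "Electronically signed out by A. Morgan, MD.\n"
    ),
)
result = m.Annotator().annotate(report)
print([(x.concept_id.value, x.assertion.value) for x in result.mentions])
print(result.fibrosis.resolved_stage, result.label.category)
```

prints

```
[('steatosis', 'present'), ('lobular_inflammation', 'present'),
 ('ballooning', 'absent'), ('fibrosis_generic', 'present')]
Stage.F2 Category.MASH_F2
```

The header and footer were stripped before extraction; "no ballooning" was
negated by trigger scoping; and although ballooning is absent, steatosis +
lobular inflammation + CRN stage F2 is promoted to MASH/F2 by the
stage-supersedes rule.

Incidence arithmetic, from a cohort cell of 117 events over 7771
person-years:

```python
est = m.incidence_rate(117, 7771)
print(round(est.rate_per_1000, 2), round(est.ci_low, 2), round(est.ci_high, 2))
# 15.06 12.45 18.04   events per 1000 person-years [95% exact Poisson CI]
```

## Command line

```bash
masldnlp synthesize --n 900 --seed 0 --corpus corpus.jsonl --gold gold.csv
masldnlp annotate corpus.jsonl -o predicted.csv
masldnlp validate predicted.csv gold.csv -o metrics.csv
masldnlp cohort followup.csv -o risk.csv --reference simple_steatosis
```

`validate` emits one row per concept (sensitivity, specificity,
PPV/precision, NPV, F1, support); `cohort` emits events, person-years,
rates with CIs, and rate differences against a reference category.

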