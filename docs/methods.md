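# Methods

This note documents the models and procedures behind `masldnlp`, the
parameters that matter, what the synthetic benchmark does and does not
show, and the design decisions taken where the design was genuinely open.

## The extraction pipeline

Annotation is a deterministic function of the report text and the rule
files. It runs in five stages.

**1. Boilerplate stripping.** Reports are NFKC-normalized and parsed line
by line against configurable heading-marker lists (`resources/
boilerplate.yaml`). Text before the first diagnosis-style heading ("Final
Diagnosis:", "Findings:", "Impression:", ...) is removed as header — with
gross-description blocks labelled separately — and text from the first
sign-out-style heading onward is removed as footer. Heading styles vary by
hospital and era, so markers are data, not code. A report with no
recognizable markers passes through unchanged; a report whose markers
leave no diagnostic text is flagged (`empty_diagnostic`), never silently
dropped. Stripping is idempotent, and all downstream character offsets are
0-based half-open intervals into the normalized text.

**2. Biopsy screening.** Simple case-insensitive matching decides whether
the diagnostic section describes a parenchymal liver biopsy. Reports with
a non-liver specimen line ("Colon, biopsy", "Bone marrow, biopsy"),
hepatic-tumor phrases ("hepatocellular carcinoma", "Liver, mass"), or
fine-needle-aspiration phrases are excluded, as are reports that never
mention "liver" or "hepatic". When several cues fire, precedence is fixed
for determinism: non-liver organ > tumor biopsy > fine-needle aspiration.

**3. Concept extraction.** Sentences are segmented at `.;!?` and newlines,
with two exceptions: a period after a bare list-item enumerator ("1.",
"2.") and a period inside a decimal number do not terminate. The
recognizer is a curated-lexicon matcher (`resources/lexicon.yaml`):
surface forms are matched with word boundaries, longest match wins among
overlapping candidates (so "steatohepatitis" is never additionally a
steatosis hit), and a small coordination rule expands "portal and lobular
inflammation" so each conjunct is matched as "<conjunct> inflammation".
The original system this package re-implements used a UMLS-driven
recognizer; UMLS licensing prevents redistributing that dictionary, so the
bundled lexicon is a curated reconstruction, user-editable, and the
`Annotator` accepts any external recognizer callable in its place — all
downstream logic operates on (concept, assertion) pairs regardless of
recognizer.

**4. Negation.** Trigger-based scoping in the NegEx style, sentence-
bounded. Pre-triggers ("no", "without", "negative for", "absence of")
negate forward to the nearest scope terminator ("but", "however",
"although", ";", ":", "."); post-triggers ("not identified", "is absent")
negate backward. Commas are deliberately not terminators, so chains like
"no steatosis, ballooning, or lobular inflammation" negate throughout.
Diminutives ("minimal", "patchy", "borderline", "mild", "focal") are not
triggers: under the scoring rubric they count as presence. Double negation
is not resolved (treated as absent) to keep the rules auditable. Matching
is case-insensitive via `str.casefold`, which is length-preserving for the
clinical English this targets; offsets are computed on the folded text.

**5. Rubric collapse, staging, categorization.** A feature is true iff at
least one present-asserted mention exists; omissions are absent; a
present/absent conflict within one report resolves to present with a
conflict flag (pathologists often negate in findings then affirm focally
in the impression). Portal/interface inflammation never sets lobular
inflammation; zone-3/centrilobular forms are lexicalized directly as
lobular inflammation.

## Fibrosis staging

Explicit stage statements are parsed first: "stage N", "stage N of M",
"N/M", bare "F N", ranges "N-M"/"N to M" (both bounds recorded), Arabic or
Roman numerals, with the denominator recorded when stated. Stage tokens
outside 0–6 are flagged malformed and ignored. Component flags are set
only from present-asserted fibrosis-pattern mentions. The resolved stage
is the maximum over all candidates: in-scale explicit stages (denominator
4 or unstated, value ≤ 4), component-mapped stages (perisinusoidal → 1,
perisinusoidal + zone 1 → 2, bridging → 3, nodularity → 4), and 4 whenever
cirrhosis is asserted. Hence "F1-F2" → F2 and "F2 with focal areas of
bridging" → F3. With no candidates, the report is F0 — by negation when a
fibrosis-family concept was explicitly denied, by omission otherwise.

Two open choices, both flagged in output for audit:

- **Ishak-style "of 6" stages are not remapped.** No published crosswalk
  onto the CRN scale is assumed; an out-of-scale stage alone yields
  `unstaged` with a scale-mismatch flag, and staging falls back to
  components when present. A wrong silent mapping would corrupt the
  endpoint definition.
- **Zone-1/periportal fibrosis alone maps to an F1-equivalent candidate**
  (the CRN 1c analog), not F2: CRN stage 2 requires both zones, and
  promoting zone-1-only would overstage.

## MASLD categorization

With steatosis absent the category is `no_steatosis`; at stage F4 it is
`cirrhosis_f4` (a cirrhosis assertion forces F4 even over a lower explicit
stage — highest-stage rule). Otherwise MASH is positive when the
pathologist asserts steatohepatitis, when all three elements (steatosis,
lobular inflammation, ballooning) are present, or — the stage-supersedes
rule — when stage F1–F3 co-occurs with at least one of lobular
inflammation, ballooning, or an assertion. Whether bland fibrotic
steatosis (stage F1–F3, no MASH co-feature at all) should also be promoted
is genuinely ambiguous; the default keeps it simple steatosis with an
audit note, and `ClassificationPolicy(supersede_requires_feature=False)`
switches the behavior. MASH with unstaged fibrosis defaults to MASH/F0
(omission-scored-absent principle), audited. A "borderline
steatohepatitis" assertion sets MASH (diminutives count), behind a policy
switch.

Steatotic reports with exactly one of ballooning or lobular inflammation
are *borderline*: excluded from primary cohort strata, and in the
sensitivity mode recategorized (ballooning-only → MASH/F0,
inflammation-only → simple steatosis).

## Validation metrics

Ten concepts are scored one-vs-rest against gold labels: the four core
features, cirrhosis, and stages F0–F4. Sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn), F1 =
harmonic mean of PPV and sensitivity, all in percent; display rounding is
one decimal with full precision retained internally; a zero-denominator
metric is reported as not applicable, never 0. Support is the count of
gold positives (tp+fn): of the two circulating definitions ("count of true
positives" vs "actual occurrences of the element"), the latter matches
standard usage and coincides with the former only for a perfect
classifier. When F1 is recomputed from a table's already-rounded
precision/recall, upstream rounding can shift the final printed decimal by
0.1; tests use that tolerance.

## The synthetic corpus generator

The generator emulates the structure and style of multi-decade hospital
pathology corpora: accession/clinical/gross headers with recorded section
boundaries, a diagnosis body (numbered lists in the modern era, prose
earlier), sign-out footers, and contaminant report types at a configurable
fraction. Era matters because fibrosis reporting changed around 2005:
pre-2005 templates use descriptive prose ("pericellular fibrosis in zone
3", "bridging fibrosis"), post-2005 templates use explicit CRN notation
("stage 2 of 4", "F1-F2"). Adversarial templates exercise stage ranges,
explicit-stage-plus-component combinations, Ishak-denominator strings with
component fallback, negation chains, diminutives, and "but"-scope breaks.

Gold labels are drawn first — a category, then a feature realization
consistent with the classification truth table — and text is rendered from
the label, never the reverse, so gold is independent of the extractor.
Absent features are realized as explicit negation sentences with
probability `negation_realization_rate` (default 0.5) and omitted
otherwise. Defaults: 900 reports; category mix of 14% each for simple
steatosis, MASH/F0–F3 and cirrhosis, 6% non-steatotic liver, and 10%
contaminants; 65% post-2005; adversarial rate 0.25. At these defaults a
900-report corpus supplies at least 100 gold positives of every scored
concept, mirroring a validation design balanced across concepts and
decades. The same spec and seed yield byte-identical corpora.

What passing this benchmark shows — and does not. The templates are built
from the same terminology family as the bundled lexicon, so perfect
round-trip accuracy demonstrates the internal consistency of the rule
logic (negation scoping, staging maxima, rubric collapse, screening
precedence), not performance on real reports, whose vocabulary is open,
whose section headings are noisier, and whose negations can be
syntactically unbounded. The generator makes no attempt to mimic real
report length or vocabulary distributions. Against real corpora the
lexicon and rule files are the tuning surface.

## Incidence analysis

Rates are events per 1000 person-years. The default interval is the exact
Poisson (Garwood) chi-square interval on the count — lower bound
χ²(α/2, 2k)/2 (0 when k = 0), upper bound χ²(1−α/2, 2k+2)/2 — scaled by
1000/PY; this is the method that reproduces the printed reference
intervals, although such tables sometimes describe their intervals as
normal approximations; the normal method is available via
`method="normal"`. Rate differences use unrounded rates with SE =
1000·√(events_a/PY_a² + events_b/PY_b²). Cumulative incidence is 1 − S
from the product-limit estimator (via lifelines), censoring at end of
follow-up. A 30-day landmark filter drops patients whose event fell within
the window. Cox modelling is deliberately out of scope; `survival_frame`
exposes the analysis dataset in a survival-ready layout for any standard
fitter.

The cohort simulator draws exponential event times at stated per-1000-PY
hazards with administrative censoring at 25 years, emulating a registry
with a multi-decade observation window. At 1000 patients per group this
yields roughly 200–900 events per group, so the events/PY estimator
recovers hazards of 15–86 per 1000 PY with a relative standard error of
3–7%, comfortably inside the 15% acceptance band.

## Numerical and degenerate-input conventions

Empty diagnostic sections are flagged and produce no label; reports
screened out produce screen metadata only. Duplicate report ids are a hard
error at ingestion, as are misaligned id sets at metric time (listing the
offending ids). Ties among overlapping lexicon matches of equal length go
to the earlier span. Denominators other than 4 or 6 on explicit stages are
treated as unstated. All randomness in generation and simulation flows
through a single `numpy` Generator seeded from the spec.

## Known limitations

Addendum/amendment threading, de-identification, steatosis grading, NAS/
SAF composite scores, machine-learned NER, hedging/uncertainty classes,
competing-risks estimators, and covariate-adjusted hazard modelling are
out of scope. Coincident-disease detection is report-text-only; a real
cohort build would add record-level exclusions (alcohol use, steatogenic
medications, transplant status) from structured data. The bundled heading
markers and screening term lists are reconstructions and should be
extended per site.
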