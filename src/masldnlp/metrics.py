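"""Validation metrics: confusion counts and performance rows per concept.

Algorithm output is scored against manual gold labels one concept at a
time. The ten validated concepts are the four core MASLD features,
cirrhosis, and the five fibrosis stages scored one-vs-rest. Sensitivity
(recall), specificity, PPV (precision), NPV and the F1 score (harmonic
mean of precision and recall) are reported as percentages; support is the
number of gold-positive reports. A metric whose denominator is zero is
reported as not applicable (None), never as 0.
"""
from __future__ import annotations

import pandas as pd

from .types import ConfusionCounts, PerformanceRow

VALIDATED_CONCEPTS = [
    "steatosis",
    "lobular_inflammation",
    "ballooning",
    "steatohepatitis",
    "cirrhosis",
    "F0",
    "F1",
    "F2",
    "F3",
    "F4",
]


def tabulate_confusion(
    predicted: dict[str, bool], gold: dict[str, bool], concept: str
) -> ConfusionCounts:
    """Count tp/fp/fn/tn for one concept over report-id-aligned labels.

    ``predicted`` and ``gold`` map report_id -> binary label for the
    concept (stage concepts already binarized one-vs-rest). Report ids
    must coincide exactly.
    """
    only_pred = set(predicted) - set(gold)
    only_gold = set(gold) - set(predicted)
    if only_pred or only_gold:
        raise ValueError(
            f"report ids do not align for {concept!r}: "
            f"only in predicted={sorted(only_pred)[:5]}, "
            f"only in gold={sorted(only_gold)[:5]}"
        )
    tp = fp = fn = tn = 0
    for rid, g in gold.items():
        p = predicted[rid]
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(concept=concept, tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def f1_from_percentages(ppv: float, sensitivity: float) -> float | None:
    """Harmonic mean of precision and recall, both given in percent."""
    if ppv + sensitivity == 0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def compute_performance(cc: ConfusionCounts) -> PerformanceRow:
    """Sensitivity/specificity/PPV/NPV/F1 (percent) for one concept.

    Full precision is retained internally; display rounding to one decimal
    belongs to the table writer.
    """
    sens = _ratio(cc.tp, cc.tp + cc.fn)
    spec = _ratio(cc.tn, cc.tn + cc.fp)
    ppv = _ratio(cc.tp, cc.tp + cc.fp)
    npv = _ratio(cc.tn, cc.tn + cc.fn)
    f1 = None if sens is None or ppv is None else f1_from_percentages(ppv, sens)
    return PerformanceRow(
        concept=cc.concept,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f1=f1,
        support=cc.tp + cc.fn,
        n=cc.n,
    )


def performance_table(
    predicted: pd.DataFrame,
    gold: pd.DataFrame,
    concepts: list[str] | None = None,
) -> pd.DataFrame:
    """Score predicted vs gold frames (indexed or keyed by report_id) for
    every concept and return a table shaped like a validation report."""
    concepts = concepts or VALIDATED_CONCEPTS
    pred = predicted.set_index("report_id") if "report_id" in predicted else predicted
    gld = gold.set_index("report_id") if "report_id" in gold else gold
    rows = []
    for concept in concepts:
        cc = tabulate_confusion(
            pred[concept].astype(bool).to_dict(),
            gld[concept].astype(bool).to_dict(),
            concept,
        )
        row = compute_performance(cc)
        rows.append(
            {
                "concept": concept,
                "n": row.n,
                "sensitivity": _round1(row.sensitivity),
                "specificity": _round1(row.specificity),
                "ppv": _round1(row.ppv),
                "npv": _round1(row.npv),
                "f1": _round1(row.f1),
                "support": row.support,
            }
        )
    return pd.DataFrame(rows)


def disagreements(
    predicted: pd.DataFrame,
    gold: pd.DataFrame,
    concepts: list[str] | None = None,
) -> pd.DataFrame:
    """Per-report disagreement listing (report_id, concept, predicted, gold)."""
    concepts = concepts or VALIDATED_CONCEPTS
    pred = predicted.set_index("report_id") if "report_id" in predicted else predicted
    gld = gold.set_index("report_id") if "report_id" in gold else gold
    rows = []
    for concept in concepts:
        p = pred[concept].astype(bool)
        g = gld[concept].astype(bool).reindex(p.index)
        for rid in p.index[p != g]:
            rows.append(
                {
                    "report_id": rid,
                    "concept": concept,
                    "predicted": bool(p[rid]),
                    "gold": bool(g[rid]),
                }
            )
    return pd.DataFrame(rows, columns=["report_id", "concept", "predicted", "gold"])


def _round1(x: float | None) -> float | None:
    return None if x is None else round(x, 1)
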