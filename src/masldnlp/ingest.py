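"""Report ingestion: boilerplate stripping and liver-biopsy screening.

Pathology reports arrive with accession headers, clinical context, gross
specimen descriptions and sign-out footers around the diagnostic text. Only
the findings/impression text is fed to concept extraction. Reports are then
screened so that only bona fide parenchymal liver biopsies enter the
cohort: biopsies of other organs that merely mention "liver" or "hepatic",
liver fine-needle aspirations, and biopsies of hepatic tumors are excluded.

All downstream character offsets refer to the NFKC-normalized report text.
"""
from __future__ import annotations

import csv
import json
import unicodedata
from pathlib import Path
from typing import Iterable, Iterator

from .config import (
    BoilerplateRules,
    ScreenLexicon,
    load_boilerplate_rules,
    load_screen_lexicon,
)
from .types import (
    BiopsyScreenResult,
    DiagnosticSection,
    ExclusionReason,
    RawPathologyReport,
    RemovedSpan,
)


def _nfkc(text: str) -> str:
    return unicodedata.normalize("NFKC", text)


def _match_heading(line: str, headings: tuple[str, ...]) -> int | None:
    """Return the length of the matched heading marker, or None."""
    lowered = line.lower()
    best = None
    for h in headings:
        if lowered.startswith(h) and (best is None or len(h) > best):
            best = len(h)
    return best


def strip_report_boilerplate(
    report: RawPathologyReport,
    rules: BoilerplateRules | None = None,
) -> DiagnosticSection:
    """Remove headers, gross description, and footers from a report.

    Heading markers are matched case-insensitively at line starts. Text
    before the first diagnosis heading is removed (label ``header``, or
    ``gross`` inside a gross-description block); text from the first
    footer-style heading after the diagnosis onward is removed (label
    ``footer``, or ``gross`` for a trailing gross block). A report with no
    recognizable markers is returned unchanged. A report whose markers
    leave no diagnostic text is flagged via ``empty_diagnostic`` rather
    than dropped.

    The operation is idempotent: re-stripping the returned diagnostic text
    leaves it unchanged.
    """
    if rules is None:
        rules = load_boilerplate_rules()
    text = _nfkc(report.text)

    # split into lines, keeping offsets; the trailing newline stays with its line
    lines: list[tuple[int, int]] = []
    pos = 0
    while pos < len(text):
        nl = text.find("\n", pos)
        end = len(text) if nl == -1 else nl + 1
        lines.append((pos, end))
        pos = end

    removed: list[RemovedSpan] = []
    pieces: list[str] = []
    state = "header"  # header -> diagnosis -> footer
    in_gross = False
    saw_marker = False

    for start, end in lines:
        line = text[start:end]
        stripped = line.lstrip()
        indent = len(line) - len(stripped)
        diag_len = _match_heading(stripped, rules.diagnosis_headings)
        head_len = _match_heading(stripped, rules.header_headings)
        foot_len = _match_heading(stripped, rules.footer_headings)
        gross_len = _match_heading(stripped, rules.gross_headings)
        # a gross heading is also a header heading; prefer diagnosis over both
        if diag_len is not None and (head_len is None or diag_len >= head_len):
            saw_marker = True
            if state == "footer":
                removed.append(RemovedSpan("footer", start, end))
                continue
            state = "diagnosis"
            in_gross = False
            marker_end = start + indent + diag_len
            removed.append(RemovedSpan("header", start, marker_end))
            rest = text[marker_end:end]
            pieces.append(rest.lstrip() if rest.strip() else rest)
            continue
        if state == "header":
            if head_len is not None or foot_len is not None:
                saw_marker = True
                in_gross = gross_len is not None
            label = "gross" if in_gross else "header"
            removed.append(RemovedSpan(label, start, end))
        elif state == "diagnosis":
            if foot_len is not None or head_len is not None:
                saw_marker = True
                state = "footer"
                in_gross = gross_len is not None
                label = "gross" if in_gross else "footer"
                removed.append(RemovedSpan(label, start, end))
            else:
                pieces.append(line)
        else:  # footer
            label = "gross" if in_gross else "footer"
            removed.append(RemovedSpan(label, start, end))

    if not saw_marker:
        # no recognizable sections: the whole text is diagnostic
        return DiagnosticSection(report.report_id, text, [])

    diagnostic = "".join(pieces).strip()
    merged = _merge_spans(removed)
    return DiagnosticSection(
        report.report_id,
        diagnostic,
        merged,
        empty_diagnostic=not diagnostic,
    )


def _merge_spans(spans: list[RemovedSpan]) -> list[RemovedSpan]:
    """Coalesce adjacent removed spans with the same label."""
    out: list[RemovedSpan] = []
    for s in sorted(spans, key=lambda s: s.start):
        if out and out[-1].label == s.label and out[-1].end == s.start:
            out[-1] = RemovedSpan(s.label, out[-1].start, s.end)
        else:
            out.append(s)
    return out


def screen_parenchymal_biopsy(
    section: DiagnosticSection,
    screen_lexicon: ScreenLexicon | None = None,
) -> BiopsyScreenResult:
    """Decide whether a diagnostic section describes a parenchymal liver biopsy.

    Simple case-insensitive text matching, with fixed precedence when
    several exclusion cues fire: non-liver specimen organ beats hepatic
    tumor, which beats fine-needle aspiration; a report with no liver
    mention at all is excluded as ``no_liver_mention``.
    """
    if screen_lexicon is None:
        screen_lexicon = load_screen_lexicon()
    t = section.diagnostic_text.casefold()

    reason = ExclusionReason.NONE
    if any(p in t for p in screen_lexicon.non_liver_specimens):
        reason = ExclusionReason.NON_LIVER_ORGAN
    elif any(p in t for p in screen_lexicon.tumor_phrases):
        reason = ExclusionReason.TUMOR_BIOPSY
    elif any(p in t for p in screen_lexicon.fna_phrases):
        reason = ExclusionReason.FINE_NEEDLE_ASPIRATION
    elif not any(p in t for p in screen_lexicon.liver_terms):
        reason = ExclusionReason.NO_LIVER_MENTION

    return BiopsyScreenResult(
        report_id=section.report_id,
        is_parenchymal_liver_biopsy=reason is ExclusionReason.NONE,
        exclusion_reason=reason,
    )


# ---------------------------------------------------------------------------
# report I/O


def read_reports(path: str | Path) -> list[RawPathologyReport]:
    """Read reports from JSONL or CSV (columns: report_id, patient_id,
    report_date, hospital, text). Report ids must be unique."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records: Iterable[dict] = list(csv.DictReader(path.open(encoding="utf-8")))
    else:
        records = (json.loads(line) for line in path.open(encoding="utf-8") if line.strip())
    reports = [
        RawPathologyReport(
            report_id=str(r["report_id"]),
            patient_id=str(r.get("patient_id", "")),
            report_date=r.get("report_date", ""),
            hospital=str(r.get("hospital", "")),
            text=r["text"],
        )
        for r in records
    ]
    seen: set[str] = set()
    for rep in reports:
        if rep.report_id in seen:
            raise ValueError(f"duplicate report_id {rep.report_id!r}")
        seen.add(rep.report_id)
    return reports


def write_reports_jsonl(reports: Iterator[RawPathologyReport] | list, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "patient_id": r.patient_id,
                        "report_date": str(r.report_date),
                        "hospital": r.hospital,
                        "text": r.text,
                    }
                )
                + "\n"
            )
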