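"""Cohort summarization, funnel tables and per-case report rendering.

Diagnostic yield arithmetic follows clinical reporting conventions: yields
to one decimal, reanalysis rates to the nearest integer percent, both with
half-up rounding. Case reports are deterministic plain text rendered from
``string.Template`` files; an unsolved case renders the negative-report
template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from string import Template

import pandas as pd

from .cnv import CnvEvent
from .prioritize import (
    NEEDS_CONFIRMATION,
    Candidate,
    CaseOutcome,
    FunnelReport,
    OutcomeLabel,
)
from .types import CaseMode, SampleCase


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    counts: dict[OutcomeLabel, int]
    by_category: dict[str, dict[OutcomeLabel, int]]
    total: int
    positive_yield: float
    combined_yield: float
    percentages: dict[OutcomeLabel, float] = field(default_factory=dict)


def summarize_cohort(
    outcomes: list[tuple[SampleCase, CaseOutcome]]
) -> CohortSummary:
    """Diagnostic yields over a cohort of diagnostic-mode cases.

    positive_yield = 100 x positives / total; combined_yield adds the
    uncertain cases (those that may ultimately prove positive). Both are
    rounded half-up to one decimal, matching clinical-audit reporting.
    """
    diag = [(c, o) for c, o in outcomes if c.mode is CaseMode.DIAGNOSTIC]
    if not diag:
        raise ValueError("empty diagnostic cohort")
    counts = {label: 0 for label in OutcomeLabel}
    by_cat: dict[str, dict[OutcomeLabel, int]] = {}
    for case, out in diag:
        counts[out.label] += 1
        cat = by_cat.setdefault(case.category or "unspecified", {
            label: 0 for label in OutcomeLabel
        })
        cat[out.label] += 1
    total = len(diag)
    pos = counts[OutcomeLabel.POSITIVE]
    unc = counts[OutcomeLabel.UNCERTAIN]
    return CohortSummary(
        counts=counts,
        by_category=by_cat,
        total=total,
        positive_yield=round_half_up(100.0 * pos / total, 1),
        combined_yield=round_half_up(100.0 * (pos + unc) / total, 1),
        percentages={
            label: round_half_up(100.0 * n / total, 1)
            for label, n in counts.items()
        },
    )


def reanalysis_rate(n_solved: int, n_reanalyzed: int) -> int:
    """Percent of reanalyzed negative/inconclusive cases later solved,
    rounded half-up to the nearest integer."""
    if n_reanalyzed <= 0:
        raise ValueError("n_reanalyzed must be positive")
    if n_solved > n_reanalyzed:
        raise ValueError("n_solved exceeds n_reanalyzed")
    return int(round_half_up(100.0 * n_solved / n_reanalyzed, 0))


def funnel_table(reports: list[FunnelReport]) -> pd.DataFrame:
    """Per-stage mean/min/max counts across cases, plus the percent
    reduction attributable to the virtual-panel stage."""
    if not reports:
        raise ValueError("no funnel reports")
    stage_names = [s for s, _ in reports[0].stages]
    for r in reports[1:]:
        if [s for s, _ in r.stages] != stage_names:
            raise ValueError("funnel reports have mismatched stage names")
    data = {name: [r.count(name) for r in reports] for name in stage_names}
    df = pd.DataFrame(
        {
            "stage": stage_names,
            "mean": [float(pd.Series(data[s]).mean()) for s in stage_names],
            "min": [min(data[s]) for s in stage_names],
            "max": [max(data[s]) for s in stage_names],
        }
    )
    raw_mean = df.loc[df["stage"] == "raw", "mean"].iloc[0]
    panel_mean = df.loc[df["stage"] == "panel", "mean"].iloc[0]
    df.attrs["panel_reduction_pct"] = (
        round_half_up(100.0 * (1.0 - panel_mean / raw_mean), 1)
        if raw_mean > 0
        else 0.0
    )
    return df


_DEFAULT_POSITIVE = Template(
    """GENETIC TEST REPORT — sample ${sample_id}
Clinical category: ${category}
Panels applied: ${panels}
Outcome: ${outcome}

Candidate variants (ranked):
${candidate_rows}
CNV events:
${cnv_rows}
${confirmation_section}"""
)

_DEFAULT_NEGATIVE = Template(
    """GENETIC TEST REPORT — sample ${sample_id}
Clinical category: ${category}
Panels applied: ${panels}
Outcome: ${outcome}

No causative variants were identified in the genes analyzed; a negative
report is emitted. This does not exclude variants outside the applied
panels, deep-intronic variation, or variant types the assay cannot detect.
"""
)


def _candidate_row(c: Candidate) -> str:
    v = c.variant
    maf = f"{v.max_maf:.2e}" if v.max_maf is not None else "NA"
    pairing = (
        f"{c.pairing[0]}:{c.pairing[1]}:{c.pairing[2]}>{c.pairing[3]}"
        if c.pairing
        else "-"
    )
    flags = ",".join(sorted(f for f in c.flags if not f.startswith("zyg:"))) or "-"
    return (
        f"  {c.rank}. {v.chrom}:{v.pos} {v.ref}>{v.alt} {v.gene} "
        f"{v.zygosity.value} {v.clin_class.value} maf={maf} "
        f"vaf={v.vaf if v.vaf is not None else 'NA'} depth={v.depth} "
        f"hgvs={v.hgvs or '-'} pair={pairing} flags={flags}"
    )


def render_case_report(
    case: SampleCase,
    candidates: list[Candidate],
    events: list[CnvEvent],
    outcome: CaseOutcome,
    template_path: str | Path | None = None,
    negative_template_path: str | Path | None = None,
) -> str:
    """Render one case's deterministic plain-text report.

    UNSOLVED cases render the negative-report template; every candidate
    flagged NEEDS_CONFIRMATION appears in the confirmation section.
    """
    common = {
        "sample_id": case.sample_id,
        "category": case.category or "unspecified",
        "panels": ",".join(case.panels),
        "outcome": outcome.label.value,
    }
    if outcome.label is OutcomeLabel.UNSOLVED:
        tmpl = (
            Template(Path(negative_template_path).read_text(encoding="utf-8"))
            if negative_template_path
            else _DEFAULT_NEGATIVE
        )
        return tmpl.substitute(common)

    needs = [c for c in candidates if NEEDS_CONFIRMATION in c.flags]
    confirmation = ""
    if needs:
        rows = "\n".join(
            f"  {c.variant.chrom}:{c.variant.pos} {c.variant.ref}>{c.variant.alt}"
            f" (depth {c.variant.depth})"
            for c in needs
        )
        confirmation = (
            "Variants below the confirmation depth floor, requiring orthogonal"
            f" (Sanger) confirmation:\n{rows}\n"
        )
    cnv_rows = "\n".join(
        f"  {e.gene} {e.type.value} n_targets={e.n_targets} "
        f"mean_dose={e.mean_dose:.3f} extreme_z={e.extreme_z:.2f}"
        for e in events
    ) or "  none"
    cand_rows = "\n".join(_candidate_row(c) for c in candidates) or "  none"
    tmpl = (
        Template(Path(template_path).read_text(encoding="utf-8"))
        if template_path
        else _DEFAULT_POSITIVE
    )
    return tmpl.substitute(
        **common,
        candidate_rows=cand_rows,
        cnv_rows=cnv_rows,
        confirmation_section=confirmation,
    )


def write_candidates_tsv(candidates: list[Candidate], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "rank\tchrom\tpos\tref\talt\tgene\tzygosity\tclin_class\t"
            "max_maf\tvaf\tdepth\tpairing\tflags\n"
        )
        for c in candidates:
            v = c.variant
            pairing = (
                f"{c.pairing[0]}:{c.pairing[1]}:{c.pairing[2]}>{c.pairing[3]}"
                if c.pairing
                else ""
            )
            flags = ";".join(sorted(c.flags))
            maf = repr(v.max_maf) if v.max_maf is not None else ""
            fh.write(
                f"{c.rank}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t"
                f"{v.zygosity.value}\t{v.clin_class.value}\t{maf}\t"
                f"{v.vaf if v.vaf is not None else ''}\t"
                f"{v.depth if v.depth is not None else ''}\t{pairing}\t{flags}\n"
            )


def write_funnel_tsv(report: FunnelReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stage\tcount\n")
        for name, count in report.stages:
            fh.write(f"{name}\t{count}\n")


def write_outcome_json(
    case: SampleCase, outcome: CaseOutcome, path: str | Path
) -> None:
    doc = {
        "sample_id": case.sample_id,
        "mode": case.mode.value,
        "outcome": outcome.label.value,
        "supporting": [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "gene": c.variant.gene,
                "zygosity": c.variant.zygosity.value,
                "clin_class": c.variant.clin_class.value,
                "rank": c.rank,
            }
            for c in outcome.supporting
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_cnv_events_tsv(events: list[CnvEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "sample\tgene\tchrom\tstart\tend\tn_targets\tmean_dose\textreme_z\ttype\n"
        )
        for e in events:
            fh.write(
                f"{e.sample_id}\t{e.gene}\t{e.span[0].chrom}\t{e.span[0].start}\t"
                f"{e.span[1].end}\t{e.n_targets}\t{e.mean_dose:.6f}\t"
                f"{e.extreme_z:.6f}\t{e.type.value}\n"
            )
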