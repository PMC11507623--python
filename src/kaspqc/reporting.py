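"""Assemble and write the annotated QC report.

The report mirrors what breeders review after a QC run: the original
genotype grid with per-cell color classes (green = polymorphic parental
locus, red = monomorphic, blue = heterozygous parent, orange = offspring
heterozygous at an informative locus, purple = non-parental allele), plus
eleven summary columns per sample and two charts (a pie of hybridity
status proportions over all offspring, and a bar chart of per-marker
efficiency).

Output artifacts: an XLSX workbook with three sheets ("results",
"hybridity_chart", "marker_efficiency"), a TSV mirror of the summary
table for diff-friendly pipelines, and standalone PNG chart files.
Percentages are rendered with one decimal; undefined values as "NA".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from openpyxl import Workbook  # noqa: E402
from openpyxl.drawing.image import Image as XLImage  # noqa: E402
from openpyxl.styles import Font, PatternFill  # noqa: E402

from .qc_core import (  # noqa: E402
    ALL_STATUSES,
    STATUS_SELF,
    STATUS_TRUE_CROSS,
    LocusClass,
    OffspringLocusClass,
    QCRunResult,
)

__all__ = ["ColorClass", "SummaryRow", "Report", "build_report",
           "write_workbook", "write_summary_tsv", "SUMMARY_COLUMNS"]

SUMMARY_COLUMNS = [
    "#polymorphic", "%polymorphism", "#parentHet", "%parentHet",
    "#NonParentAllele", "%NonParentAllele", "#true", "#missing",
    "%missing", "%hybridity", "status",
]

NA = "NA"


class ColorClass(enum.Enum):
    """Semantic cell color; hex fills are a presentation detail."""

    GREEN_POLY = "GREEN_POLY"
    RED_MONO = "RED_MONO"
    BLUE_PARENT_HET = "BLUE_PARENT_HET"
    ORANGE_F1_HET = "ORANGE_F1_HET"
    PURPLE_NON_PARENTAL = "PURPLE_NON_PARENTAL"
    NONE = "NONE"


# Default fills (standard office palette); overridable in write_workbook.
DEFAULT_FILLS = {
    ColorClass.GREEN_POLY: "00B050",
    ColorClass.RED_MONO: "FF0000",
    ColorClass.BLUE_PARENT_HET: "00B0F0",
    ColorClass.ORANGE_F1_HET: "FFC000",
    ColorClass.PURPLE_NON_PARENTAL: "7030A0",
}

_PARENT_COLORS = {
    LocusClass.POLYMORPHIC: ColorClass.GREEN_POLY,
    LocusClass.MONOMORPHIC: ColorClass.RED_MONO,
    LocusClass.PARENT_HET: ColorClass.BLUE_PARENT_HET,
    LocusClass.MISSING: ColorClass.NONE,
}

_OFFSPRING_COLORS = {
    OffspringLocusClass.HET_TRUE: ColorClass.ORANGE_F1_HET,
    OffspringLocusClass.NON_PARENTAL: ColorClass.PURPLE_NON_PARENTAL,
    OffspringLocusClass.HOM_PARENTAL: ColorClass.NONE,
    OffspringLocusClass.MISSING: ColorClass.NONE,
}


def _pct(v: float | None) -> str:
    return NA if v is None else f"{v:.1f}"


@dataclass
class SummaryRow:
    """One report row: identifiers, genotype strings and the summary columns
    rendered as strings (counts as integers, percents to one decimal,
    undefined values as "NA")."""

    sample_id: str
    sample_name: str
    type_label: str
    values: dict[str, str]
    genotypes: dict[str, str]


@dataclass
class Report:
    marker_ids: list[str]
    rows: list[SummaryRow]
    # (row index into rows, marker_id) -> ColorClass, NONE entries omitted
    annotations: dict[tuple[int, str], ColorClass] = field(default_factory=dict)
    status_counts: dict[str, int] = field(default_factory=dict)
    marker_efficiency: dict[str, float | None] = field(default_factory=dict)


def build_report(result: QCRunResult) -> Report:
    """Build the summary rows and cell annotations from a QC run.

    One row per input sample, input order preserved.  Parent rows carry
    the pair polymorphism columns and their own heterozygosity and
    missing-call columns; offspring rows carry the full statistics with
    "%hybridity" rendered "NA" whenever the status is undetermined.
    """
    table = result.table
    report = Report(marker_ids=list(table.marker_ids), rows=[])
    for fr in result.families:
        profile = fr.profile
        pair_vals = {
            "#polymorphic": str(profile.pm),
            "%polymorphism": _pct(profile.polymorphism_pct),
        }
        for rec, pstats in ((fr.family.parent1, profile.parent1),
                            (fr.family.parent2, profile.parent2)):
            values = {c: NA for c in SUMMARY_COLUMNS}
            values.update(pair_vals)
            values["#parentHet"] = str(pstats.phet)
            values["%parentHet"] = _pct(pstats.het_pct)
            values["#missing"] = str(pstats.mc_self)
            values["%missing"] = _pct(100.0 * pstats.mc_self / profile.tm
                                      if profile.tm else None)
            idx = len(report.rows)
            report.rows.append(SummaryRow(
                sample_id=rec.sample_id, sample_name=rec.sample_name,
                type_label="Parent", values=values,
                genotypes={m: str(rec.calls[m]) for m in table.marker_ids}))
            for m, cls in profile.locus_classes.items():
                color = _PARENT_COLORS[cls]
                if color is not ColorClass.NONE:
                    report.annotations[(idx, m)] = color

        for rec, off in zip(fr.family.offspring, fr.offspring):
            # hybridity withheld when the status is undetermined
            undet = off.status not in (STATUS_TRUE_CROSS, STATUS_SELF)
            values = {c: NA for c in SUMMARY_COLUMNS}
            values.update(pair_vals)
            values["#NonParentAllele"] = str(off.lnpa)
            values["%NonParentAllele"] = _pct(off.non_parental)
            values["#true"] = str(off.lhet)
            values["#missing"] = str(off.mc_f1_all)
            values["%missing"] = _pct(off.missing_pct)
            values["%hybridity"] = NA if undet else _pct(off.hybridity)
            values["status"] = off.status
            idx = len(report.rows)
            report.rows.append(SummaryRow(
                sample_id=rec.sample_id, sample_name=rec.sample_name,
                type_label="F1", values=values,
                genotypes={m: str(rec.calls[m]) for m in table.marker_ids}))
            for m, cls in off.locus_classes.items():
                color = _OFFSPRING_COLORS[cls]
                if color is not ColorClass.NONE:
                    report.annotations[(idx, m)] = color

    report.status_counts = result.status_counts()
    report.marker_efficiency = {
        m: eff.efficiency_pct for m, eff in result.marker_efficiencies.items()
    }
    return report


# ---------------------------------------------------------------------------
# Writers

_HEADER = ["Sample ID", "Sample Name", *SUMMARY_COLUMNS, "Type"]


def _summary_lines(report: Report) -> list[str]:
    header = _HEADER + report.marker_ids
    lines = ["\t".join(header)]
    for row in report.rows:
        cells = [row.sample_id, row.sample_name,
                 *(row.values[c] for c in SUMMARY_COLUMNS), row.type_label,
                 *(row.genotypes[m] for m in report.marker_ids)]
        lines.append("\t".join(cells))
    return lines


def write_summary_tsv(report: Report, path: str | Path) -> Path:
    """Write the plain-text mirror of the results sheet (no colors)."""
    path = Path(path)
    path.write_text("\n".join(_summary_lines(report)) + "\n")
    return path


def _hybridity_pie_png(report: Report, path: Path) -> Path | None:
    counts = {s: c for s, c in report.status_counts.items() if c > 0}
    if not counts:
        return None
    fig, ax = plt.subplots(figsize=(6.5, 5))
    ax.pie(list(counts.values()),
           labels=list(counts.keys()),
           autopct="%1.0f%%", startangle=90, counterclock=False)
    ax.set_title("F1 hybridity status proportions")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _efficiency_bar_png(report: Report, path: Path) -> Path:
    markers = report.marker_ids
    vals = [report.marker_efficiency.get(m) or 0.0 for m in markers]
    fig, ax = plt.subplots(figsize=(max(6.0, 0.35 * len(markers)), 4.5))
    ax.bar(range(len(markers)), vals, color="#4472C4")
    ax.set_xticks(range(len(markers)))
    ax.set_xticklabels(markers, rotation=90, fontsize=7)
    ax.set_ylabel("Marker efficiency (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def write_workbook(report: Report, path: str | Path,
                   fills: dict[ColorClass, str] | None = None,
                   charts: bool = True) -> dict[str, Path]:
    """Write the XLSX workbook plus its TSV and PNG companions.

    Returns a mapping of artifact names ("workbook", "summary_tsv",
    "hybridity_png", "efficiency_png") to the paths written.
    """
    path = Path(path)
    fills = {**DEFAULT_FILLS, **(fills or {})}
    wb = Workbook()

    ws = wb.active
    ws.title = "results"
    header = _HEADER + report.marker_ids
    ws.append(header)
    for cell in ws[1]:
        cell.font = Font(bold=True)
    first_marker_col = len(_HEADER) + 1
    for r, row in enumerate(report.rows):
        ws.append([row.sample_id, row.sample_name,
                   *(row.values[c] for c in SUMMARY_COLUMNS), row.type_label,
                   *(row.genotypes[m] for m in report.marker_ids)])
        for j, m in enumerate(report.marker_ids):
            color = report.annotations.get((r, m))
            if color is not None and color is not ColorClass.NONE:
                ws.cell(row=r + 2, column=first_marker_col + j).fill = \
                    PatternFill(start_color=fills[color],
                                end_color=fills[color], fill_type="solid")

    total = sum(report.status_counts.values())
    ws_pie = wb.create_sheet("hybridity_chart")
    ws_pie.append(["status", "count", "percent"])
    for s in ALL_STATUSES:
        c = report.status_counts.get(s, 0)
        pct = f"{100.0 * c / total:.1f}" if total else NA
        ws_pie.append([s, c, pct])

    ws_eff = wb.create_sheet("marker_efficiency")
    ws_eff.append(["marker", "efficiency_pct"])
    for m in report.marker_ids:
        v = report.marker_efficiency.get(m)
        ws_eff.append([m, NA if v is None else f"{v:.1f}"])

    artifacts: dict[str, Path] = {}
    if charts:
        pie_png = _hybridity_pie_png(report, path.with_suffix(".hybridity.png"))
        eff_png = _efficiency_bar_png(report, path.with_suffix(".efficiency.png"))
        if pie_png is not None:
            ws_pie.add_image(XLImage(str(pie_png)), "E2")
            artifacts["hybridity_png"] = pie_png
        ws_eff.add_image(XLImage(str(eff_png)), "D2")
        artifacts["efficiency_png"] = eff_png

    wb.save(path)
    artifacts["workbook"] = path
    artifacts["summary_tsv"] = write_summary_tsv(
        report, path.with_suffix(".summary.tsv"))
    return artifacts
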