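"""Human-readable report tables for every pipeline stage.

Percentages are rendered to two decimals with half-up rounding, matching
the style of published array-QC summary tables.
"""

from __future__ import annotations

from collections.abc import Sequence
from decimal import ROUND_HALF_UP, Decimal

from .models import DesignReport, QtlResult


def round_half_up(x: float, digits: int = 2) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float | None, digits: int = 2) -> str:
    if x is None:
        return "NA"
    return f"{round_half_up(x, digits):.{digits}f}"


def render_attrition(report: DesignReport) -> str:
    """Per-filter attrition table (design workflow shape)."""
    lines = ["stage\tremoved\tremaining"]
    remaining = report.input_count
    lines.append(f"input\t0\t{remaining}")
    for stage, n in report.removed.items():
        remaining -= n
        lines.append(f"{stage}\t{n}\t{remaining}")
    lines.append(f"survivors\t0\t{report.survivor_count}")
    return "\n".join(lines) + "\n"


def render_category_table(summary: dict) -> str:
    """SNP quality-category counts and percentages of the array total."""
    lines = ["category\tcount\tpercent"]
    counts = summary["counts"]
    pct = summary["percentages"]
    for cat in sorted(counts, key=lambda c: -counts[c]):
        lines.append(f"{cat}\t{counts[cat]}\t{_fmt(pct[cat])}")
    lines.append(f"Total\t{summary['total']}\t100.00")
    return "\n".join(lines) + "\n"


def render_map_table(stats: dict) -> str:
    """Per-group marker counts, lengths and densities with totals/averages."""
    lines = ["group\tmarkers\tlength_cm\tmarkers_per_cm"]
    for name, count, length, dens in zip(
        stats["groups"], stats["counts"], stats["lengths_cm"], stats["densities"]
    ):
        lines.append(f"{name}\t{count}\t{_fmt(length)}\t{_fmt(dens)}")
    lines.append(
        f"Total\t{stats['total_markers']}\t{_fmt(stats['total_length_cm'])}"
        f"\t{_fmt(stats['overall_density'])}"
    )
    lines.append(
        f"Average\t{_fmt(stats['mean_markers_per_group'])}"
        f"\t{_fmt(stats['mean_length_cm'])}\t"
    )
    return "\n".join(lines) + "\n"


def render_qtl_table(results: Sequence[QtlResult]) -> str:
    lines = [
        "trait\tlocation\tyear\tgroup\tpeak_cm\tci_lo\tci_hi\tlod\tadditive"
        "\tpve\trobust\tstable\tconsistent"
    ]
    for q in results:
        lines.append(
            f"{q.trait}\t{q.location}\t{q.year}\t{q.group}\t{_fmt(q.peak_cm)}"
            f"\t{_fmt(q.interval_cm[0])}\t{_fmt(q.interval_cm[1])}"
            f"\t{_fmt(q.lod)}\t{_fmt(q.additive, 3)}\t{_fmt(q.pve)}"
            f"\t{int(q.robust)}\t{int(q.stable)}\t{int(q.consistent)}"
        )
    return "\n".join(lines) + "\n"
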