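"""Length-by-category summaries and printed-precision formatting.

Percent denominators always include the ``unknown`` and
``already_restored`` lengths, so the seven category shares of a network
sum to 100 up to rounding. Printed values round half away from zero at
one decimal place, the convention of the report tables this module
emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import round_half_away
from .scoring import CATEGORIES, ScoredSegment


@dataclass
class CategoryReport:
    """Per-category length (km) and share (%) of a (sub-)network."""

    label: str  # e.g. "all" or a state name
    total_length_km: float
    rows: pd.DataFrame = field(repr=False)  # index: category

    def length_km(self, category: str) -> float:
        return float(self.rows.loc[category, "length_km"])

    def pct(self, category: str) -> float:
        return float(self.rows.loc[category, "pct"])


def report_from_lengths(length_km_by_category: dict[str, float],
                        label: str = "all") -> CategoryReport:
    """Build a report directly from per-category lengths in km.

    Useful for re-deriving the printed percentages of an existing summary
    table: percentages are shares of the summed lengths over all
    categories, including unknown and already_restored.
    """
    unknown = set(length_km_by_category) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    total = sum(length_km_by_category.values())
    if total <= 0:
        raise ValueError("total length must be positive")
    rows = pd.DataFrame(
        {"length_km": [length_km_by_category.get(c, 0.0) for c in CATEGORIES],
         "pct": [100.0 * length_km_by_category.get(c, 0.0) / total
                 for c in CATEGORIES]},
        index=list(CATEGORIES))
    rows.index.name = "category"
    return CategoryReport(label=label, total_length_km=total, rows=rows)


def length_by_category(scored: list[ScoredSegment],
                       per_state: bool = False):
    """Sum segment lengths per category; optionally one report per state.

    Returns a single :class:`CategoryReport`, or a dict state -> report
    with percentages relative to each state's own total length.
    """
    if not scored:
        raise ValueError("no scored segments")
    if per_state:
        states = sorted({s.state for s in scored})
        return {st: _report([s for s in scored if s.state == st], st)
                for st in states}
    return _report(scored, "all")


def _report(scored: list[ScoredSegment], label: str) -> CategoryReport:
    lengths = {c: 0.0 for c in CATEGORIES}
    for s in scored:
        lengths[s.category] += s.length_m / 1000.0
    return report_from_lengths(lengths, label=label)


def format_report(report: CategoryReport, style: str = "csv") -> str:
    """Render a report as CSV or Markdown at 1-dp printed precision.

    Deterministic: identical reports give byte-identical text.
    """
    rows = [(c, round_half_away(report.length_km(c), 1),
             round_half_away(report.pct(c), 1)) for c in CATEGORIES]
    total = round_half_away(report.total_length_km, 1)
    if style == "csv":
        lines = ["category,length_km,pct"]
        lines += [f"{c},{km:.1f},{p:.1f}" for c, km, p in rows]
        lines.append(f"total,{total:.1f},100.0")
        return "\n".join(lines) + "\n"
    if style == "markdown":
        lines = ["| category | length_km | pct |", "|---|---|---|"]
        lines += [f"| {c} | {km:.1f} | {p:.1f} |" for c, km, p in rows]
        lines.append(f"| total | {total:.1f} | 100.0 |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown style {style!r}")


def reports_frame(reports) -> pd.DataFrame:
    """Flatten one report or a per-state dict into a tidy DataFrame."""
    if isinstance(reports, CategoryReport):
        reports = {reports.label: reports}
    rows = []
    for label, rep in reports.items():
        for c in CATEGORIES:
            rows.append({"label": label, "category": c,
                         "length_km": rep.length_km(c), "pct": rep.pct(c)})
    return pd.DataFrame(rows)
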