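"""Tabular rendering of reduction curves and replicate aggregation.

The reduction table mirrors the layout of per-family extended analyses:
one row per member-addition step, column groups Coding and Non-Coding each
split Total/Homozygous/Heterozygous, plus the percent drop in the grand
total from the previous step.  Display counts are rounded half-up to
integers; JSON keeps exact values.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .segregation import ReductionCurve, reduction_percentages

_COLUMNS = [
    "step",
    "member_added",
    "coding_total",
    "coding_hom",
    "coding_het",
    "noncoding_total",
    "noncoding_hom",
    "noncoding_het",
    "percent_drop",
]


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def curve_rows(curve: ReductionCurve) -> list[dict]:
    drops = [None] + (
        reduction_percentages(curve) if len(curve.steps) >= 2 else []
    )
    rows = []
    for step, drop in zip(curve.steps, drops):
        coding = step.candidates.coding
        noncoding = step.candidates.noncoding
        rows.append(
            {
                "step": step.label,
                "member_added": step.member_added,
                "coding_total": coding.total,
                "coding_hom": coding.hom,
                "coding_het": coding.het,
                "noncoding_total": noncoding.total,
                "noncoding_hom": noncoding.hom,
                "noncoding_het": noncoding.het,
                "percent_drop": drop,
            }
        )
    return rows


def render_reduction(curve: ReductionCurve, format: str = "tsv") -> str:
    """Render a reduction curve as a TSV table or a JSON document."""
    rows = curve_rows(curve)
    if format == "json":
        return json.dumps({"steps": rows}, indent=2) + "\n"
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    lines = ["\t".join(_COLUMNS)]
    for row in rows:
        cells = []
        for col in _COLUMNS:
            v = row[col]
            if v is None:
                cells.append(".")
            elif isinstance(v, float):
                cells.append(f"{v:.2f}")
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


_STRATA = [
    "coding_total", "coding_hom", "coding_het",
    "noncoding_total", "noncoding_hom", "noncoding_het",
]


@dataclass
class ReplicateSummary:
    labels: list[str]
    #: per step: stratum -> exact mean count across replicates
    mean_counts: list[dict[str, float]]
    #: per step: stratum -> half-up rounded display count
    display_counts: list[dict[str, int]]
    #: per post-first step: {median,min,max} of the percent drop across
    #: replicates (drop computed within each replicate first)
    drop_stats: list[dict[str, float]]
    n_replicates: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_replicates": self.n_replicates,
                "labels": self.labels,
                "mean_counts": self.mean_counts,
                "display_counts": self.display_counts,
                "drop_stats": self.drop_stats,
            },
            indent=2,
        ) + "\n"


def aggregate_replicates(curves: Sequence[ReductionCurve]) -> ReplicateSummary:
    """Average step counts across replicate curves of identical structure."""
    if not curves:
        raise ValueError("no curves to aggregate")
    labels = curves[0].labels()
    for c in curves[1:]:
        if c.labels() != labels:
            raise ValueError(
                "replicate curves have mismatched step structure: "
                f"{labels} vs {c.labels()}"
            )
    all_rows = [curve_rows(c) for c in curves]
    mean_counts, display_counts = [], []
    for k in range(len(labels)):
        means = {
            s: statistics.fmean(rows[k][s] for rows in all_rows)
            for s in _STRATA
        }
        mean_counts.append(means)
        display_counts.append({s: _round_half_up(v) for s, v in means.items()})
    per_rep_drops = [reduction_percentages(c) for c in curves] if len(labels) >= 2 else []
    drop_stats = []
    for k in range(len(labels) - 1):
        vals = [d[k] for d in per_rep_drops]
        drop_stats.append(
            {
                "median": statistics.median(vals),
                "min": min(vals),
                "max": max(vals),
            }
        )
    return ReplicateSummary(
        labels=list(labels),
        mean_counts=mean_counts,
        display_counts=display_counts,
        drop_stats=drop_stats,
        n_replicates=len(curves),
    )
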