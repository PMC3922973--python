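"""Detection-vs-reference matching and census assessment metrics.

Automatic detections are matched one-to-one to reference annotations by
centroid distance, tallied by the reference object's manual class, and
summarized in the ten-statistic assessment layout used for the original
Golfo Nuevo WorldView2 right-whale census: total signals, matches per
class, total found, % found, % of probable, total/% missed, false
positives, % false positives and % good.

Denominator conventions (they reproduce the published assessment table
cell-for-cell): percentages of matches are taken over the manual grand
total; "% of probable" over the manual probable total; "% false
positives" over the method's own total signal count; "% good" is
100 minus % false positives. Percentages are rounded half-up to one
decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .scene import CLASS_LABELS, ReferenceAnnotation

__all__ = [
    "ConfusionCounts",
    "MetricsTable",
    "MatchResult",
    "match_detections",
    "confusion_counts",
    "compute_metrics",
    "table1_report",
    "format_report",
    "GOLFO_NUEVO_REFERENCE_TOTALS",
    "GOLFO_NUEVO_METHOD_COUNTS",
]


#: Manual digitization class totals from the original Golfo Nuevo
#: WorldView2 right-whale census (113 km^2 scene): 55 probable whales,
#: 23 possible whales, 13 coastal-band-only objects (91 signals in all).
GOLFO_NUEVO_REFERENCE_TOTALS: dict[str, int] = {
    "probable": 55,
    "possible": 23,
    "band5_only": 13,
}

#: Published per-method count rows from the same census assessment:
#: total signals, matches by manual class, and false positives.
GOLFO_NUEVO_METHOD_COUNTS: dict[str, dict[str, int]] = {
    "isodata": {"total": 158, "probable": 44, "possible": 16, "band5": 1, "fp": 97},
    "kmeans": {"total": 102, "probable": 42, "possible": 11, "band5": 0, "fp": 49},
    "threshold_pan": {"total": 64, "probable": 43, "possible": 14, "band5": 0, "fp": 7},
    "threshold_band5": {"total": 101, "probable": 49, "possible": 15, "band5": 13, "fp": 24},
}


@dataclass
class ConfusionCounts:
    """Raw assessment counts for one detection method."""

    method_total_signals: int
    probable_matches: int
    possible_matches: int
    band5_matches: int
    false_positives: int
    reference_totals: dict[str, int]

    def __post_init__(self) -> None:
        matched = self.probable_matches + self.possible_matches + self.band5_matches
        if self.method_total_signals != matched + self.false_positives:
            raise ValueError(
                "inconsistent counts: total signals "
                f"{self.method_total_signals} != matches {matched} + FP {self.false_positives}"
            )
        for cls, n in (
            ("probable", self.probable_matches),
            ("possible", self.possible_matches),
            ("band5_only", self.band5_matches),
        ):
            if n > self.reference_totals.get(cls, 0):
                raise ValueError(f"{cls} matches exceed reference total")

    @property
    def total_found(self) -> int:
        return self.probable_matches + self.possible_matches + self.band5_matches

    @property
    def reference_grand_total(self) -> int:
        return sum(self.reference_totals.values())

    @classmethod
    def from_published(cls, method: str) -> "ConfusionCounts":
        """Counts for one method of the published census assessment."""
        c = GOLFO_NUEVO_METHOD_COUNTS[method]
        return cls(
            method_total_signals=c["total"],
            probable_matches=c["probable"],
            possible_matches=c["possible"],
            band5_matches=c["band5"],
            false_positives=c["fp"],
            reference_totals=dict(GOLFO_NUEVO_REFERENCE_TOTALS),
        )


@dataclass
class MetricsTable:
    """The derived assessment statistics for one method."""

    total_found: int
    total_missed: int
    pct_found: float
    pct_of_probable: float
    pct_missed: float
    pct_false_positives: float
    pct_good: float


def _pct(numerator: int, denominator: int) -> float:
    """Exact percentage rounded half-up to one decimal."""
    q = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_metrics(counts: ConfusionCounts) -> MetricsTable:
    """Derive the percentage rows from the count rows.

    Match percentages use the reference grand total; "% of probable" the
    reference probable total; "% false positives" the method's own total
    signals; "% good" = 100 - "% false positives".
    """
    grand = counts.reference_grand_total
    if grand <= 0:
        raise ValueError("empty reference")
    if counts.method_total_signals <= 0:
        raise ValueError("empty method output")
    found = counts.total_found
    missed = grand - found
    pct_fp = _pct(counts.false_positives, counts.method_total_signals)
    return MetricsTable(
        total_found=found,
        total_missed=missed,
        pct_found=_pct(found, grand),
        pct_of_probable=_pct(counts.probable_matches, counts.reference_totals["probable"]),
        pct_missed=_pct(missed, grand),
        pct_false_positives=pct_fp,
        pct_good=round(100.0 - pct_fp, 1),
    )


# -- matching ---------------------------------------------------------------


@dataclass
class MatchResult:
    """One-to-one pairing between detections and reference annotations."""

    pairs: list[tuple[int, int, float]]  # (detection idx, reference idx, distance m)
    unmatched_detections: list[int]
    unmatched_reference: list[int]


def match_detections(
    detections: Sequence,
    reference: Sequence[ReferenceAnnotation],
    match_radius_m: float = 10.0,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching by centroid distance.

    Candidate pairs within ``match_radius_m`` are taken in ascending
    distance (ties broken by detection then reference index, so the
    pairing is order-stable); each detection and each reference object is
    used at most once.
    """
    cands: list[tuple[float, int, int]] = []
    for i, det in enumerate(detections):
        dx, dy = det.centroid_xy_m
        for j, ref in enumerate(reference):
            d = math.hypot(dx - ref.centroid_xy_m[0], dy - ref.centroid_xy_m[1])
            if d <= match_radius_m:
                cands.append((d, i, j))
    cands.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in cands:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j, d))
    return MatchResult(
        pairs=pairs,
        unmatched_detections=[i for i in range(len(detections)) if i not in used_d],
        unmatched_reference=[j for j in range(len(reference)) if j not in used_r],
    )


def confusion_counts(
    match: MatchResult, reference: Sequence[ReferenceAnnotation]
) -> ConfusionCounts:
    """Tally a pairing by the *reference* object's manual class.

    A matched detection inherits the reference class for counting;
    unmatched detections are false positives.
    """
    by_class = {cls: 0 for cls in CLASS_LABELS}
    for _, j, _ in match.pairs:
        by_class[reference[j].class_label] += 1
    ref_totals = {cls: 0 for cls in CLASS_LABELS}
    for r in reference:
        ref_totals[r.class_label] += 1
    n_det = len(match.pairs) + len(match.unmatched_detections)
    return ConfusionCounts(
        method_total_signals=n_det,
        probable_matches=by_class["probable"],
        possible_matches=by_class["possible"],
        band5_matches=by_class["band5_only"],
        false_positives=len(match.unmatched_detections),
        reference_totals=ref_totals,
    )


# -- reporting --------------------------------------------------------------

_ROW_ORDER = [
    "total signals",
    "probable matches",
    "possible matches",
    "band 5 matches",
    "total found",
    "% found",
    "% of probable",
    "total missed",
    "% missed",
    "false positives",
    "% false positives",
    "% good",
]


def table1_report(counts_by_method: dict[str, ConfusionCounts]) -> pd.DataFrame:
    """Render the 12-row assessment comparison table.

    Columns: a leading reference column (manual class totals on the match
    rows) followed by one column per method. Percentage rows are derived
    with :func:`compute_metrics`.
    """
    if not counts_by_method:
        raise ValueError("empty reference")
    first = next(iter(counts_by_method.values()))
    ref = first.reference_totals
    data: dict[str, list] = {
        "manual": [
            sum(ref.values()),
            ref.get("probable", 0),
            ref.get("possible", 0),
            ref.get("band5_only", 0),
            "", "", "", "", "", "", "", "",
        ]
    }
    for method, counts in counts_by_method.items():
        m = compute_metrics(counts)
        data[method] = [
            counts.method_total_signals,
            counts.probable_matches,
            counts.possible_matches,
            counts.band5_matches,
            m.total_found,
            m.pct_found,
            m.pct_of_probable,
            m.total_missed,
            m.pct_missed,
            counts.false_positives,
            m.pct_false_positives,
            m.pct_good,
        ]
    return pd.DataFrame(data, index=_ROW_ORDER)


def format_report(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the comparison table."""
    return df.to_string()
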