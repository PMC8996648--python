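"""Relative-recall evaluation of a search filter.

The relative-recall design replays a systematic review's baseline
search, applies the candidate filter on top of it (Boolean AND), and
scores retrieval against the review's included studies (the reference
set).  The 2x2 of the comparison is::

                     reference set    non-reference set
    retrieved            A (TP)            B (FP)
    not retrieved        C (FN)            D (TN)

with five derived statistics:

* sensitivity  = 100 * A / (A + C)
* specificity  = 100 * D / (B + D)
* precision    = 100 * A / (A + B)        (PPV)
* NNR          = 100 / precision          (records screened per relevant hit)
* time saved   = 100 * (C + D) / (A+B+C+D)

Published evaluations usually print only (included n, retrieved N,
sensitivity, specificity); :func:`back_derive_counts` reconstructs the
integer cells from such a row so the remaining statistics can be
recomputed and cross-checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .corpus import MeshTree, Record, ReferenceSet
from .ovidql import Strategy, apply_strategy

__all__ = [
    "ConfusionTable",
    "PerformanceMetrics",
    "build_confusion",
    "compute_metrics",
    "back_derive_counts",
    "evaluate_review",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 always rounds up in magnitude)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionTable:
    """The A/B/C/D cells of one filter-vs-reference-set evaluation."""

    a: int  # true positives: reference-set records retrieved by the filter
    b: int  # false positives
    c: int  # false negatives
    d: int  # true negatives

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def reference_size(self) -> int:
        return self.a + self.c

    @property
    def retrieved(self) -> int:
        return self.a + self.b


@dataclass(frozen=True)
class PerformanceMetrics:
    """The five retrieval statistics, unrounded.

    ``precision`` and ``nnr`` are NaN with ``precision_defined=False``
    when the filter retrieves nothing (A + B = 0).
    """

    sensitivity: float
    specificity: float
    precision: float
    nnr: float
    time_saved: float
    precision_defined: bool = True

    def rounded(
        self,
        sens_decimals: int = 0,
        spec_decimals: int = 0,
        precision_decimals: int = 0,
        time_decimals: int = 0,
    ) -> dict[str, float]:
        """Display rounding: NNR to nearest integer from unrounded precision."""
        return {
            "sensitivity": round_half_away(self.sensitivity, sens_decimals),
            "specificity": round_half_away(self.specificity, spec_decimals),
            "precision": round_half_away(self.precision, precision_decimals)
            if self.precision_defined
            else float("nan"),
            "nnr": round_half_away(self.nnr)
            if self.precision_defined
            else float("nan"),
            "time_saved": round_half_away(self.time_saved, time_decimals),
        }


def build_confusion(
    baseline_ids: Iterable[str],
    filter_ids: Iterable[str],
    reference: ReferenceSet,
) -> ConfusionTable:
    """Cross-classify a baseline result set by filter retrieval and relevance.

    The relative-recall premise requires the reference set (and the
    filtered set) to lie inside the baseline result; violations raise
    with the offending ids listed.
    """
    baseline = frozenset(baseline_ids)
    filtered = frozenset(filter_ids)
    stray_filter = filtered - baseline
    if stray_filter:
        raise ValueError(
            "filter ids outside the baseline result: "
            + ", ".join(sorted(stray_filter))
        )
    stray_ref = reference.included_ids - baseline
    if stray_ref:
        raise ValueError(
            f"reference set {reference.review_label!r} ids missing from the "
            "baseline result (relative recall premise fails): "
            + ", ".join(sorted(stray_ref))
        )
    ref = reference.included_ids
    a = len(filtered & ref)
    b = len(filtered - ref)
    c = len(ref - filtered)
    d = len(baseline - (filtered | ref))
    return ConfusionTable(a=a, b=b, c=c, d=d)


def compute_metrics(ct: ConfusionTable) -> PerformanceMetrics:
    """Evaluate the five statistics exactly from the 2x2 cells."""
    if ct.a + ct.c == 0:
        raise ValueError("empty reference set (A + C = 0)")
    if ct.b + ct.d == 0:
        raise ValueError("no non-relevant records in baseline (B + D = 0)")
    sensitivity = 100.0 * ct.a / (ct.a + ct.c)
    specificity = 100.0 * ct.d / (ct.b + ct.d)
    if ct.a + ct.b == 0:
        precision, nnr, defined = float("nan"), float("nan"), False
    else:
        precision = 100.0 * ct.a / (ct.a + ct.b)
        nnr = 100.0 / precision if precision > 0 else float("inf")
        defined = True
    time_saved = 100.0 * (ct.c + ct.d) / ct.total
    return PerformanceMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        nnr=nnr,
        time_saved=time_saved,
        precision_defined=defined,
    )


def back_derive_counts(
    included_n: int,
    retrieved_total: int,
    sensitivity_pct: float,
    specificity_pct: float,
) -> ConfusionTable:
    """Reconstruct integer 2x2 cells from a published summary row.

    ``A = round(sens * n / 100)``, ``C = n - A``,
    ``D = round(spec * (N - n) / 100)``, ``B = N - n - D``, with
    nearest-integer rounding half away from zero.
    """
    if not 0 < included_n <= retrieved_total:
        raise ValueError("need 0 < included_n <= retrieved_total")
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise ValueError("percentages must be in [0, 100]")
    a = int(round_half_away(sensitivity_pct * included_n / 100.0))
    c = included_n - a
    non_ref = retrieved_total - included_n
    d = int(round_half_away(specificity_pct * non_ref / 100.0))
    b = non_ref - d
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"derived cell negative: (a, b, c, d) = ({a}, {b}, {c}, {d})"
        )
    return ConfusionTable(a=a, b=b, c=c, d=d)


def evaluate_review(
    baseline_records: Iterable[Record],
    strategy: Strategy,
    mesh_tree: MeshTree,
    reference: ReferenceSet,
) -> tuple[ConfusionTable, PerformanceMetrics]:
    """Apply a filter strategy to a review's baseline result and score it."""
    baseline_records = list(baseline_records)
    filtered = apply_strategy(strategy, baseline_records, mesh_tree)
    ct = build_confusion(
        (rec.id for rec in baseline_records), filtered, reference
    )
    return ct, compute_metrics(ct)
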