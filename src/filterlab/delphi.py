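"""RAND/UCLA appropriateness aggregation of expert-panel term ratings.

Candidate filter terms are rated by a panel on a 1-9 scale (1 = least
appropriate for inclusion, 9 = most appropriate) over one or more
rounds.  The classic RAND rules classify each term by the median of its
final-round ratings — 7-9 appropriate, 4-6 uncertain, 1-3 inappropriate
— and flag *disagreement* when at least a third of the panel rates in
the bottom tertile (1-3) while at least a third rates in the top tertile
(7-9).  A term enters the filter only if it is appropriate without
disagreement.  The extreme fraction defaults to 1/3 and is configurable,
the standard generalization for panels larger than nine.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

__all__ = [
    "RatingTable",
    "TermVerdict",
    "classify_term",
    "select_filter_terms",
    "read_ratings",
]

CATEGORIES = ("appropriate", "uncertain", "inappropriate")


@dataclass(frozen=True)
class TermVerdict:
    term: str
    median: float
    category: str
    disagreement: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "appropriate" and (self.median < 7 or self.disagreement):
            raise ValueError(
                f"{self.term!r}: 'appropriate' requires median >= 7 and no disagreement"
            )


@dataclass
class RatingTable:
    """Panel ratings: (term, panelist, round) -> integer in 1..9."""

    terms: list[str]
    panelists: list[str]
    rounds: int
    ratings: dict[tuple[str, str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        for (term, panelist, rnd), value in self.ratings.items():
            if not 1 <= value <= 9:
                raise ValueError(
                    f"rating {value} for ({term!r}, {panelist!r}, round {rnd}) "
                    "outside 1..9"
                )
            if not 1 <= rnd <= self.rounds:
                raise ValueError(f"round {rnd} outside 1..{self.rounds}")

    def final_round_ratings(self, term: str) -> list[int]:
        out = []
        for panelist in self.panelists:
            key = (term, panelist, self.rounds)
            if key not in self.ratings:
                raise ValueError(
                    f"final round incomplete: no rating for ({term!r}, {panelist!r})"
                )
            out.append(self.ratings[key])
        return out


def classify_term(
    ratings_for_term: Sequence[int], extreme_fraction: float = 1 / 3
) -> TermVerdict:
    """Apply the RAND median-tertile and disagreement rules to one term.

    Requires at least three ratings, each in 1..9.  Disagreement — at
    least ``ceil(extreme_fraction * n)`` ratings in 1-3 AND as many in
    7-9 — overrides the median category to uncertain.
    """
    ratings = list(ratings_for_term)
    if len(ratings) < 3:
        raise ValueError("at least 3 ratings are required")
    for r in ratings:
        if not isinstance(r, int) or not 1 <= r <= 9:
            raise ValueError(f"rating {r!r} outside 1..9")
    median = float(statistics.median(ratings))
    threshold = math.ceil(extreme_fraction * len(ratings))
    low = sum(r <= 3 for r in ratings)
    high = sum(r >= 7 for r in ratings)
    disagreement = low >= threshold and high >= threshold
    if disagreement:
        category = "uncertain"
    elif median >= 7:
        category = "appropriate"
    elif median >= 4:
        category = "uncertain"
    else:
        category = "inappropriate"
    return TermVerdict(
        term="", median=median, category=category, disagreement=disagreement
    )


def classify_table(
    table: RatingTable, extreme_fraction: float = 1 / 3
) -> list[TermVerdict]:
    """Final-round verdict for every term, in table order."""
    out = []
    for term in table.terms:
        verdict = classify_term(
            table.final_round_ratings(term), extreme_fraction=extreme_fraction
        )
        out.append(
            TermVerdict(
                term=term,
                median=verdict.median,
                category=verdict.category,
                disagreement=verdict.disagreement,
            )
        )
    return out


def select_filter_terms(
    table: RatingTable, extreme_fraction: float = 1 / 3
) -> list[str]:
    """Terms whose final-round verdict is appropriate without disagreement.

    Earlier rounds are retained in the table for audit but do not affect
    selection.  Returned in input order.
    """
    return [
        v.term
        for v in classify_table(table, extreme_fraction=extreme_fraction)
        if v.category == "appropriate"
    ]


def read_ratings(source) -> RatingTable:
    """Read delimited ratings: columns term, panelist, round, rating.

    Accepts a header row (detected by a non-integer rating column).
    Delimiter is sniffed from {tab, comma, semicolon}.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_ratings(fh)
    text = source.read()
    delimiter = "\t"
    for cand in ("\t", ",", ";"):
        if cand in text.splitlines()[0]:
            delimiter = cand
            break
    ratings: dict[tuple[str, str, int], int] = {}
    terms: list[str] = []
    panelists: list[str] = []
    max_round = 0
    for i, row in enumerate(csv.reader(text.splitlines(), delimiter=delimiter)):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) != 4:
            raise ValueError(f"ratings line {i + 1}: expected 4 columns, got {len(row)}")
        term, panelist, rnd_s, rating_s = (cell.strip() for cell in row)
        if i == 0 and not rating_s.lstrip("-").isdigit():
            continue  # header
        rnd, rating = int(rnd_s), int(rating_s)
        key = (term, panelist, rnd)
        if key in ratings:
            raise ValueError(f"duplicate rating for {key}")
        ratings[key] = rating
        if term not in terms:
            terms.append(term)
        if panelist not in panelists:
            panelists.append(panelist)
        max_round = max(max_round, rnd)
    if not ratings:
        raise ValueError("no ratings found")
    return RatingTable(
        terms=terms, panelists=panelists, rounds=max_round, ratings=ratings
    )


def verdicts_to_text(verdicts: Sequence[TermVerdict], sep: str = "\t") -> str:
    lines = [sep.join(["term", "median", "category", "disagreement"])]
    for v in verdicts:
        lines.append(
            sep.join([v.term, f"{v.median:g}", v.category, str(int(v.disagreement))])
        )
    return "\n".join(lines) + "\n"
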