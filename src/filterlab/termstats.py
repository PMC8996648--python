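"""Word-frequency and chi-square discrimination analysis of candidate terms.

Given a positive record set (studies included in the reviews that define
the reference standard) and a negative set (retrieved but not included),
these functions count unigram/bigram frequencies over titles and
abstracts and score each term's discrimination with a Pearson chi-square
on the 2x2 table of document presence/absence by set.  Document
frequency — not occurrence count — feeds the chi-square, because the
unit of the comparison is the study, not the token.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import Record
from .ovidql import tokenize

__all__ = [
    "TermContingency",
    "DEFAULT_STOPWORDS",
    "word_frequency",
    "term_chi_square",
    "rank_candidate_terms",
]

#: Small English stopword list applied to unigrams and bigram boundaries.
#: Configurable: every public function takes a ``stopwords`` argument.
DEFAULT_STOPWORDS = frozenset(
    """a about above after again against all also am an and any are as at be
    because been before being below between both but by can could did do does
    doing down during each few for from further had has have having he her
    here hers him his how i if in into is it its itself just me more most my
    no nor not of off on once only or other our ours out over own s same she
    should so some such t than that the their theirs them then there these
    they this those through to too under until up very was we were what when
    where which while who whom why will with you your yours""".split()
)


@dataclass(frozen=True)
class TermContingency:
    """2x2 document-frequency table and chi-square for one term."""

    term: str
    pos_with: int
    pos_total: int
    neg_with: int
    neg_total: int
    chi2: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.pos_with <= self.pos_total:
            raise ValueError(f"{self.term!r}: pos_with outside [0, pos_total]")
        if not 0 <= self.neg_with <= self.neg_total:
            raise ValueError(f"{self.term!r}: neg_with outside [0, neg_total]")


def _record_terms(record: Record, ngram_max: int, stopwords: frozenset[str]):
    """Yield (term, count) pairs for one record's title+abstract."""
    counts: dict[str, int] = {}
    for fld in (record.title, record.abstract):
        tokens = tokenize(fld)
        for i, tok in enumerate(tokens):
            if tok not in stopwords:
                counts[tok] = counts.get(tok, 0) + 1
                if (
                    ngram_max >= 2
                    and i + 1 < len(tokens)
                    and tokens[i + 1] not in stopwords
                ):
                    bigram = f"{tok} {tokens[i + 1]}"
                    counts[bigram] = counts.get(bigram, 0) + 1
    return counts


def word_frequency(
    records: Sequence[Record],
    ngram_max: int = 1,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> dict[str, tuple[int, int]]:
    """Map term -> (document count, occurrence count) over titles+abstracts.

    ``ngram_max`` is 1 (unigrams) or 2 (unigrams + bigrams of adjacent
    non-stopword tokens).  Raises on an empty corpus.
    """
    if ngram_max not in (1, 2):
        raise ValueError("ngram_max must be 1 or 2")
    records = list(records)
    if not records:
        raise ValueError("word_frequency: empty corpus")
    freq: dict[str, tuple[int, int]] = {}
    for rec in records:
        for term, count in _record_terms(rec, ngram_max, stopwords).items():
            doc, occ = freq.get(term, (0, 0))
            freq[term] = (doc + 1, occ + count)
    return freq


def _contains(record: Record, term: str, stopwords: frozenset[str]) -> bool:
    ngram_max = 2 if " " in term else 1
    return term in _record_terms(record, ngram_max, stopwords)


def term_chi_square(
    term: str,
    pos_records: Sequence[Record],
    neg_records: Sequence[Record],
    yates: bool = False,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> TermContingency:
    """Pearson chi-square (1 df) on document presence/absence by set.

    A term absent from (or present in) every record of both sets has a
    degenerate margin; by convention chi2 = 0, p = 1.
    """
    pos_records, neg_records = list(pos_records), list(neg_records)
    if not pos_records or not neg_records:
        raise ValueError("both record sets must be non-empty")
    pw = sum(_contains(r, term, stopwords) for r in pos_records)
    nw = sum(_contains(r, term, stopwords) for r in neg_records)
    return _chi_square_from_counts(
        term, pw, len(pos_records), nw, len(neg_records), yates
    )


def _chi_square_from_counts(
    term: str, pos_with: int, pos_total: int, neg_with: int, neg_total: int,
    yates: bool,
) -> TermContingency:
    table = np.array(
        [
            [pos_with, pos_total - pos_with],
            [neg_with, neg_total - neg_with],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=yates)
        chi2, p = float(res.statistic), float(res.pvalue)
    return TermContingency(
        term=term,
        pos_with=pos_with,
        pos_total=pos_total,
        neg_with=neg_with,
        neg_total=neg_total,
        chi2=chi2,
        p_value=p,
    )


def rank_candidate_terms(
    pos_records: Sequence[Record],
    neg_records: Sequence[Record],
    top_n: int,
    ngram_max: int = 2,
    yates: bool = False,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> list[TermContingency]:
    """Rank candidate filter terms by positive-set document frequency.

    Ties break by chi-square descending, then lexicographically.  The
    returned list is truncated to ``top_n`` items.  Screening out
    clinical content words (keeping only methodological terms) is a
    judgement step left to the expert panel.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pos_records, neg_records = list(pos_records), list(neg_records)
    pos_freq = word_frequency(pos_records, ngram_max=ngram_max, stopwords=stopwords)
    neg_doc: dict[str, int] = {}
    for rec in neg_records:
        for term in _record_terms(rec, ngram_max, stopwords):
            neg_doc[term] = neg_doc.get(term, 0) + 1
    scored = [
        _chi_square_from_counts(
            term, doc, len(pos_records), neg_doc.get(term, 0), len(neg_records), yates
        )
        for term, (doc, _) in pos_freq.items()
    ]
    scored.sort(key=lambda tc: (-tc.pos_with, -tc.chi2, tc.term))
    return scored[:top_n]


def contingency_table_text(
    rows: Iterable[TermContingency], sep: str = "\t"
) -> str:
    """Delimited-text rendering of ranked terms (header + one row per term)."""
    header = sep.join(
        ["term", "pos_with", "pos_total", "neg_with", "neg_total", "chi2", "p"]
    )
    lines = [header]
    for tc in rows:
        lines.append(
            sep.join(
                [
                    tc.term,
                    str(tc.pos_with),
                    str(tc.pos_total),
                    str(tc.neg_with),
                    str(tc.neg_total),
                    f"{tc.chi2:.6g}",
                    f"{tc.p_value:.6g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
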