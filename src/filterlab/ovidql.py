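"""Parse and evaluate a subset of Ovid MEDLINE search-strategy syntax.

A strategy is a numbered list of lines.  Each line is one of:

* ``exp Heading/``      — exploded MeSH heading (heading + tree descendants)
* ``Heading/``          — non-exploded MeSH heading
* ``term.tw`` / ``"multi word term*".tw``
                        — textword search over title and abstract; a
                          trailing ``*`` is truncation (token-prefix
                          match on the final word)
* ``or/1-13``, ``and/2-4``, ``1 and 2``, ``1 or 2 or 3``, ``3 not 1``
                        — Boolean combinations of earlier lines

Textword matching is deliberately simple and transparent: text is
lowercased and split on non-alphanumeric characters; a multi-word term
must occur as an adjacent token sequence; truncation is the only
wildcard and applies to the final token.  There is no stemming and no
hidden normalization.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import MeshTree, Record

logger = logging.getLogger(__name__)

__all__ = [
    "MeshExp",
    "MeshNoExp",
    "TextWord",
    "LineCombo",
    "Strategy",
    "StrategyResult",
    "parse_strategy",
    "evaluate_line",
    "apply_strategy",
    "builtin_strategies",
    "tokenize",
]

TEXT_FIELDS = ("title", "abstract")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters."""
    return [t for t in re.split(r"[^0-9a-z]+", text.lower()) if t]


@dataclass(frozen=True)
class MeshExp:
    """Exploded MeSH heading: matches the heading or any tree descendant."""

    heading: str

    def __post_init__(self) -> None:
        if not self.heading:
            raise ValueError("MeSH heading must be non-empty")


@dataclass(frozen=True)
class MeshNoExp:
    """Non-exploded MeSH heading: exact (case-insensitive) heading match."""

    heading: str

    def __post_init__(self) -> None:
        if not self.heading:
            raise ValueError("MeSH heading must be non-empty")


@dataclass(frozen=True)
class TextWord:
    """Textword search over the record's title and/or abstract."""

    term: str
    truncated: bool = False
    fields: tuple[str, ...] = TEXT_FIELDS

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("textword term must be non-empty")
        if "*" in self.term:
            raise ValueError(
                f"term {self.term!r}: wildcards are only allowed as trailing "
                "truncation (set truncated=True)"
            )
        bad = set(self.fields) - set(TEXT_FIELDS)
        if bad:
            raise ValueError(f"unknown text fields {sorted(bad)}")


@dataclass(frozen=True)
class LineCombo:
    """Boolean combination of earlier strategy lines."""

    op: str
    line_refs: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or", "not"):
            raise ValueError(f"unknown Boolean operator {self.op!r}")
        if not self.line_refs:
            raise ValueError("line combination references no lines")
        if self.op == "not" and len(self.line_refs) != 2:
            raise ValueError("'not' takes exactly two line references")


QueryNode = MeshExp | MeshNoExp | TextWord | LineCombo


@dataclass
class Strategy:
    """An ordered, numbered search strategy (1..k consecutive lines)."""

    name: str
    lines: list[tuple[int, QueryNode]]

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.lines]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError(
                f"strategy {self.name!r}: line numbers must be 1..k consecutive"
            )
        for number, node in self.lines:
            if isinstance(node, LineCombo):
                for ref in node.line_refs:
                    if not 1 <= ref < number:
                        raise ValueError(
                            f"strategy {self.name!r} line {number}: reference to "
                            f"line {ref} is forward or out of range"
                        )

    def __len__(self) -> int:
        return len(self.lines)

    @property
    def final_line(self) -> int:
        return self.lines[-1][0]

    def leaves(self) -> list[QueryNode]:
        return [node for _, node in self.lines if not isinstance(node, LineCombo)]

    def to_dict(self) -> dict:
        def node_dict(node: QueryNode) -> dict:
            if isinstance(node, MeshExp):
                return {"type": "mesh_exp", "heading": node.heading}
            if isinstance(node, MeshNoExp):
                return {"type": "mesh_noexp", "heading": node.heading}
            if isinstance(node, TextWord):
                return {
                    "type": "textword",
                    "term": node.term,
                    "truncated": node.truncated,
                    "fields": list(node.fields),
                }
            return {"type": "combo", "op": node.op, "refs": list(node.line_refs)}

        return {
            "name": self.name,
            "lines": [{"n": n, "node": node_dict(node)} for n, node in self.lines],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Serialize back to the numbered-line text format."""
        out = []
        for number, node in self.lines:
            if isinstance(node, MeshExp):
                expr = f"exp {node.heading}/"
            elif isinstance(node, MeshNoExp):
                expr = f"{node.heading}/"
            elif isinstance(node, TextWord):
                term = node.term + ("*" if node.truncated else "")
                expr = f'"{term}".tw' if " " in node.term or node.truncated else f"{term}.tw"
            else:
                refs = node.line_refs
                if list(refs) == list(range(refs[0], refs[-1] + 1)) and len(refs) > 2:
                    expr = f"{node.op}/{refs[0]}-{refs[-1]}"
                else:
                    expr = f" {node.op} ".join(str(r) for r in refs)
            out.append(f"{number} {expr}")
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Parsing

_LINE = re.compile(r"^\s*(\d+)\s+(.+?)\s*$")
_RANGE_COMBO = re.compile(r"^(and|or|not)\s*/\s*(\d+)\s*-\s*(\d+)$", re.IGNORECASE)
_INFIX_COMBO = re.compile(r"^\d+(\s+(and|or|not)\s+\d+)+$", re.IGNORECASE)
_FIELDED = re.compile(r'^"?(?P<term>[^".]+?)"?\.(?P<suffix>[a-z]+)\.?$', re.IGNORECASE)


def _parse_expr(expr: str, line_number: int) -> QueryNode:
    expr = expr.replace("–", "-").replace("—", "-").strip()

    m = _RANGE_COMBO.match(expr)
    if m:
        op, lo, hi = m.group(1).lower(), int(m.group(2)), int(m.group(3))
        if hi < lo:
            raise ValueError(f"line {line_number}: empty range {lo}-{hi}")
        return LineCombo(op=op, line_refs=tuple(range(lo, hi + 1)))

    if _INFIX_COMBO.match(expr):
        parts = expr.lower().split()
        ops = set(parts[1::2])
        if len(ops) != 1:
            raise ValueError(
                f"line {line_number}: mixed Boolean operators in {expr!r}"
            )
        return LineCombo(op=ops.pop(), line_refs=tuple(int(p) for p in parts[0::2]))

    if expr.lower().startswith("exp ") and expr.endswith("/"):
        return MeshExp(heading=expr[4:-1].strip())

    if expr.endswith("/") and "." not in expr:
        return MeshNoExp(heading=expr[:-1].strip())

    m = _FIELDED.match(expr)
    if m:
        suffix = m.group("suffix").lower()
        if suffix != "tw":
            raise ValueError(
                f"line {line_number}: unsupported field suffix .{suffix} "
                f"(only .tw is recognized)"
            )
        term = m.group("term").strip()
        truncated = term.endswith("*")
        term = term.rstrip("*").strip()
        if "*" in term:
            raise ValueError(
                f"line {line_number}: embedded wildcard in {m.group('term')!r} "
                "(only trailing truncation is supported)"
            )
        return TextWord(term=term.lower(), truncated=truncated)

    raise ValueError(f"line {line_number}: cannot parse expression {expr!r}")


def parse_strategy(text: str, name: str = "strategy") -> Strategy:
    """Parse numbered-line Ovid-dialect strategy text into a Strategy.

    Hyphen and en-dash are both accepted in ``or/1–13`` ranges.  Forward
    or out-of-range line references are errors naming the line.
    """
    lines: list[tuple[int, QueryNode]] = []
    for raw in text.splitlines():
        if not raw.strip():
            continue
        m = _LINE.match(raw)
        if not m:
            raise ValueError(f"cannot parse strategy line {raw!r}")
        number = int(m.group(1))
        node = _parse_expr(m.group(2), number)
        lines.append((number, node))
    if not lines:
        raise ValueError("strategy text contains no lines")
    return Strategy(name=name, lines=lines)


def strategy_from_dict(data: Mapping) -> Strategy:
    """Inverse of Strategy.to_dict (JSON round-trip)."""
    lines: list[tuple[int, QueryNode]] = []
    for item in data["lines"]:
        nd = item["node"]
        node: QueryNode
        if nd["type"] == "mesh_exp":
            node = MeshExp(nd["heading"])
        elif nd["type"] == "mesh_noexp":
            node = MeshNoExp(nd["heading"])
        elif nd["type"] == "textword":
            node = TextWord(nd["term"], nd["truncated"], tuple(nd["fields"]))
        else:
            node = LineCombo(nd["op"], tuple(nd["refs"]))
        lines.append((item["n"], node))
    return Strategy(name=data["name"], lines=lines)


# ---------------------------------------------------------------------------
# Evaluation

_warned_empty_tree = False


def _match_tokens(term: str, truncated: bool, tokens: Sequence[str]) -> bool:
    words = term.split()
    if not words:
        return False
    head, last = words[:-1], words[-1]
    k = len(words)
    for i in range(len(tokens) - k + 1):
        if list(tokens[i : i + k - 1]) != head:
            continue
        tok = tokens[i + k - 1]
        if tok.startswith(last) if truncated else tok == last:
            return True
    return False


def evaluate_line(node: QueryNode, record: Record, mesh_tree: MeshTree) -> bool:
    """Evaluate one leaf query node against one record.

    LineCombo nodes depend on sibling lines and must be evaluated through
    :func:`apply_strategy`.
    """
    global _warned_empty_tree
    if isinstance(node, TextWord):
        for fld in node.fields:
            tokens = tokenize(getattr(record, fld))
            if _match_tokens(node.term, node.truncated, tokens):
                return True
        return False
    if isinstance(node, MeshNoExp):
        from .corpus import normalize_heading

        return normalize_heading(node.heading) in record.mesh_keys
    if isinstance(node, MeshExp):
        if len(mesh_tree) == 0 and not _warned_empty_tree:
            logger.warning(
                "empty MeSH tree: exploded headings behave as non-exploded"
            )
            _warned_empty_tree = True
        return bool(mesh_tree.explode(node.heading) & record.mesh_keys)
    raise TypeError("LineCombo nodes are evaluated by apply_strategy")


@dataclass
class StrategyResult:
    """Per-line match sets of one strategy run; .retrieved is the final line."""

    strategy: Strategy
    line_sets: dict[int, frozenset[str]]

    @property
    def retrieved(self) -> frozenset[str]:
        return self.line_sets[self.strategy.final_line]


def apply_strategy(
    strategy: Strategy,
    records: Iterable[Record],
    mesh_tree: MeshTree,
    full_result: bool = False,
) -> frozenset[str] | StrategyResult:
    """Run a strategy over a corpus; return the final line's id set.

    With ``full_result=True`` returns a :class:`StrategyResult` exposing
    every line's match set for inspection.
    """
    records = list(records)
    line_sets: dict[int, frozenset[str]] = {}
    for number, node in strategy.lines:
        if isinstance(node, LineCombo):
            sets = [line_sets[r] for r in node.line_refs]
            if node.op == "or":
                result = frozenset().union(*sets)
            elif node.op == "and":
                result = sets[0].intersection(*sets[1:])
            else:  # not
                result = sets[0] - sets[1]
        else:
            result = frozenset(
                rec.id for rec in records if evaluate_line(node, rec, mesh_tree)
            )
        line_sets[number] = result
    res = StrategyResult(strategy=strategy, line_sets=line_sets)
    return res if full_result else res.retrieved


# ---------------------------------------------------------------------------
# Built-in strategies

#: The prognostic-factor filter: five exploded MeSH headings and eight
#: textword terms (prognos* and predict* truncated), OR-joined.
PF_FILTER_TEXT = """\
1 exp Risk/
2 risk.tw
3 exp Cohort Studies/
4 cohort.tw
5 exp Prognosis/
6 "prognos*".tw
7 "predict*".tw
8 exp Incidence/
9 incidence.tw
10 exp Survival Analysis/
11 survival.tw
12 "causal factor".tw
13 course.tw
14 or/1-13
"""


def _haynes_broad() -> Strategy:
    # Hand-translated from the PubMed form of the Haynes sensitive ("broad")
    # prognosis filter: incidence[MeSH:noexp] OR mortality[MeSH Terms] OR
    # follow up studies[MeSH:noexp] OR prognos*/predict*/course*[Text Word].
    lines: list[tuple[int, QueryNode]] = [
        (1, MeshNoExp("Incidence")),
        (2, MeshExp("Mortality")),
        (3, MeshNoExp("Follow-Up Studies")),
        (4, TextWord("prognos", truncated=True)),
        (5, TextWord("predict", truncated=True)),
        (6, TextWord("course", truncated=True)),
        (7, LineCombo("or", tuple(range(1, 7)))),
    ]
    return Strategy(name="haynes_broad", lines=lines)


def builtin_strategies() -> dict[str, Strategy]:
    """Bundled strategies: ``pf_filter`` and ``haynes_broad``."""
    return {
        "pf_filter": parse_strategy(PF_FILTER_TEXT, name="pf_filter"),
        "haynes_broad": _haynes_broad(),
    }
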