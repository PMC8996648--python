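"""Bibliographic records, reference sets and the MeSH tree.

The unit of analysis throughout the package is a bibliographic record:
an identifier, a title, an (optionally empty) abstract and a set of MeSH
headings.  Records are read from the PubMed/MEDLINE flat-file ("nbib")
format or from RIS.  Reference sets — the known-relevant records of a
systematic review — are plain id lists.  The MeSH tree maps headings to
dot-separated tree numbers and supplies the descendant relation that
"exploded" MeSH searches rely on.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import Medline

logger = logging.getLogger(__name__)

__all__ = [
    "Record",
    "MeshTree",
    "ReferenceSet",
    "read_records",
    "write_records",
    "read_mesh_tree",
    "read_reference_set",
]


def normalize_heading(heading: str) -> str:
    """Canonical key for MeSH heading comparison.

    Case-insensitive and punctuation-insensitive, so that e.g.
    "Follow-Up Studies" and "follow up studies" compare equal.
    """
    return " ".join(re.split(r"[^0-9a-z]+", heading.casefold())).strip()


@dataclass(frozen=True)
class Record:
    """One bibliographic record — the unit retrieved or not retrieved."""

    id: str
    title: str
    abstract: str = ""
    mesh_headings: frozenset[str] = frozenset()
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.title:
            raise ValueError(f"record {self.id!r}: title must be non-empty")
        object.__setattr__(self, "mesh_headings", frozenset(self.mesh_headings))

    @property
    def mesh_keys(self) -> frozenset[str]:
        return frozenset(normalize_heading(h) for h in self.mesh_headings)


@dataclass
class MeshTree:
    """Heading <-> tree-number maps with prefix-based descendant relation.

    X is a descendant of Y iff some tree number of X extends a tree
    number of Y by one or more ".suffix" components.
    """

    heading_to_treenums: dict[str, set[str]] = field(default_factory=dict)
    treenum_to_heading: dict[str, str] = field(default_factory=dict)
    _key_to_heading: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._key_to_heading = {
            normalize_heading(h): h for h in self.heading_to_treenums
        }

    def __len__(self) -> int:
        return len(self.heading_to_treenums)

    def treenums(self, heading: str) -> set[str]:
        canonical = self._key_to_heading.get(normalize_heading(heading))
        if canonical is None:
            return set()
        return self.heading_to_treenums[canonical]

    def is_descendant(self, heading: str, ancestor: str) -> bool:
        """Strict descendant test under the tree-number prefix rule."""
        anc_nums = self.treenums(ancestor)
        return any(
            num.startswith(a + ".")
            for num in self.treenums(heading)
            for a in anc_nums
        )

    def explode(self, heading: str) -> set[str]:
        """Normalized keys of *heading* and every tree descendant."""
        keys = {normalize_heading(heading)}
        anc_nums = self.treenums(heading)
        for num, h in self.treenum_to_heading.items():
            if any(num.startswith(a + ".") for a in anc_nums):
                keys.add(normalize_heading(h))
        return keys


@dataclass
class ReferenceSet:
    """The known-relevant records of one systematic review."""

    review_label: str
    included_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.included_ids = frozenset(self.included_ids)
        if not self.included_ids:
            raise ValueError(f"reference set {self.review_label!r} is empty")

    def __len__(self) -> int:
        return len(self.included_ids)


# ---------------------------------------------------------------------------
# MEDLINE flat file


def _strip_mesh(value: str) -> str:
    # "Risk Factors/*epidemiology" -> "Risk Factors"; "*Prognosis" -> "Prognosis"
    return value.split("/")[0].replace("*", "").strip()


def _year_from_dp(dp: str | None) -> int | None:
    if not dp:
        return None
    m = re.match(r"\s*(\d{4})", dp)
    return int(m.group(1)) if m else None


def _records_from_medline(stream: TextIO) -> list[Record]:
    records: list[Record] = []
    for index, entry in enumerate(Medline.parse(stream)):
        pmid = entry.get("PMID", "").strip()
        title = (entry.get("TI") or "").strip()
        if not pmid:
            raise ValueError(f"entry {index}: missing PMID")
        if not title:
            raise ValueError(f"entry {index} (PMID {pmid}): missing title")
        mesh = frozenset(
            _strip_mesh(mh) for mh in entry.get("MH", []) if _strip_mesh(mh)
        )
        records.append(
            Record(
                id=pmid,
                title=title,
                abstract=(entry.get("AB") or "").strip(),
                mesh_headings=mesh,
                year=_year_from_dp(entry.get("DP")),
            )
        )
    return records


def _wrap_field(tag: str, value: str) -> str:
    return f"{tag.ljust(4)}- {value}"


def _write_medline(records: Iterable[Record], stream: TextIO) -> None:
    for rec in records:
        lines = [_wrap_field("PMID", rec.id), _wrap_field("TI", rec.title)]
        if rec.abstract:
            lines.append(_wrap_field("AB", rec.abstract))
        for mh in sorted(rec.mesh_headings):
            lines.append(_wrap_field("MH", mh))
        if rec.year is not None:
            lines.append(_wrap_field("DP", str(rec.year)))
        stream.write("\n".join(lines) + "\n\n")


# ---------------------------------------------------------------------------
# RIS (minimal tag subset: TY, ID, TI/T1, AB/N2, KW, PY, ER)

_RIS_LINE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _records_from_ris(stream: TextIO) -> list[Record]:
    records: list[Record] = []
    current: dict[str, list[str]] = {}
    index = 0
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        m = _RIS_LINE.match(line)
        if not m:
            continue  # continuation lines of long fields are ignored
        tag, value = m.group(1), m.group(2).strip()
        if tag == "ER":
            records.append(_ris_entry_to_record(current, index))
            current = {}
            index += 1
        else:
            current.setdefault(tag, []).append(value)
    if current:
        records.append(_ris_entry_to_record(current, index))
    return records


def _ris_entry_to_record(entry: dict[str, list[str]], index: int) -> Record:
    rid = (entry.get("ID") or entry.get("AN") or [""])[0]
    title = (entry.get("TI") or entry.get("T1") or [""])[0]
    if not rid:
        raise ValueError(f"entry {index}: missing ID")
    if not title:
        raise ValueError(f"entry {index} (ID {rid}): missing title")
    abstract = (entry.get("AB") or entry.get("N2") or [""])[0]
    year = None
    if entry.get("PY"):
        m = re.match(r"(\d{4})", entry["PY"][0])
        year = int(m.group(1)) if m else None
    return Record(
        id=rid,
        title=title,
        abstract=abstract,
        mesh_headings=frozenset(entry.get("KW", [])),
        year=year,
    )


def _write_ris(records: Iterable[Record], stream: TextIO) -> None:
    for rec in records:
        stream.write("TY  - JOUR\n")
        stream.write(f"ID  - {rec.id}\n")
        stream.write(f"TI  - {rec.title}\n")
        if rec.abstract:
            stream.write(f"AB  - {rec.abstract}\n")
        for kw in sorted(rec.mesh_headings):
            stream.write(f"KW  - {kw}\n")
        if rec.year is not None:
            stream.write(f"PY  - {rec.year}\n")
        stream.write("ER  - \n\n")


# ---------------------------------------------------------------------------
# Public readers / writers


def _as_text_stream(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8")
    return source


def read_records(source, format: str = "medline") -> list[Record]:
    """Read bibliographic records from a path or open text stream.

    Parameters
    ----------
    source
        Path or text stream.
    format
        ``"medline"`` (PubMed nbib flat file) or ``"ris"``.

    MEDLINE ``MH`` values have subheadings (text after ``/``) and
    major-topic asterisks stripped.  Duplicate ids raise a ``ValueError``
    naming the id.
    """
    stream = _as_text_stream(source)
    try:
        if format == "medline":
            records = _records_from_medline(stream)
        elif format == "ris":
            records = _records_from_ris(stream)
        else:
            raise ValueError(f"unknown record format {format!r}")
    finally:
        if stream is not source:
            stream.close()
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_records(records: Iterable[Record], sink, format: str = "medline") -> None:
    """Write records in MEDLINE or RIS format (round-trips with read_records)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_records(records, fh, format=format)
        return
    if format == "medline":
        _write_medline(records, sink)
    elif format == "ris":
        _write_ris(records, sink)
    else:
        raise ValueError(f"unknown record format {format!r}")


def records_to_medline_text(records: Iterable[Record]) -> str:
    buf = io.StringIO()
    _write_medline(records, buf)
    return buf.getvalue()


def read_mesh_tree(source) -> MeshTree:
    """Read a two-column (heading, tree number) delimited file.

    Tab, comma or semicolon delimited; one pair per line; a heading may
    appear on several lines (one per tree number).  Malformed lines raise
    with their line number.  An empty file yields an empty tree, under
    which explosion degenerates to exact heading match.
    """
    stream = _as_text_stream(source)
    h2t: dict[str, set[str]] = {}
    t2h: dict[str, str] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t|,|;", line)
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise ValueError(
                    f"mesh tree line {lineno}: expected 'heading<TAB>treenum', got {line!r}"
                )
            heading, treenum = parts
            if not re.fullmatch(r"[A-Za-z]\d+(\.\d+)*", treenum):
                raise ValueError(
                    f"mesh tree line {lineno}: malformed tree number {treenum!r}"
                )
            h2t.setdefault(heading, set()).add(treenum)
            t2h[treenum] = heading
    finally:
        if stream is not source:
            stream.close()
    return MeshTree(heading_to_treenums=h2t, treenum_to_heading=t2h)


def read_reference_set(source, label: str) -> ReferenceSet:
    """Read a one-id-per-line reference set; blank lines ignored.

    Repeated ids are de-duplicated with a logged warning; an input that
    is empty after parsing is an error.
    """
    stream = _as_text_stream(source)
    ids: set[str] = set()
    try:
        for raw in stream:
            rid = raw.strip()
            if not rid:
                continue
            if rid in ids:
                logger.warning(
                    "reference set %s: duplicate id %s de-duplicated", label, rid
                )
            ids.add(rid)
    finally:
        if stream is not source:
            stream.close()
    if not ids:
        raise ValueError(f"reference set {label!r}: no ids found")
    return ReferenceSet(review_label=label, included_ids=frozenset(ids))
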