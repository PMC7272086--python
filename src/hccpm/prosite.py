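"""Prosite-syntax motif patterns: parsing and sliding-window scanning.

A Prosite pattern is a dash-separated list of elements: a literal residue
(``A``), a residue class (``[RK]``), a negated class (``{P}``), or the
wildcard ``x``; any element may carry a repeat count ``(n)`` or range
``(n,m)``. ``<`` anchors the match to the N terminus, ``>`` to the
C terminus, and a trailing ``.`` terminates the pattern.

The scanner tests every window of the target sequence (all overlapping
matches are reported, variable-length elements enumerate every length) and
reports the phosphoacceptor position for each match.  Motif hits whose
acceptor residue is not Ser/Thr/Tyr/His are discarded before a motif may
nominate its kinases.

Coordinates in all reports are 1-based inclusive.  ``site_offset`` counts
0-based residue slots of the matched window (a repeat of length *k*
occupies *k* slots), so the acceptor position is ``start + site_offset``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .core import AMINO_ACIDS, PHOSPHOACCEPTORS, ProteinRecord


class PatternError(ValueError):
    """Raised for a malformed Prosite pattern; names the offending element."""

    def __init__(self, message: str, element_index: Optional[int] = None):
        self.element_index = element_index
        where = "" if element_index is None else f" (element {element_index})"
        super().__init__(message + where)


@dataclass(frozen=True)
class Element:
    """One pattern element with its repeat range."""

    kind: str  # "literal" | "class" | "negated" | "wildcard"
    residues: Optional[frozenset[str]]  # None for wildcard
    min_rep: int = 1
    max_rep: int = 1

    def matches(self, residue: str) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "negated":
            return residue not in self.residues
        return residue in self.residues


@dataclass(frozen=True)
class PatternAST:
    elements: tuple[Element, ...]
    anchor_n: bool = False
    anchor_c: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.min_rep for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_rep for e in self.elements)


@dataclass
class MotifDefinition:
    """A motif as distributed in a motif table (id, pattern, site, kinases)."""

    motif_id: str
    pattern: str
    site_offset: int
    max_repeat: int = 0  # 0 = unlimited
    skip_flag: bool = False
    kinase_accessions: set[str] = field(default_factory=set)
    description: str = ""

    def ast(self) -> PatternAST:
        return parse_pattern(self.pattern)


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence on one protein (1-based inclusive coordinates)."""

    accession: str
    motif_id: str
    start: int
    end: int
    matched_span: str
    site_position: int
    site_residue: str


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str, index: int) -> Element:
    min_rep = max_rep = 1
    m = _REPEAT_RE.search(token)
    if m:
        min_rep = int(m.group(1))
        max_rep = int(m.group(2)) if m.group(2) else min_rep
        if min_rep < 1 or max_rep < min_rep:
            raise PatternError(
                f"invalid repeat range ({min_rep},{max_rep})", index)
        token = token[: m.start()]
    if "(" in token or ")" in token:
        raise PatternError(f"malformed repeat in {token!r}", index)
    if token == "x":
        return Element("wildcard", None, min_rep, max_rep)
    if token.startswith("[") or token.startswith("{"):
        close = "]" if token[0] == "[" else "}"
        if not token.endswith(close) or len(token) < 3:
            raise PatternError(f"malformed or empty bracket in {token!r}", index)
        residues = frozenset(token[1:-1].upper())
        bad = residues - AMINO_ACIDS
        if bad:
            raise PatternError(
                f"non-residue letters {sorted(bad)} in {token!r}", index)
        kind = "class" if close == "]" else "negated"
        return Element(kind, residues, min_rep, max_rep)
    if len(token) == 1 and token.upper() in AMINO_ACIDS:
        return Element("literal", frozenset(token.upper()), min_rep, max_rep)
    raise PatternError(f"unrecognized element {token!r}", index)


def parse_pattern(pattern: str) -> PatternAST:
    """Parse a Prosite-syntax pattern into its element list."""
    if not pattern or not pattern.strip():
        raise PatternError("empty pattern")
    text = pattern.strip()
    if text.endswith("."):
        text = text[:-1]
    anchor_n = text.startswith("<")
    if anchor_n:
        text = text[1:]
    anchor_c = text.endswith(">")
    if anchor_c:
        text = text[:-1]
    if not text:
        raise PatternError("pattern has anchors but no elements")
    elements = tuple(
        _parse_element(tok, i) for i, tok in enumerate(text.split("-"))
    )
    return PatternAST(elements, anchor_n, anchor_c)


def _enumerate_matches(
    ast: PatternAST, seq: str, start: int
) -> Iterator[int]:
    """Yield end positions (exclusive) of every match beginning at ``start``."""

    def rec(idx: int, pos: int) -> Iterator[int]:
        if idx == len(ast.elements):
            yield pos
            return
        el = ast.elements[idx]
        # longest run of residues this element can absorb from pos
        k = 0
        while k < el.max_rep and pos + k < len(seq) and el.matches(seq[pos + k]):
            k += 1
        for rep in range(el.min_rep, k + 1):
            yield from rec(idx + 1, pos + rep)

    yield from rec(0, start)


def scan_sequence(
    ast: PatternAST, sequence: str, site_offset: int
) -> list[MotifMatch]:
    """Slide the pattern over ``sequence``, reporting all matches.

    Every start position is tested (anchored patterns restrict the tested
    windows); overlapping and duplicate-length matches are reported once per
    distinct (start, end) pair.  ``accession`` and ``motif_id`` are left
    empty; :func:`find_candidate_kinases` fills them in.
    """
    if site_offset < 0 or site_offset >= ast.min_length:
        raise ValueError(
            f"site_offset {site_offset} out of range for pattern of minimal "
            f"length {ast.min_length}")
    seq = sequence.upper()
    starts = [0] if ast.anchor_n else range(len(seq))
    out: list[MotifMatch] = []
    seen: set[tuple[int, int]] = set()
    for start in starts:
        for end in _enumerate_matches(ast, seq, start):
            if ast.anchor_c and end != len(seq):
                continue
            if (start, end) in seen:
                continue
            seen.add((start, end))
            site = start + site_offset
            out.append(MotifMatch(
                accession="",
                motif_id="",
                start=start + 1,
                end=end,
                matched_span=seq[start:end],
                site_position=site + 1,
                site_residue=seq[site],
            ))
    out.sort(key=lambda m: (m.start, m.end))
    return out


def find_candidate_kinases(
    protein: ProteinRecord,
    motifs: Iterable[MotifDefinition],
    enforce_max_repeat: bool = False,
    include_skipped: bool = False,
) -> dict[str, tuple[list[MotifMatch], frozenset[str]]]:
    """Map each matching motif to its surviving matches and candidate kinases.

    Motifs flagged ``skip_flag`` are excluded (unless ``include_skipped``);
    matches whose acceptor residue is not S/T/Y/H are discarded; a motif
    contributes its kinases iff at least one match survives.  When
    ``enforce_max_repeat`` is set and a motif declares ``max_repeat > 0``,
    at most that many matches are kept per protein.
    """
    if protein.sequence is None:
        raise ValueError(
            f"protein {protein.accession} has no sequence; provide one "
            "before motif scanning")
    result: dict[str, tuple[list[MotifMatch], frozenset[str]]] = {}
    for motif in motifs:
        if motif.skip_flag and not include_skipped:
            continue
        ast = motif.ast()
        matches = [
            MotifMatch(
                accession=protein.accession,
                motif_id=motif.motif_id,
                start=m.start,
                end=m.end,
                matched_span=m.matched_span,
                site_position=m.site_position,
                site_residue=m.site_residue,
            )
            for m in scan_sequence(ast, protein.sequence, motif.site_offset)
            if m.site_residue in PHOSPHOACCEPTORS
        ]
        if enforce_max_repeat and motif.max_repeat > 0:
            matches = matches[: motif.max_repeat]
        if matches:
            result[motif.motif_id] = (matches, frozenset(motif.kinase_accessions))
    return result


def candidate_kinase_set(
    protein: ProteinRecord, motifs: Iterable[MotifDefinition], **kwargs
) -> frozenset[str]:
    """Union of candidate kinases over all contributing motifs."""
    hits = find_candidate_kinases(protein, motifs, **kwargs)
    out: set[str] = set()
    for _, kinases in hits.values():
        out |= kinases
    return frozenset(out)
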