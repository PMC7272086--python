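"""Pattern parsing and sliding-window scanning, checked against an
independent regex translation of the Prosite syntax."""

from __future__ import annotations

import random
import re

import pytest

from hccpm.core import ProteinRecord
from hccpm.prosite import (
    MotifDefinition,
    PatternError,
    find_candidate_kinases,
    parse_pattern,
    scan_sequence,
)

# ---------------------------------------------------------------------------
# Independent oracle: Prosite -> Python regex, overlapped-start matching
# ---------------------------------------------------------------------------


def prosite_to_regex(pattern: str) -> str:
    text = pattern.strip().rstrip(".")
    prefix = suffix = ""
    if text.startswith("<"):
        prefix, text = "^", text[1:]
    if text.endswith(">"):
        suffix, text = "$", text[:-1]
    parts = []
    for token in text.split("-"):
        m = re.search(r"\((\d+)(?:,(\d+))?\)$", token)
        rep = ""
        if m:
            rep = "{%s}" % m.group(1) if m.group(2) is None \
                else "{%s,%s}" % (m.group(1), m.group(2))
            token = token[: m.start()]
        if token == "x":
            parts.append("." + rep)
        elif token.startswith("["):
            parts.append(token + rep)
        elif token.startswith("{"):
            parts.append("[^" + token[1:-1] + "]" + rep)
        else:
            parts.append(token + rep)
    return prefix + "".join(parts) + suffix


def regex_match_starts(pattern: str, seq: str) -> set[int]:
    """1-based start positions where the regex translation matches."""
    rx = re.compile(prosite_to_regex(pattern))
    if prosite_to_regex(pattern).startswith("^"):
        return {1} if rx.match(seq) else set()
    return {i + 1 for i in range(len(seq)) if rx.match(seq, i)}


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def test_parse_class_repeat_wildcard():
    ast = parse_pattern("[RK](2)-x-[ST].")
    assert len(ast.elements) == 3
    e0, e1, e2 = ast.elements
    assert e0.kind == "class" and e0.residues == frozenset("RK")
    assert (e0.min_rep, e0.max_rep) == (2, 2)
    assert e1.kind == "wildcard"
    assert e2.residues == frozenset("ST")


def test_parse_minimal_wildcard():
    ast = parse_pattern("x.")
    assert len(ast.elements) == 1
    assert ast.elements[0].kind == "wildcard"


def test_parse_negated_and_range():
    ast = parse_pattern("[ST]-x(2,3)-{P}")
    assert ast.elements[1].min_rep == 2 and ast.elements[1].max_rep == 3
    assert ast.elements[2].kind == "negated"
    assert ast.elements[2].residues == frozenset("P")


@pytest.mark.parametrize("bad", [
    "", "[ST", "[]", "x(3,2)", "x(0)", "[ST]-J", "x(2", "<>",
])
def test_parse_errors(bad):
    with pytest.raises((PatternError, ValueError)):
        parse_pattern(bad)


def test_parse_error_names_element_index():
    with pytest.raises(PatternError) as exc:
        parse_pattern("[ST]-x(3,2)")
    assert exc.value.element_index == 1


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def test_scan_reports_site_of_match():
    ast = parse_pattern("[ST]-x(2)-[DE]")
    matches = scan_sequence(ast, "AASGGDAA", 0)
    assert len(matches) == 1
    m = matches[0]
    assert (m.start, m.end, m.matched_span) == (3, 6, "SGGD")
    assert (m.site_position, m.site_residue) == (3, "S")


def test_scan_site_slot_inside_repeat_expansion():
    # the acceptor slot is counted over expanded residue positions
    ast = parse_pattern("[RK](2)-x-[ST]")
    matches = scan_sequence(ast, "AARRASAA", 3)
    assert len(matches) == 1
    assert (matches[0].site_position, matches[0].site_residue) == (6, "S")


def test_scan_n_terminal_anchor():
    ast = parse_pattern("<A-x")
    matches = scan_sequence(ast, "AGA", 0)
    assert [(m.start, m.end) for m in matches] == [(1, 2)]


def test_scan_c_terminal_anchor():
    ast = parse_pattern("A-x>")
    matches = scan_sequence(ast, "AGAG", 0)
    assert [(m.start, m.end) for m in matches] == [(3, 4)]


def test_scan_short_sequence_no_window():
    ast = parse_pattern("[ST]-x(2)-[DE]")
    assert scan_sequence(ast, "SG", 0) == []


def test_scan_variable_lengths_all_reported():
    ast = parse_pattern("A-x(1,3)-C")
    starts_ends = {(m.start, m.end)
                   for m in scan_sequence(ast, "AGGCC", 0)}
    # A at 1; windows AGGC (len 4) and AGGCC (len 5) both match
    assert starts_ends == {(1, 4), (1, 5)}


def test_scan_site_offset_out_of_range():
    ast = parse_pattern("A-x")
    with pytest.raises(ValueError):
        scan_sequence(ast, "AG", 5)


# ---------------------------------------------------------------------------
# Kinase candidate mapping
# ---------------------------------------------------------------------------


def _motif(pattern, offset, kinases, skip=False, motif_id="M1"):
    return MotifDefinition(motif_id, pattern, offset, skip_flag=skip,
                           kinase_accessions=set(kinases))


def test_candidate_kinases_from_surviving_match():
    protein = ProteinRecord("P1", sequence="AARRASAA")
    hits = find_candidate_kinases(
        protein, [_motif("[RK](2)-x-[ST]", 3, {"K1", "K2"})])
    assert set(hits) == {"M1"}
    matches, kinases = hits["M1"]
    assert kinases == frozenset({"K1", "K2"})
    assert matches[0].site_residue == "S"


def test_skip_flag_excludes_motif():
    protein = ProteinRecord("P1", sequence="AARRASAA")
    hits = find_candidate_kinases(
        protein, [_motif("[RK](2)-x-[ST]", 3, {"K1"}, skip=True)])
    assert hits == {}


def test_non_acceptor_site_discards_match():
    # pattern matches but the acceptor slot holds 'A'
    protein = ProteinRecord("P1", sequence="GGRAGG")
    hits = find_candidate_kinases(protein, [_motif("R-x", 1, {"K1"})])
    assert hits == {}


def test_protein_without_sequence_errors():
    with pytest.raises(ValueError):
        find_candidate_kinases(ProteinRecord("P1"), [_motif("x", 0, {"K1"})])


def test_max_repeat_caps_matches_when_enforced():
    protein = ProteinRecord("P1", sequence="GSGGSGGSG")
    motif = MotifDefinition("M1", "S-x", 0, max_repeat=2,
                            kinase_accessions={"K1"})
    hits = find_candidate_kinases(protein, [motif], enforce_max_repeat=True)
    assert len(hits["M1"][0]) == 2
    hits = find_candidate_kinases(protein, [motif])
    assert len(hits["M1"][0]) == 3


# ---------------------------------------------------------------------------
# Properties: regex-oracle equivalence, anchoring, specialization, revalidation
# ---------------------------------------------------------------------------

_ALPHABET = "ACDEGS"


def _random_pattern(rng: random.Random) -> str:
    tokens = []
    for _ in range(rng.randint(2, 4)):
        kind = rng.choice(["literal", "class", "negated", "wildcard"])
        if kind == "literal":
            tok = rng.choice(_ALPHABET)
        elif kind == "class":
            tok = "[" + "".join(rng.sample(_ALPHABET, rng.randint(2, 3))) + "]"
        elif kind == "negated":
            tok = "{" + "".join(rng.sample(_ALPHABET, rng.randint(1, 2))) + "}"
        else:
            tok = "x"
        r = rng.random()
        if r < 0.2:
            tok += f"({rng.randint(1, 3)})"
        elif r < 0.35:
            n = rng.randint(1, 2)
            tok += f"({n},{n + rng.randint(1, 2)})"
        tokens.append(tok)
    pattern = "-".join(tokens)
    if rng.random() < 0.15:
        pattern = "<" + pattern
    if rng.random() < 0.15:
        pattern += ">"
    return pattern


def test_scanner_agrees_with_regex_oracle_on_random_pairs():
    rng = random.Random(20240601)
    n_checked = 0
    for _ in range(1200):
        pattern = _random_pattern(rng)
        seq = "".join(rng.choices(_ALPHABET, k=rng.randint(5, 25)))
        ast = parse_pattern(pattern)
        got = {m.start for m in scan_sequence(ast, seq, 0)}
        expected = regex_match_starts(pattern, seq)
        if pattern.endswith(">"):
            # oracle start set must also respect the C anchor
            rx = re.compile(prosite_to_regex(pattern))
            expected = {i + 1 for i in range(len(seq))
                        if rx.match(seq, i)}
        assert got == expected, (pattern, seq)
        n_checked += 1
    assert n_checked >= 1000


def test_anchored_patterns_report_single_start():
    rng = random.Random(99)
    for _ in range(200):
        pattern = "<" + _random_pattern(rng).lstrip("<")
        seq = "".join(rng.choices(_ALPHABET, k=15))
        starts = {m.start for m in scan_sequence(parse_pattern(pattern),
                                                 seq, 0)}
        assert starts <= {1}


def test_specializing_wildcard_never_adds_matches():
    rng = random.Random(7)
    for _ in range(200):
        tokens = ["x", rng.choice(["[AC]", "{G}", "x"]),
                  rng.choice(list(_ALPHABET))]
        rng.shuffle(tokens)
        general = "-".join(tokens)
        special = "-".join(t if t != "x" else "A" for t in tokens)
        seq = "".join(rng.choices(_ALPHABET, k=20))
        g = {m.start for m in scan_sequence(parse_pattern(general), seq, 0)}
        s = {m.start for m in scan_sequence(parse_pattern(special), seq, 0)}
        assert s <= g, (general, special, seq)


def test_matched_spans_revalidate_in_isolation():
    rng = random.Random(11)
    for _ in range(200):
        pattern = _random_pattern(rng).lstrip("<").rstrip(">")
        seq = "".join(rng.choices(_ALPHABET, k=20))
        ast = parse_pattern(pattern)
        for m in scan_sequence(ast, seq, 0):
            inner = scan_sequence(ast, m.matched_span, 0)
            assert any(x.start == 1 and x.end == len(m.matched_span)
                       for x in inner), (pattern, m)
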