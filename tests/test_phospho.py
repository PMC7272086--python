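"""Component rule tables, the weighted kinase-correlation score, and
classification of phosphorylation support."""

import itertools

import pytest

from conftest import record
from hccpm.core import (
    Corpus,
    EvidenceClass as L,
    Localization,
    ProteinRecord,
    Support,
    Tissue as T,
)
from hccpm.phospho import (
    ClassificationMode,
    PhosphoCorrelationResult,
    PhosphoWeights,
    classify_phospho,
    kinase_correlation,
    localization_score,
    phase_score,
    score_protein,
    tissue_score,
)
from hccpm.prosite import MotifDefinition

# ---------------------------------------------------------------------------
# Tissue component St
# ---------------------------------------------------------------------------

TISSUE_TABLE = {
    (T.T1, T.T1): 10, (T.T1, T.T2): 6, (T.T2, T.T2): 6,
    (T.T1, T.T3): 2, (T.T2, T.T3): 2, (T.T3, T.T3): 2,
}


@pytest.mark.parametrize("a,b", list(itertools.product(list(T), repeat=2)))
def test_tissue_table_exhaustive(a, b):
    expected = 0 if T.ABSENT in (a, b) else TISSUE_TABLE[
        tuple(sorted((a, b), key=list(T).index))]
    assert tissue_score(record("Q", tissue=a), record("K", tissue=b)) \
        == expected


def test_tissue_symmetry():
    for a, b in itertools.product(list(T), repeat=2):
        assert tissue_score(record("Q", tissue=a), record("K", tissue=b)) \
            == tissue_score(record("Q", tissue=b), record("K", tissue=a))


# ---------------------------------------------------------------------------
# Localization component Sl
# ---------------------------------------------------------------------------

LAYER1_TABLE = {
    (L.L1, L.L1): 10,
    (L.L1, L.L2): 8, (L.L2, L.L2): 8,
    (L.L1, L.L3): 4, (L.L2, L.L3): 4, (L.L3, L.L3): 4,
    (L.L1, L.L4): 2, (L.L2, L.L4): 2, (L.L3, L.L4): 2, (L.L4, L.L4): 2,
}


@pytest.mark.parametrize("qa,ka", list(itertools.product(list(L), repeat=2)))
def test_layer1_table_exhaustive(qa, ka):
    q = record("Q", go={("GO:1", qa)})
    k = record("K", go={("GO:1", ka)})
    expected = LAYER1_TABLE[tuple(sorted((qa, ka), key=list(L).index))]
    assert localization_score(q, k) == expected


def test_no_shared_term_no_category_scores_zero():
    q = record("Q", go={("GO:1", L.L1)})
    k = record("K", go={("GO:2", L.L1)})
    assert localization_score(q, k) == 0


def test_layer2_shared_category_lifts_low_layer1():
    q = record("Q", go={("GO:1", L.L1)}, cats={Localization.NUCLEUS})
    k = record("K", go={("GO:1", L.L4)}, cats={Localization.NUCLEUS})
    assert localization_score(q, k) == 6


def test_layer2_does_not_override_final_layer1():
    # layer-1 score of 8 is final even with a shared category
    q = record("Q", go={("GO:1", L.L2)}, cats={Localization.NUCLEUS})
    k = record("K", go={("GO:1", L.L2)}, cats={Localization.NUCLEUS})
    assert localization_score(q, k) == 8


def test_layer1_takes_best_shared_term():
    q = record("Q", go={("GO:1", L.L4), ("GO:2", L.L1)})
    k = record("K", go={("GO:1", L.L4), ("GO:2", L.L1)})
    assert localization_score(q, k) == 10


def test_layer2_without_shared_category_keeps_layer1():
    q = record("Q", go={("GO:1", L.L3)}, cats={Localization.NUCLEUS})
    k = record("K", go={("GO:1", L.L1)}, cats={Localization.CYTOPLASM})
    assert localization_score(q, k) == 4


# ---------------------------------------------------------------------------
# Phase component Sp
# ---------------------------------------------------------------------------


def test_phase_overlapping_support():
    assert phase_score(record("Q", phase=0), record("K", phase=25)) == 10


def test_phase_disjoint_support():
    assert phase_score(record("Q", phase=0), record("K", phase=50)) == 0


def test_phase_missing_profile_scores_zero():
    assert phase_score(record("Q"), record("K", phase=0)) == 0
    assert phase_score(record("Q", phase=0), record("K")) == 0


# ---------------------------------------------------------------------------
# Sk and classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("st,sl,sp,expected", [
    (6, 6, 10, 6.8),
    (6, 6, 0, 4.8),
    (0, 0, 0, 0.0),
    (10, 10, 10, 10.0),
])
def test_weighted_mean_examples(st, sl, sp, expected):
    assert kinase_correlation(st, sl, sp) == pytest.approx(expected)


def test_nonpositive_weights_rejected():
    with pytest.raises(ValueError):
        PhosphoWeights(0, 3, 2)


ST_VALUES = (0, 2, 6, 10)
SL_VALUES = (0, 2, 4, 6, 8, 10)
SP_VALUES = (0, 10)


def test_lattice_minima_match_published_cutoffs():
    """Brute force over the 4x6x2 component lattice: the minimal Sk among
    strongly-suggestive states is 6.8 and among phase-free suggestive
    states is 4.8, so the component criteria imply the Sk cutoffs."""
    strong = [kinase_correlation(st, sl, 10)
              for st in ST_VALUES if st >= 6
              for sl in SL_VALUES if sl >= 6]
    sugg = [kinase_correlation(st, sl, 0)
            for st in ST_VALUES if st >= 6
            for sl in SL_VALUES if sl >= 6]
    assert min(strong) == pytest.approx(6.8)
    assert min(sugg) == pytest.approx(4.8)


def test_sk_monotone_and_bounded_on_lattice():
    for st, sl, sp in itertools.product(ST_VALUES, SL_VALUES, SP_VALUES):
        sk = kinase_correlation(st, sl, sp)
        assert 0 <= sk <= 10
        # one-step monotonicity in each coordinate
        for dst, dsl, dsp in ((2, 0, 0), (0, 2, 0), (0, 0, 10)):
            sk2 = kinase_correlation(st + dst, sl + dsl, sp + dsp)
            assert sk2 >= sk
        # default weights sum to 10 -> Sk is an integer multiple of 0.1
        assert round(sk * 10) == pytest.approx(sk * 10)


def _result(st, sl, sp, kinase="K1"):
    return PhosphoCorrelationResult(
        query_accession="Q", best_kinase=kinase,
        st=st, sl=sl, sp=sp, sk=kinase_correlation(st, sl, sp))


@pytest.mark.parametrize("st,sl,sp,criteria,threshold", [
    (6, 6, 10, Support.STRONGLY_SUGGESTIVE, Support.STRONGLY_SUGGESTIVE),
    (6, 6, 0, Support.SUGGESTIVE, Support.SUGGESTIVE),
    (10, 6, 0, Support.SUGGESTIVE, Support.STRONGLY_SUGGESTIVE),
    (2, 10, 10, Support.NOT_SUPPORTED, Support.SUGGESTIVE),
    (0, 0, 0, Support.NOT_SUPPORTED, Support.NOT_SUPPORTED),
])
def test_classification_modes(st, sl, sp, criteria, threshold):
    r = _result(st, sl, sp)
    assert classify_phospho(r, ClassificationMode.CRITERIA) == criteria
    assert classify_phospho(r, ClassificationMode.THRESHOLD) == threshold


def test_modes_diverge_at_documented_state():
    # (10, 10, 0): criteria say suggestive (phase fails), Sk = 8 >= 6.8
    r = _result(10, 10, 0)
    assert r.sk == pytest.approx(8.0)
    assert classify_phospho(r, ClassificationMode.CRITERIA) \
        == Support.SUGGESTIVE
    assert classify_phospho(r, ClassificationMode.THRESHOLD) \
        == Support.STRONGLY_SUGGESTIVE


# ---------------------------------------------------------------------------
# score_protein integration
# ---------------------------------------------------------------------------


def _corpus(query, kinases, motif_kinases):
    return Corpus(
        proteins=[query, *kinases],
        motifs=[MotifDefinition("M1", "[RK](2)-x-[ST]", 3,
                                kinase_accessions=set(motif_kinases))],
    )


def test_perfect_pair_scores_ten():
    q = record("Q", sequence="AARRASAA", tissue=T.T1,
               go={("GO:1", L.L1)}, phase=0)
    k = record("K1", tissue=T.T1, go={("GO:1", L.L1)}, phase=25,
               is_kinase=True)
    res = score_protein(q, _corpus(q, [k], ["K1"]))
    assert res.best_kinase == "K1"
    assert res.sk == pytest.approx(10.0)
    assert res.classification == Support.STRONGLY_SUGGESTIVE


def test_no_motif_match_not_supported():
    q = record("Q", sequence="AAAAAAAA")
    k = record("K1", is_kinase=True)
    res = score_protein(q, _corpus(q, [k], ["K1"]))
    assert res.best_kinase is None
    assert res.per_kinase == []
    assert res.classification == Support.NOT_SUPPORTED


def test_highest_sk_kinase_selected():
    q = record("Q", sequence="AARRASAA", tissue=T.T1,
               go={("GO:1", L.L1)}, phase=0)
    weak = record("KA", tissue=T.T3, is_kinase=True)           # Sk low
    strong = record("KB", tissue=T.T1, go={("GO:1", L.L1)},
                    phase=25, is_kinase=True)                  # Sk = 10
    res = score_protein(q, _corpus(q, [weak, strong], ["KA", "KB"]))
    assert res.best_kinase == "KB"


def test_equal_sk_ties_break_lexicographically():
    q = record("Q", sequence="AARRASAA", tissue=T.T1)
    k1 = record("KB", tissue=T.T1, is_kinase=True)
    k2 = record("KA", tissue=T.T1, is_kinase=True)
    res = score_protein(q, _corpus(q, [k1, k2], ["KA", "KB"]))
    assert res.best_kinase == "KA"


def test_unresolvable_kinase_skipped_with_warning():
    q = record("Q", sequence="AARRASAA", tissue=T.T1)
    k = record("K1", tissue=T.T1, is_kinase=True)
    with pytest.warns(UserWarning, match="GHOST"):
        res = score_protein(q, _corpus(q, [k], ["K1", "GHOST"]))
    assert [s.kinase_accession for s in res.per_kinase] == ["K1"]
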