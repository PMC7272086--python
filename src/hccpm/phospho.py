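"""Kinase-correlation scoring of phosphorylation plausibility.

For a query protein and each candidate kinase nominated by motif scanning,
three environmental components are scored:

* tissue (``St``): both partners must be expressed in liver, blood, or the
  lymphatic system; the weaker evidence tier of the pair sets the score
  (both T1 -> 10, weakest T2 -> 6, weakest T3 -> 2, either absent -> 0);
* subcellular localization (``Sl``): a two-layer rule — layer 1 scores the
  best shared GO cellular-component term by the pair's evidence classes
  (both L1 -> 10, worst L2 -> 8, worst L3 -> 4, worst L4 -> 2); when layer 1
  stays below 8, a shared UniProt-style category yields 6;
* cell-cycle phase (``Sp``): 10 when both genes are co-expressed at some
  point of the cycle, 0 otherwise (including missing profiles).

The kinase-correlation score is their weighted mean

    Sk = (Wt*St + Wl*Sl + Wp*Sp) / (Wt + Wl + Wp)

with default weights Wt=5, Wl=3, Wp=2 (tissue specificity carries half the
total weight; phase data are scarcer than localization data).  The best
kinase is the one with the highest Sk.

Two classification modes exist.  The component-criteria mode (default)
calls a pair strongly suggestive when St >= 6, Sl >= 6 and Sp = 10, and
suggestive when St >= 6 and Sl >= 6 regardless of phase (phase data being
sparse).  The threshold mode uses the Sk cutoffs 6.8 and 4.8 instead; with
default weights the two modes agree on the canonical states but diverge
e.g. at (St, Sl, Sp) = (10, 10, 0), where Sk = 8 >= 6.8 yet the phase
criterion fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .core import Corpus, EvidenceClass, ProteinRecord, Support, Tissue
from .cycle import coexpressed
from .prosite import candidate_kinase_set


class ClassificationMode(str, Enum):
    CRITERIA = "criteria"
    THRESHOLD = "threshold"


@dataclass(frozen=True)
class PhosphoWeights:
    """Component weights of the kinase-correlation score."""

    wt: float = 5.0
    wl: float = 3.0
    wp: float = 2.0

    def __post_init__(self) -> None:
        if min(self.wt, self.wl, self.wp) <= 0:
            raise ValueError("all weights must be positive")


DEFAULT_WEIGHTS = PhosphoWeights()

#: Sk cutoffs of the threshold classification mode.
SK_STRONG = 6.8
SK_SUGGESTIVE = 4.8

_TISSUE_RANK = {Tissue.T1: 0, Tissue.T2: 1, Tissue.T3: 2}
_TISSUE_SCORE = {Tissue.T1: 10.0, Tissue.T2: 6.0, Tissue.T3: 2.0}

_CLASS_RANK = {
    EvidenceClass.L1: 0, EvidenceClass.L2: 1,
    EvidenceClass.L3: 2, EvidenceClass.L4: 3,
}
_PAIR_SCORE = {
    EvidenceClass.L1: 10.0,  # both L1
    EvidenceClass.L2: 8.0,   # worst is L2
    EvidenceClass.L3: 4.0,   # worst is L3
    EvidenceClass.L4: 2.0,   # worst is L4
}


def tissue_score(query: ProteinRecord, kinase: ProteinRecord) -> float:
    """``St``: set by the weaker tissue-evidence tier of the pair."""
    a, b = query.tissue_evidence, kinase.tissue_evidence
    if a == Tissue.ABSENT or b == Tissue.ABSENT:
        return 0.0
    weaker = max(a, b, key=_TISSUE_RANK.__getitem__)
    return _TISSUE_SCORE[weaker]


def localization_score(query: ProteinRecord, kinase: ProteinRecord) -> float:
    """``Sl``: two-layer shared-localization score.

    Layer 1 examines every GO CC term annotated on both records and scores
    the pair of (best) evidence classes; the maximum over shared terms is
    kept.  A layer-1 score of 8 or more is final; otherwise sharing a
    localization category lifts the score to at least 6.
    """
    q_terms = query.best_class_per_term()
    k_terms = kinase.best_class_per_term()
    layer1 = 0.0
    for term in q_terms.keys() & k_terms.keys():
        worst = max(q_terms[term], k_terms[term], key=_CLASS_RANK.__getitem__)
        layer1 = max(layer1, _PAIR_SCORE[worst])
    if layer1 >= 8:
        return layer1
    if query.localization_categories & kinase.localization_categories:
        return max(layer1, 6.0)
    return layer1


def phase_score(
    query: ProteinRecord, kinase: ProteinRecord, threshold: float = 0.0
) -> float:
    """``Sp``: 10 iff both genes have profiles and are co-expressed."""
    if query.cycle_profile is None or kinase.cycle_profile is None:
        return 0.0
    return 10.0 if coexpressed(
        query.cycle_profile, kinase.cycle_profile, threshold) else 0.0


def kinase_correlation(
    st: float, sl: float, sp: float,
    weights: PhosphoWeights = DEFAULT_WEIGHTS,
) -> float:
    """Weighted-mean kinase-correlation score ``Sk``."""
    total = weights.wt + weights.wl + weights.wp
    return (weights.wt * st + weights.wl * sl + weights.wp * sp) / total


@dataclass(frozen=True)
class KinaseScore:
    kinase_accession: str
    st: float
    sl: float
    sp: float
    sk: float
    is_self: bool = False  # autophosphorylation candidate


@dataclass
class PhosphoCorrelationResult:
    query_accession: str
    best_kinase: Optional[str] = None
    st: float = 0.0
    sl: float = 0.0
    sp: float = 0.0
    sk: float = 0.0
    per_kinase: list[KinaseScore] = field(default_factory=list)
    classification: Support = Support.NOT_SUPPORTED


def classify_phospho(
    result: PhosphoCorrelationResult,
    mode: ClassificationMode = ClassificationMode.CRITERIA,
    strong_cutoff: float = SK_STRONG,
    suggestive_cutoff: float = SK_SUGGESTIVE,
) -> Support:
    """Classify a scored result by component criteria or Sk thresholds."""
    if mode == ClassificationMode.THRESHOLD:
        if result.best_kinase is None:
            return Support.NOT_SUPPORTED
        if result.sk >= strong_cutoff:
            return Support.STRONGLY_SUGGESTIVE
        if result.sk >= suggestive_cutoff:
            return Support.SUGGESTIVE
        return Support.NOT_SUPPORTED
    if result.best_kinase is None:
        return Support.NOT_SUPPORTED
    if result.st >= 6 and result.sl >= 6:
        if result.sp == 10:
            return Support.STRONGLY_SUGGESTIVE
        return Support.SUGGESTIVE
    return Support.NOT_SUPPORTED


def score_pair(
    query: ProteinRecord,
    kinase: ProteinRecord,
    weights: PhosphoWeights = DEFAULT_WEIGHTS,
    coexpression_threshold: float = 0.0,
) -> KinaseScore:
    st = tissue_score(query, kinase)
    sl = localization_score(query, kinase)
    sp = phase_score(query, kinase, coexpression_threshold)
    return KinaseScore(
        kinase_accession=kinase.accession,
        st=st, sl=sl, sp=sp,
        sk=kinase_correlation(st, sl, sp, weights),
        is_self=kinase.accession == query.accession,
    )


def score_protein(
    query: ProteinRecord,
    corpus: Corpus,
    weights: PhosphoWeights = DEFAULT_WEIGHTS,
    coexpression_threshold: float = 0.0,
    mode: ClassificationMode = ClassificationMode.CRITERIA,
    enforce_max_repeat: bool = False,
    strong_cutoff: float = SK_STRONG,
    suggestive_cutoff: float = SK_SUGGESTIVE,
) -> PhosphoCorrelationResult:
    """Score one query against every motif-nominated candidate kinase.

    The best kinase is the Sk argmax (ties broken by lexicographic
    accession).  A query with no surviving motif match — or no sequence —
    yields an empty result classified NOT_SUPPORTED.
    """
    result = PhosphoCorrelationResult(query_accession=query.accession)
    if query.sequence is None:
        result.classification = Support.NOT_SUPPORTED
        return result
    candidates = candidate_kinase_set(
        query, corpus.motifs, enforce_max_repeat=enforce_max_repeat)
    records = corpus.protein_map()
    scored: list[KinaseScore] = []
    for acc in sorted(candidates):
        kin = records.get(acc)
        if kin is None:
            warnings.warn(
                f"candidate kinase {acc!r} for {query.accession} not in "
                "corpus: skipped", stacklevel=2)
            continue
        scored.append(score_pair(query, kin, weights, coexpression_threshold))
    result.per_kinase = scored
    if scored:
        best = min(scored, key=lambda s: (-s.sk, s.kinase_accession))
        result.best_kinase = best.kinase_accession
        result.st, result.sl, result.sp, result.sk = (
            best.st, best.sl, best.sp, best.sk)
    result.classification = classify_phospho(
        result, mode, strong_cutoff, suggestive_cutoff)
    return result
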