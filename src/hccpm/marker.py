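"""Pathway-evidence scoring of HCC-marker potential.

A gene already confirmed as HCC-associated scores ``Sc = 10`` (small-scale
wet-lab evidence, tier E1) or ``Sc = 8`` (large-scale microarray/proteomic
evidence, tier E2) in every pathway containing it.  An unconfirmed gene is
scored per pathway from the evidence carried by the *other* genes of the
same pathway (OGSPs):

    Sc = W1 * (Ne + 0.8*Nm) / Np + W2      if Ne >= 1
    Sc = W2 * Nm / Np                      if Ne = 0 and Nm >= 1
    Sc = 0                                 otherwise

where Ne and Nm count OGSPs with E1 and E2 evidence, Np counts all OGSPs,
and W1 = 5, W2 = 3 — chosen so that an unconfirmed gene saturates at
Sc = 8 (an all-E1 pathway) and an all-E2 pathway gives exactly Sc = 3.

Across the pathways containing the gene, scores are combined as a weighted
mean Scm = sum(Sc * W(Sc)) / sum(W(Sc)) with the step weights
W(10) = 10, W(8) = 8, W(Sc) = 5 for 5 <= Sc < 8 and 3 for Sc < 5, so that
confident pathways dominate.  Classification: Scm >= 4.25 (one quarter of a
pathway E1-confirmed) is strongly suggestive, Scm >= 3 suggestive,
otherwise not supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .core import HccEvidence, ProteinRecord, Support

SCM_STRONG = 4.25
SCM_SUGGESTIVE = 3.0
W1_DEFAULT = 5.0
W2_DEFAULT = 3.0


@dataclass
class PathwayGeneSet:
    """A named pathway with its member gene/protein identifiers."""

    pathway_id: str
    name: str = ""
    members: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class PathwayEvidenceCounts:
    """Evidence tally over a pathway's OGSPs (members minus the query)."""

    np_: int
    ne: int
    nm: int

    def __post_init__(self) -> None:
        if self.ne < 0 or self.nm < 0 or self.np_ < 0:
            raise ValueError("counts must be non-negative")
        if self.ne + self.nm > self.np_:
            raise ValueError("Ne + Nm cannot exceed Np")


def count_pathway_evidence(
    query_accession: str,
    pathway: PathwayGeneSet,
    evidence_of: Callable[[str], HccEvidence],
) -> PathwayEvidenceCounts:
    """Tally E1/E2 evidence over the pathway members other than the query."""
    others = pathway.members - {query_accession}
    ne = sum(1 for m in others if evidence_of(m) == HccEvidence.E1)
    nm = sum(1 for m in others if evidence_of(m) == HccEvidence.E2)
    return PathwayEvidenceCounts(np_=len(others), ne=ne, nm=nm)


def pathway_score(
    query_evidence: HccEvidence,
    counts: PathwayEvidenceCounts,
    w1: float = W1_DEFAULT,
    w2: float = W2_DEFAULT,
) -> float:
    """Per-pathway marker score ``Sc`` (see module docstring)."""
    if query_evidence == HccEvidence.E1:
        return 10.0
    if query_evidence == HccEvidence.E2:
        return 8.0
    if counts.np_ == 0:
        raise ValueError("pathway has no OGSPs; skip it for unconfirmed genes")
    if counts.ne >= 1:
        return w1 * (counts.ne + 0.8 * counts.nm) / counts.np_ + w2
    if counts.nm >= 1:
        return w2 * counts.nm / counts.np_
    return 0.0


def pathway_weight(sc: float, tol: float = 1e-9) -> float:
    """Step weight ``W(Sc)``: 10 at Sc=10, 8 at Sc=8, 5 on [5, 8), else 3.

    Scores in the open interval (8, 10) cannot arise from the scoring rules
    (the unconfirmed maximum is exactly 8); they are weighted 5 by extending
    the middle band upward.
    """
    if abs(sc - 10.0) <= tol:
        return 10.0
    if abs(sc - 8.0) <= tol:
        return 8.0
    if sc >= 5.0:
        return 5.0
    return 3.0


@dataclass(frozen=True)
class PathwayScore:
    """One pathway's contribution to a gene's marker evaluation."""

    pathway_id: str
    counts: PathwayEvidenceCounts
    sc: float
    weight: float

    def __iter__(self):
        # unpack as (pathway_id, sc, weight) for convenience
        return iter((self.pathway_id, self.sc, self.weight))


@dataclass
class MarkerEvaluationResult:
    accession: str
    per_pathway: list[PathwayScore] = field(default_factory=list)
    scm: float = 0.0
    classification: Support = Support.NOT_SUPPORTED
    known_marker: bool = False


def classify_marker(
    scm: float,
    n_pathways: int,
    strong_cutoff: float = SCM_STRONG,
    suggestive_cutoff: float = SCM_SUGGESTIVE,
) -> Support:
    if n_pathways == 0:
        return Support.NOT_SUPPORTED
    if scm >= strong_cutoff:
        return Support.STRONGLY_SUGGESTIVE
    if scm >= suggestive_cutoff:
        return Support.SUGGESTIVE
    return Support.NOT_SUPPORTED


def marker_score(
    query: ProteinRecord,
    pathways: Iterable[PathwayGeneSet],
    evidence_of: Optional[Callable[[str], HccEvidence]] = None,
    w1: float = W1_DEFAULT,
    w2: float = W2_DEFAULT,
    strong_cutoff: float = SCM_STRONG,
    suggestive_cutoff: float = SCM_SUGGESTIVE,
) -> MarkerEvaluationResult:
    """Evaluate one gene over every pathway containing it.

    ``evidence_of`` maps any member accession to its HCC evidence tier;
    it must cover all OGSPs (unknown members default to no evidence).
    A gene outside every pathway is NOT_SUPPORTED with an empty breakdown.
    """
    if evidence_of is None:
        evidence_of = lambda _: HccEvidence.NONE  # noqa: E731
    result = MarkerEvaluationResult(
        accession=query.accession,
        known_marker=query.hcc_evidence in (HccEvidence.E1, HccEvidence.E2),
    )
    for pw in pathways:
        if query.accession not in pw.members:
            continue
        counts = count_pathway_evidence(query.accession, pw, evidence_of)
        try:
            sc = pathway_score(query.hcc_evidence, counts, w1, w2)
        except ValueError:
            warnings.warn(
                f"pathway {pw.pathway_id} has no OGSPs for "
                f"{query.accession}: skipped", stacklevel=2)
            continue
        result.per_pathway.append(
            PathwayScore(pw.pathway_id, counts, sc, pathway_weight(sc)))
    if result.per_pathway:
        num = sum(p.sc * p.weight for p in result.per_pathway)
        den = sum(p.weight for p in result.per_pathway)
        result.scm = num / den
    result.classification = classify_marker(
        result.scm, len(result.per_pathway), strong_cutoff, suggestive_cutoff)
    return result
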