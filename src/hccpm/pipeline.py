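"""Combined HCCPM classification, drug-target joining, and summaries.

A gene is a *strongly suggestive* phosphorylated HCC marker (HCCPM) when it
is strongly suggestive in both the kinase-correlation analysis and the
pathway-evidence marker evaluation; *not supported* when both systems say
not supported; and *suggestive* in every mixed case.  Drug-target rows are
joined by accession and tallied per category (liver-cancer, other-cancer,
non-cancer drugs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .core import Corpus, HccEvidence, ProteinRecord, Support
from .marker import (
    SCM_STRONG,
    SCM_SUGGESTIVE,
    MarkerEvaluationResult,
    marker_score,
)
from .phospho import (
    ClassificationMode,
    DEFAULT_WEIGHTS,
    SK_STRONG,
    SK_SUGGESTIVE,
    PhosphoCorrelationResult,
    PhosphoWeights,
    score_protein,
)


class DrugCategory(str, Enum):
    LIVER_CANCER = "LIVER_CANCER"
    CANCER = "CANCER"
    NON_CANCER = "NON_CANCER"


@dataclass(frozen=True)
class DrugTarget:
    drug_id: str
    drug_name: str
    category: DrugCategory
    target_accession: str


@dataclass
class HccpmResult:
    accession: str
    phospho: PhosphoCorrelationResult
    marker: MarkerEvaluationResult
    hccpm_class: Support
    drugs: list[DrugTarget] = field(default_factory=list)
    drug_counts: Counter = field(default_factory=Counter)

    @property
    def sk(self) -> float:
        return self.phospho.sk

    @property
    def scm(self) -> float:
        return self.marker.scm


def classify_hccpm(phospho_class: Support, marker_class: Support) -> Support:
    """Combine the two per-system classes into the HCCPM class."""
    strong = Support.STRONGLY_SUGGESTIVE
    absent = Support.NOT_SUPPORTED
    if phospho_class == strong and marker_class == strong:
        return strong
    if phospho_class == absent and marker_class == absent:
        return absent
    return Support.SUGGESTIVE


def join_drugs(
    accession: str, drug_table: Iterable[DrugTarget]
) -> tuple[list[DrugTarget], Counter]:
    """All drug rows targeting ``accession``, plus counts per category."""
    rows = [d for d in drug_table if d.target_accession == accession]
    counts = Counter(d.category for d in rows)
    for cat in DrugCategory:
        counts.setdefault(cat, 0)
    return rows, counts


def candidate_accessions(corpus: Corpus) -> list[str]:
    """The candidate set: union of pathway members present in the corpus.

    Mirrors the construction of the marker candidate list — every gene of
    every disease-related pathway is a candidate, including the already
    confirmed markers.
    """
    known = set(corpus.protein_map())
    members: set[str] = set()
    for pw in corpus.pathways:
        members |= pw.members
    return sorted(members & known)


def evaluate_corpus(
    corpus: Corpus,
    candidates: Optional[Sequence[str]] = None,
    weights: PhosphoWeights = DEFAULT_WEIGHTS,
    coexpression_threshold: float = 0.0,
    mode: ClassificationMode = ClassificationMode.CRITERIA,
    enforce_max_repeat: bool = False,
    sk_strong: float = SK_STRONG,
    sk_suggestive: float = SK_SUGGESTIVE,
    scm_strong: float = SCM_STRONG,
    scm_suggestive: float = SCM_SUGGESTIVE,
) -> list[HccpmResult]:
    """Run phospho scoring, marker scoring, HCCPM call and drug join."""
    if candidates is None:
        candidates = candidate_accessions(corpus)
    records = corpus.protein_map()
    evidence_of = lambda acc: (  # noqa: E731
        records[acc].hcc_evidence if acc in records else HccEvidence.NONE)
    by_member: dict[str, list] = {}
    for pw in corpus.pathways:
        for m in pw.members:
            by_member.setdefault(m, []).append(pw)
    by_target: dict[str, list[DrugTarget]] = {}
    for d in corpus.drugs:
        by_target.setdefault(d.target_accession, []).append(d)
    results: list[HccpmResult] = []
    for acc in candidates:
        rec = records[acc]
        ph = score_protein(
            rec, corpus, weights, coexpression_threshold, mode,
            enforce_max_repeat, sk_strong, sk_suggestive)
        mk = marker_score(rec, by_member.get(acc, []), evidence_of,
                          strong_cutoff=scm_strong,
                          suggestive_cutoff=scm_suggestive)
        drugs, counts = join_drugs(acc, by_target.get(acc, []))
        results.append(HccpmResult(
            accession=acc,
            phospho=ph,
            marker=mk,
            hccpm_class=classify_hccpm(ph.classification, mk.classification),
            drugs=drugs,
            drug_counts=counts,
        ))
    return results


def class_counts(classes: Iterable[Support]) -> dict[Support, int]:
    counts = Counter(classes)
    return {s: counts.get(s, 0) for s in Support}


def supported_fraction(counts: dict[Support, int]) -> float:
    """Percent of candidates classified suggestive or better."""
    total = sum(counts.values())
    if total == 0:
        return 0.0
    supported = (counts[Support.STRONGLY_SUGGESTIVE]
                 + counts[Support.SUGGESTIVE])
    return 100.0 * supported / total


def summarize(results: Sequence[HccpmResult]) -> dict:
    """Corpus-level class counts for all three systems plus drug coverage.

    Each per-system triple of counts sums to the candidate count; drug
    coverage counts genes with at least one drug in each category.
    """
    phospho = class_counts(r.phospho.classification for r in results)
    marker = class_counts(r.marker.classification for r in results)
    hccpm = class_counts(r.hccpm_class for r in results)
    coverage = {
        cat: sum(1 for r in results if r.drug_counts.get(cat, 0) > 0)
        for cat in DrugCategory
    }
    return {
        "n_candidates": len(results),
        "phospho": phospho,
        "marker": marker,
        "hccpm": hccpm,
        "phospho_supported_pct": supported_fraction(phospho),
        "drug_coverage": coverage,
    }
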