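"""Shared domain types for HCC biomarker prediction.

The prediction system reasons over a *corpus*: protein records carrying
tissue-expression evidence, GO cellular-component annotations, UniProt-style
subcellular-localization categories, hepatocellular-carcinoma (HCC) evidence
tiers, and optional cell-cycle expression profiles; plus motif definitions,
pathway gene sets, and a drug–target table.

Evidence tiers
--------------
* Tissue (``T1``/``T2``/``T3``/``ABSENT``): protein-level validation,
  mRNA-level validation, sequence-origin only, or not expressed in liver,
  blood or the lymphatic system.
* HCC (``E1``/``E2``/``NONE``): small-scale wet-lab confirmation,
  large-scale microarray/proteomic identification, or unconfirmed.
* GO evidence classes (``L1``–``L4``): experimental, computational,
  curatorial statement, automatically assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .cycle import CycleProfile
    from .marker import PathwayGeneSet
    from .pipeline import DrugTarget
    from .prosite import MotifDefinition

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PHOSPHOACCEPTORS = frozenset("STYH")
"""Residues accepted as phosphorylation sites (Ser, Thr, Tyr, His)."""


class Tissue(str, Enum):
    """Tissue-expression evidence tier (liver / blood / lymphatic system)."""

    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    ABSENT = "ABSENT"


class HccEvidence(str, Enum):
    """HCC-association evidence tier of a gene."""

    E1 = "E1"
    E2 = "E2"
    NONE = "NONE"


class EvidenceClass(str, Enum):
    """Credibility class of a GO annotation's evidence code."""

    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    L4 = "L4"


class Localization(str, Enum):
    """UniProt-style subcellular localization category."""

    SECRETED = "Secreted"
    CELL_MEMBRANE = "CellMembrane"
    ER_GOLGI = "ER_Golgi"
    MITOCHONDRION = "Mitochondrion"
    CYTOPLASM = "Cytoplasm"
    NUCLEUS = "Nucleus"


class Support(str, Enum):
    """Three-level classification used by all three scoring systems."""

    STRONGLY_SUGGESTIVE = "STRONGLY_SUGGESTIVE"
    SUGGESTIVE = "SUGGESTIVE"
    NOT_SUPPORTED = "NOT_SUPPORTED"


#: Default GO evidence-code -> class mapping, following the standard GO
#: evidence-code taxonomy: experimental codes are L1, computational-analysis
#: codes L2, curatorial statements L3, automatic assignments L4.
DEFAULT_EVIDENCE_CLASSES: dict[str, EvidenceClass] = {
    **{c: EvidenceClass.L1 for c in
       ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP")},
    **{c: EvidenceClass.L2 for c in
       ("ISS", "ISO", "ISA", "ISM", "IGC", "IBA",
        "IBD", "IKR", "IRD", "RCA")},
    **{c: EvidenceClass.L3 for c in ("TAS", "NAS", "IC")},
    **{c: EvidenceClass.L4 for c in ("IEA", "ND")},
}


def map_evidence_code(
    code: str,
    mapping: Optional[Mapping[str, EvidenceClass]] = None,
) -> EvidenceClass:
    """Map a GO evidence code (e.g. ``IDA``) to its class ``L1``–``L4``.

    Unknown codes fall back to ``L4`` (the most conservative class) with a
    warning, so the mapping is total over any input.
    """
    if not code:
        raise ValueError("evidence code must be a non-empty token")
    table = DEFAULT_EVIDENCE_CLASSES if mapping is None else mapping
    cls = table.get(code.upper())
    if cls is None:
        warnings.warn(
            f"unknown GO evidence code {code!r}: classified as L4",
            stacklevel=2,
        )
        return EvidenceClass.L4
    return EvidenceClass(cls)


@dataclass
class ProteinRecord:
    """A protein/gene with the annotations the scoring systems consume."""

    accession: str
    gene_id: Optional[str] = None
    gene_symbol: Optional[str] = None
    sequence: Optional[str] = None
    tissue_evidence: Tissue = Tissue.ABSENT
    hcc_evidence: HccEvidence = HccEvidence.NONE
    go_cc_annotations: set[tuple[str, EvidenceClass]] = field(default_factory=set)
    localization_categories: set[Localization] = field(default_factory=set)
    cycle_profile: Optional["CycleProfile"] = None
    is_kinase: bool = False

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()

    def invalid_residues(self) -> set[str]:
        if self.sequence is None:
            return set()
        return set(self.sequence) - AMINO_ACIDS

    def best_class_per_term(self) -> dict[str, EvidenceClass]:
        """Most credible (lowest L) evidence class for each annotated GO term."""
        order = [EvidenceClass.L1, EvidenceClass.L2, EvidenceClass.L3, EvidenceClass.L4]
        best: dict[str, EvidenceClass] = {}
        for term, cls in self.go_cc_annotations:
            if term not in best or order.index(cls) < order.index(best[term]):
                best[term] = cls
        return best


@dataclass
class Corpus:
    """All inputs of one prediction run, cross-referenced by accession."""

    proteins: list[ProteinRecord] = field(default_factory=list)
    motifs: list["MotifDefinition"] = field(default_factory=list)
    pathways: list["PathwayGeneSet"] = field(default_factory=list)
    drugs: list["DrugTarget"] = field(default_factory=list)

    def protein_map(self) -> dict[str, ProteinRecord]:
        """Accession -> record index (first occurrence wins on duplicates)."""
        out: dict[str, ProteinRecord] = {}
        for rec in self.proteins:
            out.setdefault(rec.accession, rec)
        return out


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "ERROR" | "WARNING" | "INFO"
    location: str
    message: str


def validate_corpus(corpus: Corpus) -> list[ValidationIssue]:
    """Check corpus invariants; an empty report means the corpus is clean.

    Dangling cross-references and duplicate accessions are ERRORs; missing
    optional fields (sequence, profile) are INFO.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for rec in corpus.proteins:
        if rec.accession in seen:
            issues.append(ValidationIssue(
                "ERROR", f"protein:{rec.accession}", "duplicate accession"))
        seen.add(rec.accession)
        bad = rec.invalid_residues()
        if bad:
            issues.append(ValidationIssue(
                "ERROR", f"protein:{rec.accession}",
                f"non-standard residues in sequence: {sorted(bad)}"))
        if rec.sequence is None:
            issues.append(ValidationIssue(
                "INFO", f"protein:{rec.accession}",
                "no sequence: record cannot be motif-scanned"))
        if rec.cycle_profile is None:
            issues.append(ValidationIssue(
                "INFO", f"protein:{rec.accession}",
                "no cell-cycle profile: phase score will be 0"))
    accessions = seen
    for motif in corpus.motifs:
        for kin in sorted(motif.kinase_accessions):
            if kin not in accessions:
                issues.append(ValidationIssue(
                    "ERROR", f"motif:{motif.motif_id}",
                    f"kinase accession {kin!r} not in corpus"))
    for pw in corpus.pathways:
        for member in sorted(pw.members):
            if member not in accessions:
                issues.append(ValidationIssue(
                    "ERROR", f"pathway:{pw.pathway_id}",
                    f"member {member!r} not in corpus"))
    seen_pairs: set[tuple[str, str]] = set()
    for drug in corpus.drugs:
        key = (drug.drug_id, drug.target_accession)
        if key in seen_pairs:
            issues.append(ValidationIssue(
                "ERROR", f"drug:{drug.drug_id}",
                f"duplicate (drug, target) pair {key}"))
        seen_pairs.add(key)
        if drug.target_accession not in accessions:
            issues.append(ValidationIssue(
                "ERROR", f"drug:{drug.drug_id}",
                f"target {drug.target_accession!r} not in corpus"))
    return issues


def errors_only(issues: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    return [i for i in issues if i.severity == "ERROR"]
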