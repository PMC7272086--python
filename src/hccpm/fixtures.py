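"""Synthetic corpora with constructive ground truth.

The generator builds complete input corpora — protein records with planted
motif occurrences, evidence annotations, cell-cycle profiles, pathways with
controlled evidence composition, and a drug–target table — together with a
*ledger* of the scores and classifications every record should receive.

The ledger is computed constructively while planting (literal rule tables
local to this module, never calls into the scoring engine), so a pipeline
run compared against the ledger is a genuine oracle test rather than
self-confirmation.

Synthetic motifs and accessions carry no biological meaning.  Background
sequence is drawn from an alphabet disjoint from every non-wildcard motif
residue, so a planted occurrence is the *only* occurrence — accidental
matches are impossible by construction, which keeps the ledger exact.

Cycle profiles are half-period square waves (log2 ratio +a for 50 of the
100 grid points, -a elsewhere) at phases 0/25/50/75, so co-expression is
decidable from the planted phases alone: two profiles overlap unless they
are exactly antiphase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    Corpus,
    EvidenceClass,
    HccEvidence,
    Localization,
    ProteinRecord,
    Tissue,
)
from .cycle import CycleProfile
from .marker import PathwayGeneSet
from .pipeline import DrugCategory, DrugTarget
from .prosite import MotifDefinition, parse_pattern

#: Letters never used by any fixture motif element (wildcards aside), so
#: background never matches a motif.
BACKGROUND_ALPHABET = "AGLVNQFWI"

#: Synthetic fixture motifs (Prosite-style shapes; not curated content).
FIXTURE_MOTIFS: list[MotifDefinition] = [
    MotifDefinition("PM001", "[RK](2)-x-[ST]", site_offset=3,
                    kinase_accessions={"KIN01", "KIN02"},
                    description="synthetic basophilic-like Ser/Thr motif"),
    MotifDefinition("PM002", "[ST]-x(2)-[DE]", site_offset=0,
                    kinase_accessions={"KIN03"},
                    description="synthetic acidophilic-like Ser/Thr motif"),
    MotifDefinition("PM003", "H-x-[DE]", site_offset=0,
                    kinase_accessions={"KIN04", "KIN05"},
                    description="synthetic His-acceptor motif"),
    MotifDefinition("PM004", "[RK]-x-x-Y", site_offset=3,
                    kinase_accessions={"KIN06"},
                    description="synthetic Tyr-acceptor motif"),
    MotifDefinition("PM005", "M-x-C", site_offset=0, skip_flag=True,
                    kinase_accessions={"KIN01"},
                    description="synthetic skipped motif (never scanned)"),
]

KINASE_ACCESSIONS = ("KIN01", "KIN02", "KIN03", "KIN04", "KIN05", "KIN06")

_PROFILE_PHASES = (0, 25, 50, 75)
_PROFILE_HALF = 50  # grid points with positive log2 ratio


@dataclass
class FixtureConfig:
    """Composition of a generated corpus.

    Defaults emulate the real candidate corpus where its composition is
    known: about 7% of pathway genes carry small-scale (E1) and 3%
    large-scale (E2) HCC evidence, mirroring the 421 + 190 confirmed genes
    among 5955 candidates; the remaining proportions are plausible round
    figures chosen once for coverage of every scoring branch.
    """

    seed: int
    n_candidates: int = 1000
    tissue_mix: dict[Tissue, float] = field(default_factory=lambda: {
        Tissue.T1: 0.45, Tissue.T2: 0.30, Tissue.T3: 0.15,
        Tissue.ABSENT: 0.10,
    })
    e1_fraction: float = 0.07
    e2_fraction: float = 0.03
    p_motif: float = 0.85          # probability a query carries a motif
    go_sharing: float = 0.6        # probability a query shares a kinase's GO term
    class_mix: dict[EvidenceClass, float] = field(default_factory=lambda: {
        EvidenceClass.L1: 0.40, EvidenceClass.L2: 0.25,
        EvidenceClass.L3: 0.20, EvidenceClass.L4: 0.15,
    })
    p_profile: float = 0.6
    p_drug: float = 0.3
    pathway_range: tuple[int, int] = (1, 3)
    ogsp_range: tuple[int, int] = (3, 8)
    ogsp_e1: float = 0.25
    ogsp_e2: float = 0.35
    sequence_length: int = 60

    def validate(self) -> None:
        for name, mix in (("tissue_mix", self.tissue_mix),
                          ("class_mix", self.class_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} proportions must be >= 0 and sum to 1")
        if not (0 <= self.e1_fraction and 0 <= self.e2_fraction
                and self.e1_fraction + self.e2_fraction <= 1):
            raise ValueError("e1_fraction + e2_fraction must lie in [0, 1]")
        for name, p in (("p_motif", self.p_motif),
                        ("go_sharing", self.go_sharing),
                        ("p_profile", self.p_profile),
                        ("p_drug", self.p_drug),
                        ("ogsp_e1", self.ogsp_e1), ("ogsp_e2", self.ogsp_e2)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ogsp_e1 + self.ogsp_e2 > 1:
            raise ValueError("ogsp_e1 + ogsp_e2 must not exceed 1")


# ---------------------------------------------------------------------------
# Constructive rule tables (deliberately duplicated from the scoring engine
# so the ledger is an independent oracle).
# ---------------------------------------------------------------------------

_T_RANK = {Tissue.T1: 0, Tissue.T2: 1, Tissue.T3: 2}
_T_VALUE = {Tissue.T1: 10.0, Tissue.T2: 6.0, Tissue.T3: 2.0}
_L_RANK = {EvidenceClass.L1: 0, EvidenceClass.L2: 1,
           EvidenceClass.L3: 2, EvidenceClass.L4: 3}
_L_VALUE = {EvidenceClass.L1: 10.0, EvidenceClass.L2: 8.0,
            EvidenceClass.L3: 4.0, EvidenceClass.L4: 2.0}


def _expected_st(a: Tissue, b: Tissue) -> float:
    if a == Tissue.ABSENT or b == Tissue.ABSENT:
        return 0.0
    return _T_VALUE[max(a, b, key=_T_RANK.__getitem__)]


def _expected_sl(shared_class_pairs: list[tuple[EvidenceClass, EvidenceClass]],
                 share_category: bool) -> float:
    layer1 = 0.0
    for qa, ka in shared_class_pairs:
        worst = max(qa, ka, key=_L_RANK.__getitem__)
        layer1 = max(layer1, _L_VALUE[worst])
    if layer1 >= 8:
        return layer1
    if share_category:
        return max(layer1, 6.0)
    return layer1


def _expected_sp(q_phase: Optional[int], k_phase: Optional[int]) -> float:
    if q_phase is None or k_phase is None:
        return 0.0
    q = np.zeros(100, dtype=bool)
    k = np.zeros(100, dtype=bool)
    for t in range(100):
        q[t] = (t - q_phase) % 100 < _PROFILE_HALF
        k[t] = (t - k_phase) % 100 < _PROFILE_HALF
    return 10.0 if bool(np.any(q & k)) else 0.0


def _expected_sk(st: float, sl: float, sp: float) -> float:
    return (5.0 * st + 3.0 * sl + 2.0 * sp) / 10.0


def _expected_phospho_class(st: float, sl: float, sp: float,
                            has_candidates: bool) -> str:
    if not has_candidates:
        return "NOT_SUPPORTED"
    if st >= 6 and sl >= 6:
        return "STRONGLY_SUGGESTIVE" if sp == 10 else "SUGGESTIVE"
    return "NOT_SUPPORTED"


def _expected_sc(evidence: HccEvidence, np_: int, ne: int, nm: int) -> float:
    if evidence == HccEvidence.E1:
        return 10.0
    if evidence == HccEvidence.E2:
        return 8.0
    if ne >= 1:
        return 5.0 * (ne + 0.8 * nm) / np_ + 3.0
    if nm >= 1:
        return 3.0 * nm / np_
    return 0.0


def _expected_weight(sc: float) -> float:
    if sc == 10.0:
        return 10.0
    if sc == 8.0:
        return 8.0
    if sc >= 5.0:
        return 5.0
    return 3.0


def _expected_marker_class(scm: float, n_pathways: int) -> str:
    if n_pathways == 0:
        return "NOT_SUPPORTED"
    if scm >= 4.25:
        return "STRONGLY_SUGGESTIVE"
    if scm >= 3.0:
        return "SUGGESTIVE"
    return "NOT_SUPPORTED"


def _expected_hccpm(pc: str, mc: str) -> str:
    if pc == "STRONGLY_SUGGESTIVE" and mc == "STRONGLY_SUGGESTIVE":
        return "STRONGLY_SUGGESTIVE"
    if pc == "NOT_SUPPORTED" and mc == "NOT_SUPPORTED":
        return "NOT_SUPPORTED"
    return "SUGGESTIVE"


# ---------------------------------------------------------------------------
# Planting primitives
# ---------------------------------------------------------------------------

def _square_profile(accession: str, phase: int,
                    amplitude: float) -> CycleProfile:
    points = [
        (float(t),
         amplitude if (t - phase) % 100 < _PROFILE_HALF else -amplitude)
        for t in range(100)
    ]
    return CycleProfile.from_points(accession, points)


def plant_motif(
    sequence_length: int,
    pattern: str,
    position: int,
    rng: np.random.Generator,
    site_offset: Optional[int] = None,
) -> str:
    """Background sequence with one guaranteed motif occurrence.

    ``position`` is the 1-based start of the planted occurrence.  Elements
    are realized at their minimal repeat length; when ``site_offset`` is
    given, the residue at that slot is chosen from the phosphoacceptors
    S/T/Y/H allowed by the element (error if none is allowed).  With the
    module's background alphabet and fixture motifs, the planted occurrence
    is provably the only one.
    """
    ast = parse_pattern(pattern)
    min_len = ast.min_length
    if position < 1 or position + min_len - 1 > sequence_length:
        raise ValueError(
            f"cannot plant pattern of length {min_len} at position "
            f"{position} in a sequence of length {sequence_length}")
    if ast.anchor_n and position != 1:
        raise ValueError("N-terminal-anchored pattern must be planted at 1")
    if ast.anchor_c and position + min_len - 1 != sequence_length:
        raise ValueError("C-terminal-anchored pattern must end the sequence")
    bg = list(BACKGROUND_ALPHABET)
    seq = [str(rng.choice(bg)) for _ in range(sequence_length)]
    slot = 0
    for el in ast.elements:
        for _ in range(el.min_rep):
            if el.kind == "wildcard":
                allowed = set(bg)
            elif el.kind == "negated":
                allowed = set(bg) - el.residues
            else:
                allowed = set(el.residues)
            if site_offset is not None and slot == site_offset:
                acceptors = allowed & set("STYH")
                if not acceptors:
                    raise ValueError(
                        f"site slot {site_offset} of {pattern!r} cannot hold "
                        "a phosphoacceptor residue")
                allowed = acceptors
            if not allowed:
                raise ValueError(
                    f"element {el} admits no residue under the fixture "
                    "background alphabet")
            seq[position - 1 + slot] = str(rng.choice(sorted(allowed)))
            slot += 1
    return "".join(seq)


def make_pathway(
    np_others: int,
    ne: int,
    nm: int,
    seed: int,
    pathway_id: str = "PWFIX",
    query_accession: str = "QFIX",
) -> tuple[PathwayGeneSet, list[ProteinRecord]]:
    """A pathway holding one unconfirmed query plus controlled OGSPs.

    Exactly ``ne`` of the ``np_others`` other members carry E1 evidence and
    ``nm`` carry E2; the rest are unconfirmed.
    """
    if ne < 0 or nm < 0 or ne + nm > np_others:
        raise ValueError("need ne, nm >= 0 and ne + nm <= np_others")
    rng = np.random.default_rng(seed)
    records = [ProteinRecord(accession=query_accession)]
    tiers = ([HccEvidence.E1] * ne + [HccEvidence.E2] * nm
             + [HccEvidence.NONE] * (np_others - ne - nm))
    rng.shuffle(tiers)
    for j, tier in enumerate(tiers):
        records.append(ProteinRecord(
            accession=f"{pathway_id}_OG{j:03d}", hcc_evidence=tier))
    pathway = PathwayGeneSet(
        pathway_id=pathway_id,
        name=f"synthetic pathway {pathway_id}",
        members={r.accession for r in records},
    )
    return pathway, records


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, mix: dict) -> object:
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def make_corpus(
    config: FixtureConfig,
) -> tuple[Corpus, pd.DataFrame, pd.DataFrame]:
    """Generate a corpus plus its constructive ground-truth ledgers.

    Returns ``(corpus, ledger, pathway_ledger)``.  ``ledger`` has one row
    per candidate query with the expected best-kinase components, Sk, Scm,
    the three classifications and drug counts; ``pathway_ledger`` has one
    row per (query, pathway) with the expected evidence counts, Sc and
    weight.  Identical seeds give identical corpora.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scannable = [m for m in FIXTURE_MOTIFS if not m.skip_flag]

    # -- global kinase records ------------------------------------------------
    kinases: dict[str, ProteinRecord] = {}
    kin_term: dict[str, tuple[str, EvidenceClass]] = {}
    kin_phase: dict[str, Optional[int]] = {}
    all_cats = list(Localization)
    for acc in KINASE_ACCESSIONS:
        tissue = _choice(rng, config.tissue_mix)
        term = f"GO:{acc}"
        cls = _choice(rng, config.class_mix)
        cats = {all_cats[i] for i in rng.choice(6, size=int(rng.integers(1, 3)),
                                                replace=False)}
        phase: Optional[int] = None
        profile = None
        if rng.random() < config.p_profile:
            phase = int(rng.choice(_PROFILE_PHASES))
            profile = _square_profile(acc, phase,
                                      float(rng.uniform(0.5, 2.0)))
        kinases[acc] = ProteinRecord(
            accession=acc,
            tissue_evidence=tissue,
            go_cc_annotations={(term, cls)},
            localization_categories=cats,
            cycle_profile=profile,
            is_kinase=True,
        )
        kin_term[acc] = (term, cls)
        kin_phase[acc] = phase

    proteins: list[ProteinRecord] = list(kinases.values())
    pathways: list[PathwayGeneSet] = []
    drugs: list[DrugTarget] = []
    ledger_rows: list[dict] = []
    pathway_rows: list[dict] = []
    drug_counter = 0

    for i in range(config.n_candidates):
        acc = f"Q{i:05d}"
        tissue = _choice(rng, config.tissue_mix)
        u = rng.random()
        if u < config.e1_fraction:
            evidence = HccEvidence.E1
        elif u < config.e1_fraction + config.e2_fraction:
            evidence = HccEvidence.E2
        else:
            evidence = HccEvidence.NONE

        # --- sequence with at most one planted motif -------------------------
        motif: Optional[MotifDefinition] = None
        if rng.random() < config.p_motif:
            motif = scannable[int(rng.integers(len(scannable)))]
        if motif is not None:
            min_len = parse_pattern(motif.pattern).min_length
            pos = int(rng.integers(1, config.sequence_length - min_len + 2))
            sequence = plant_motif(
                config.sequence_length, motif.pattern, pos, rng,
                site_offset=motif.site_offset)
        else:
            sequence = "".join(
                str(rng.choice(list(BACKGROUND_ALPHABET)))
                for _ in range(config.sequence_length))

        # --- annotations ------------------------------------------------------
        go: set[tuple[str, EvidenceClass]] = {
            (f"GO:P{i:05d}", _choice(rng, config.class_mix))}
        shared_pairs: dict[str, tuple[EvidenceClass, EvidenceClass]] = {}
        if motif is not None:
            for kin_acc in sorted(motif.kinase_accessions):
                if rng.random() < config.go_sharing:
                    term, kin_cls = kin_term[kin_acc]
                    q_cls = _choice(rng, config.class_mix)
                    go.add((term, q_cls))
                    shared_pairs[kin_acc] = (q_cls, kin_cls)
        cats = {all_cats[i2] for i2 in rng.choice(
            6, size=int(rng.integers(1, 3)), replace=False)}
        phase: Optional[int] = None
        profile = None
        if rng.random() < config.p_profile:
            phase = int(rng.choice(_PROFILE_PHASES))
            profile = _square_profile(acc, phase,
                                      float(rng.uniform(0.5, 2.0)))
        proteins.append(ProteinRecord(
            accession=acc,
            gene_id=str(10000 + i),
            gene_symbol=f"GENE{i:05d}",
            sequence=sequence,
            tissue_evidence=tissue,
            hcc_evidence=evidence,
            go_cc_annotations=go,
            localization_categories=cats,
            cycle_profile=profile,
        ))

        # --- expected phospho outcome ----------------------------------------
        best = None  # (sk, kin_acc, st, sl, sp)
        if motif is not None:
            for kin_acc in sorted(motif.kinase_accessions):
                kin = kinases[kin_acc]
                st = _expected_st(tissue, kin.tissue_evidence)
                # shared terms: the kinase signature term when drawn; the
                # query's private term never collides.
                pairs = ([shared_pairs[kin_acc]]
                         if kin_acc in shared_pairs else [])
                sl = _expected_sl(
                    pairs, bool(cats & kin.localization_categories))
                sp = _expected_sp(phase, kin_phase[kin_acc])
                sk = _expected_sk(st, sl, sp)
                key = (-sk, kin_acc)
                if best is None or key < (-best[0], best[1]):
                    best = (sk, kin_acc, st, sl, sp)
        if best is not None:
            exp_sk, exp_kin, exp_st, exp_sl, exp_sp = best
        else:
            exp_sk, exp_kin, exp_st, exp_sl, exp_sp = 0.0, "", 0.0, 0.0, 0.0
        phospho_class = _expected_phospho_class(
            exp_st, exp_sl, exp_sp, best is not None)

        # --- pathways and expected marker outcome ----------------------------
        n_pw = int(rng.integers(config.pathway_range[0],
                                config.pathway_range[1] + 1))
        scs: list[float] = []
        for j in range(n_pw):
            np_others = int(rng.integers(config.ogsp_range[0],
                                         config.ogsp_range[1] + 1))
            ne = nm = 0
            members = {acc}
            for k in range(np_others):
                v = rng.random()
                if v < config.ogsp_e1:
                    tier = HccEvidence.E1
                    ne += 1
                elif v < config.ogsp_e1 + config.ogsp_e2:
                    tier = HccEvidence.E2
                    nm += 1
                else:
                    tier = HccEvidence.NONE
                og_acc = f"OG{i:05d}_{j}_{k:02d}"
                proteins.append(ProteinRecord(
                    accession=og_acc, hcc_evidence=tier))
                members.add(og_acc)
            pw_id = f"PW{i:05d}_{j}"
            pathways.append(PathwayGeneSet(
                pathway_id=pw_id,
                name=f"synthetic pathway {pw_id}",
                members=members,
            ))
            sc = _expected_sc(evidence, np_others, ne, nm)
            scs.append(sc)
            pathway_rows.append({
                "accession": acc, "pathway_id": pw_id,
                "np": np_others, "ne": ne, "nm": nm,
                "sc": sc, "weight": _expected_weight(sc),
            })
        weights = [_expected_weight(sc) for sc in scs]
        scm = (sum(sc * w for sc, w in zip(scs, weights)) / sum(weights)
               if scs else 0.0)
        marker_class = _expected_marker_class(scm, n_pw)

        # --- drugs ------------------------------------------------------------
        n_lc = n_ca = n_nc = 0
        if rng.random() < config.p_drug:
            for _ in range(int(rng.integers(1, 4))):
                cat = list(DrugCategory)[int(rng.integers(3))]
                drugs.append(DrugTarget(
                    drug_id=f"DB{drug_counter:05d}",
                    drug_name=f"compound-{drug_counter:05d}",
                    category=cat,
                    target_accession=acc,
                ))
                drug_counter += 1
                if cat == DrugCategory.LIVER_CANCER:
                    n_lc += 1
                elif cat == DrugCategory.CANCER:
                    n_ca += 1
                else:
                    n_nc += 1

        ledger_rows.append({
            "accession": acc,
            "best_kinase": exp_kin,
            "st": exp_st, "sl": exp_sl, "sp": exp_sp, "sk": exp_sk,
            "phospho_class": phospho_class,
            "n_pathways": n_pw,
            "scm": scm,
            "marker_class": marker_class,
            "hccpm_class": _expected_hccpm(phospho_class, marker_class),
            "n_liver_cancer_drugs": n_lc,
            "n_cancer_drugs": n_ca,
            "n_non_cancer_drugs": n_nc,
        })

    corpus = Corpus(
        proteins=proteins,
        motifs=list(FIXTURE_MOTIFS),
        pathways=pathways,
        drugs=drugs,
    )
    ledger = pd.DataFrame(ledger_rows)
    pathway_ledger = pd.DataFrame(pathway_rows)
    return corpus, ledger, pathway_ledger
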