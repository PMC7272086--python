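"""Readers, writers, run configuration, and pipeline orchestration.

All tabular interchange is tab-delimited UTF-8 with a header row (TSV keeps
free-text drug names unambiguous); pathways use the GMT gene-set format;
sequences use FASTA.  Scores are printed with 3 decimals but every
classification is computed on full precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AMINO_ACIDS,
    Corpus,
    EvidenceClass,
    HccEvidence,
    Localization,
    ProteinRecord,
    Tissue,
    errors_only,
    map_evidence_code,
    validate_corpus,
)
from .cycle import CycleProfile
from .marker import (
    SCM_STRONG,
    SCM_SUGGESTIVE,
    W1_DEFAULT,
    W2_DEFAULT,
    PathwayGeneSet,
)
from .phospho import (
    SK_STRONG,
    SK_SUGGESTIVE,
    ClassificationMode,
    PhosphoWeights,
)
from .pipeline import (
    DrugCategory,
    DrugTarget,
    HccpmResult,
    evaluate_corpus,
    summarize,
)
from .prosite import MotifDefinition

logger = logging.getLogger("hccpm")

PathLike = Union[str, Path]

#: Representative evidence code written for each class (round-trip support).
_CLASS_TO_CODE = {
    EvidenceClass.L1: "IDA",
    EvidenceClass.L2: "ISS",
    EvidenceClass.L3: "TAS",
    EvidenceClass.L4: "IEA",
}


class CorpusValidationError(RuntimeError):
    """Raised when validation ERRORs must abort a pipeline run."""

    def __init__(self, issues):
        self.issues = issues
        lines = "; ".join(f"{i.location}: {i.message}" for i in issues[:10])
        super().__init__(f"{len(issues)} validation error(s): {lines}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Accession -> sequence; accession is the first header token.

    Sequences are upper-cased; a single terminal ``*`` is stripped; records
    with non-standard residues are skipped with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = set(seq) - AMINO_ACIDS
        if bad:
            warnings.warn(
                f"FASTA record {rec.id}: non-standard residues "
                f"{sorted(bad)}; record skipped", stacklevel=2)
            continue
        out[rec.id] = seq
    return out


def write_fasta(sequences: dict[str, str], path: PathLike,
                width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sequences.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_annotations(path: PathLike) -> pd.DataFrame:
    """Per-protein annotation rows (evidence tiers, categories, kinase flag)."""
    df = _read_tsv(path)
    required = {"accession", "tissue_evidence", "hcc_evidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    return df


def read_go_annotations(
    path: PathLike, evidence_map=None
) -> dict[str, set[tuple[str, EvidenceClass]]]:
    df = _read_tsv(path)
    out: dict[str, set[tuple[str, EvidenceClass]]] = {}
    for row in df.itertuples(index=False):
        cls = map_evidence_code(row.evidence_code, evidence_map)
        out.setdefault(row.accession, set()).add((row.go_term_id, cls))
    return out


def read_motifs(path: PathLike) -> list[MotifDefinition]:
    df = _read_tsv(path)
    motifs = []
    for row in df.itertuples(index=False):
        kinases = {k for k in row.kinase_accessions.split(";") if k}
        motifs.append(MotifDefinition(
            motif_id=row.motif_id,
            pattern=row.pattern,
            site_offset=int(row.site_offset),
            max_repeat=int(row.max_repeat),
            skip_flag=row.skip_flag.strip().lower() in ("true", "1", "yes"),
            kinase_accessions=kinases,
            description=getattr(row, "description", ""),
        ))
    return motifs


def write_motifs(motifs: list[MotifDefinition], path: PathLike) -> None:
    pd.DataFrame([{
        "motif_id": m.motif_id,
        "pattern": m.pattern,
        "site_offset": m.site_offset,
        "max_repeat": m.max_repeat,
        "skip_flag": str(m.skip_flag).lower(),
        "kinase_accessions": ";".join(sorted(m.kinase_accessions)),
        "description": m.description,
    } for m in motifs]).to_csv(path, sep="\t", index=False)


def read_profiles(path: PathLike) -> dict[str, CycleProfile]:
    """Long-format profile TSV: accession, time_percent, log2_ratio."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, CycleProfile] = {}
    for acc, grp in df.groupby("accession", sort=True):
        points = list(zip(grp["time_percent"].astype(float),
                          grp["log2_ratio"].astype(float)))
        out[str(acc)] = CycleProfile.from_points(str(acc), points)
    return out


def write_profiles(profiles: dict[str, CycleProfile], path: PathLike) -> None:
    rows = [
        {"accession": acc, "time_percent": t, "log2_ratio": v}
        for acc in sorted(profiles)
        for t, v in profiles[acc].raw_points
    ]
    pd.DataFrame(rows, columns=["accession", "time_percent", "log2_ratio"]
                 ).to_csv(path, sep="\t", index=False)


def read_gmt(path: PathLike) -> list[PathwayGeneSet]:
    """GMT gene sets: id <tab> description <tab> member...; one per line."""
    pathways: list[PathwayGeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need at least "
                    "3 tab-separated fields")
            pw_id, name, *members = fields
            member_set = {m for m in members if m}
            if len(member_set) < len([m for m in members if m]):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate members "
                    "deduplicated", stacklevel=2)
            pathways.append(PathwayGeneSet(pw_id, name, member_set))
    return pathways


def write_gmt(pathways: list[PathwayGeneSet], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name,
                                *sorted(pw.members)]) + "\n")


def read_drugs(path: PathLike) -> list[DrugTarget]:
    df = _read_tsv(path)
    return [
        DrugTarget(
            drug_id=row.drug_id,
            drug_name=row.drug_name,
            category=DrugCategory(row.category),
            target_accession=row.target_accession,
        )
        for row in df.itertuples(index=False)
    ]


def write_drugs(drugs: list[DrugTarget], path: PathLike) -> None:
    pd.DataFrame([{
        "drug_id": d.drug_id,
        "drug_name": d.drug_name,
        "category": d.category.value,
        "target_accession": d.target_accession,
    } for d in drugs]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Corpus bundles
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "fasta": "sequences.fasta",
    "annotations": "annotations.tsv",
    "go": "go_annotations.tsv",
    "motifs": "motifs.tsv",
    "profiles": "profiles.tsv",
    "pathways": "pathways.gmt",
    "drugs": "drugs.tsv",
}


def write_corpus(corpus: Corpus, directory: PathLike) -> None:
    """Serialize a corpus as a complete input bundle under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sequences = {r.accession: r.sequence for r in corpus.proteins
                 if r.sequence is not None}
    write_fasta(sequences, directory / BUNDLE_FILES["fasta"])
    pd.DataFrame([{
        "accession": r.accession,
        "gene_id": r.gene_id or "",
        "gene_symbol": r.gene_symbol or "",
        "tissue_evidence": r.tissue_evidence.value,
        "hcc_evidence": r.hcc_evidence.value,
        "localization_categories": ";".join(
            sorted(c.value for c in r.localization_categories)),
        "is_kinase": str(r.is_kinase).lower(),
    } for r in corpus.proteins]).to_csv(
        directory / BUNDLE_FILES["annotations"], sep="\t", index=False)
    go_rows = [
        {"accession": r.accession, "go_term_id": term,
         "evidence_code": _CLASS_TO_CODE[cls]}
        for r in corpus.proteins
        for term, cls in sorted(r.go_cc_annotations)
    ]
    pd.DataFrame(go_rows, columns=["accession", "go_term_id", "evidence_code"]
                 ).to_csv(directory / BUNDLE_FILES["go"], sep="\t",
                          index=False)
    write_motifs(corpus.motifs, directory / BUNDLE_FILES["motifs"])
    profiles = {r.accession: r.cycle_profile for r in corpus.proteins
                if r.cycle_profile is not None}
    write_profiles(profiles, directory / BUNDLE_FILES["profiles"])
    write_gmt(corpus.pathways, directory / BUNDLE_FILES["pathways"])
    write_drugs(corpus.drugs, directory / BUNDLE_FILES["drugs"])


def load_corpus(directory: PathLike, evidence_map=None) -> Corpus:
    """Assemble a corpus from a bundle directory (see ``BUNDLE_FILES``)."""
    directory = Path(directory)
    sequences = read_fasta(directory / BUNDLE_FILES["fasta"]) \
        if (directory / BUNDLE_FILES["fasta"]).exists() else {}
    go = read_go_annotations(directory / BUNDLE_FILES["go"], evidence_map) \
        if (directory / BUNDLE_FILES["go"]).exists() else {}
    profiles = read_profiles(directory / BUNDLE_FILES["profiles"]) \
        if (directory / BUNDLE_FILES["profiles"]).exists() else {}
    ann = read_annotations(directory / BUNDLE_FILES["annotations"])
    proteins: list[ProteinRecord] = []
    for row in ann.itertuples(index=False):
        cats = {
            Localization(c) for c in row.localization_categories.split(";")
            if c
        } if getattr(row, "localization_categories", "") else set()
        proteins.append(ProteinRecord(
            accession=row.accession,
            gene_id=row.gene_id or None,
            gene_symbol=row.gene_symbol or None,
            sequence=sequences.get(row.accession),
            tissue_evidence=Tissue(row.tissue_evidence),
            hcc_evidence=HccEvidence(row.hcc_evidence),
            go_cc_annotations=go.get(row.accession, set()),
            localization_categories=cats,
            cycle_profile=profiles.get(row.accession),
            is_kinase=row.is_kinase.strip().lower() in ("true", "1", "yes"),
        ))
    motifs = read_motifs(directory / BUNDLE_FILES["motifs"]) \
        if (directory / BUNDLE_FILES["motifs"]).exists() else []
    pathways = read_gmt(directory / BUNDLE_FILES["pathways"]) \
        if (directory / BUNDLE_FILES["pathways"]).exists() else []
    drugs = read_drugs(directory / BUNDLE_FILES["drugs"]) \
        if (directory / BUNDLE_FILES["drugs"]).exists() else []
    return Corpus(proteins=proteins, motifs=motifs, pathways=pathways,
                  drugs=drugs)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run (YAML-serializable)."""

    wt: float = 5.0
    wl: float = 3.0
    wp: float = 2.0
    w1: float = W1_DEFAULT
    w2: float = W2_DEFAULT
    mode: str = ClassificationMode.CRITERIA.value
    coexpression_threshold: float = 0.0
    sk_strong: float = SK_STRONG
    sk_suggestive: float = SK_SUGGESTIVE
    scm_strong: float = SCM_STRONG
    scm_suggestive: float = SCM_SUGGESTIVE
    enforce_max_repeat: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sk_strong < self.sk_suggestive:
            raise ValueError("sk_strong must be >= sk_suggestive")
        if self.scm_strong < self.scm_suggestive:
            raise ValueError("scm_strong must be >= scm_suggestive")

    def weights(self) -> PhosphoWeights:
        return PhosphoWeights(self.wt, self.wl, self.wp)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Result tables and orchestration
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.3f}"


def results_to_frames(results: list[HccpmResult]) -> dict[str, pd.DataFrame]:
    phospho = pd.DataFrame([{
        "accession": r.accession,
        "best_kinase": r.phospho.best_kinase or "",
        "St": _fmt(r.phospho.st),
        "Sl": _fmt(r.phospho.sl),
        "Sp": _fmt(r.phospho.sp),
        "Sk": _fmt(r.phospho.sk),
        "classification": r.phospho.classification.value,
        "n_candidate_kinases": len(r.phospho.per_kinase),
    } for r in results])
    marker = pd.DataFrame([{
        "accession": r.accession,
        "n_pathways": len(r.marker.per_pathway),
        "Scm": _fmt(r.marker.scm),
        "classification": r.marker.classification.value,
        "known_marker": str(r.marker.known_marker).lower(),
    } for r in results])
    marker_pathways = pd.DataFrame([
        {"accession": r.accession, "pathway_id": p.pathway_id,
         "Np": p.counts.np_, "Ne": p.counts.ne, "Nm": p.counts.nm,
         "Sc": _fmt(p.sc), "weight": _fmt(p.weight)}
        for r in results for p in r.marker.per_pathway
    ], columns=["accession", "pathway_id", "Np", "Ne", "Nm", "Sc",
                "weight"])
    hccpm = pd.DataFrame([{
        "accession": r.accession,
        "Sk": _fmt(r.sk),
        "Scm": _fmt(r.scm),
        "phospho_class": r.phospho.classification.value,
        "marker_class": r.marker.classification.value,
        "hccpm_class": r.hccpm_class.value,
        "n_liver_cancer_drugs": r.drug_counts.get(
            DrugCategory.LIVER_CANCER, 0),
        "n_cancer_drugs": r.drug_counts.get(DrugCategory.CANCER, 0),
        "n_non_cancer_drugs": r.drug_counts.get(DrugCategory.NON_CANCER, 0),
    } for r in results])
    return {"phospho": phospho, "marker": marker,
            "marker_pathways": marker_pathways, "hccpm": hccpm}


def summary_frame(results: list[HccpmResult]) -> pd.DataFrame:
    s = summarize(results)
    rows = []
    for system in ("phospho", "marker", "hccpm"):
        for support, count in s[system].items():
            rows.append({"system": system, "class": support.value,
                         "count": count})
    for cat, count in s["drug_coverage"].items():
        rows.append({"system": "drug_coverage", "class": cat.value,
                     "count": count})
    rows.append({"system": "total", "class": "n_candidates",
                 "count": s["n_candidates"]})
    return pd.DataFrame(rows)


def run_pipeline(
    corpus: Corpus,
    config: Optional[RunConfig] = None,
    outdir: Optional[PathLike] = None,
) -> dict[str, pd.DataFrame]:
    """Validate, score, classify, join drugs, and summarize a corpus.

    Stage order: validation -> motif scan + phospho scoring -> marker
    scoring -> HCCPM combination -> drug join -> summary.  Validation
    ERRORs abort with :class:`CorpusValidationError`.  When ``outdir`` is
    given every table is written as TSV there.
    """
    config = config or RunConfig()
    issues = validate_corpus(corpus)
    errors = errors_only(issues)
    if errors:
        raise CorpusValidationError(errors)
    logger.info("corpus validated: %d proteins, %d motifs, %d pathways, "
                "%d drug rows", len(corpus.proteins), len(corpus.motifs),
                len(corpus.pathways), len(corpus.drugs))
    results = evaluate_corpus(
        corpus,
        weights=config.weights(),
        coexpression_threshold=config.coexpression_threshold,
        mode=ClassificationMode(config.mode),
        enforce_max_repeat=config.enforce_max_repeat,
        sk_strong=config.sk_strong,
        sk_suggestive=config.sk_suggestive,
        scm_strong=config.scm_strong,
        scm_suggestive=config.scm_suggestive,
    )
    frames = results_to_frames(results)
    frames["summary"] = summary_frame(results)
    logger.info("scored %d candidates", len(results))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return frames
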