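from __future__ import annotations

import pytest

from hccpm.core import (
    EvidenceClass,
    HccEvidence,
    Localization,
    ProteinRecord,
    Tissue,
)
from hccpm.cycle import CycleProfile


def square_profile(accession: str, phase: int, amplitude: float = 1.0,
                   half: int = 50) -> CycleProfile:
    """Square-wave log2 profile: +amplitude on [phase, phase+half) mod 100."""
    points = [
        (float(t), amplitude if (t - phase) % 100 < half else -amplitude)
        for t in range(100)
    ]
    return CycleProfile.from_points(accession, points)


def record(
    accession: str,
    sequence: str | None = None,
    tissue: Tissue = Tissue.T1,
    hcc: HccEvidence = HccEvidence.NONE,
    go: set[tuple[str, EvidenceClass]] | None = None,
    cats: set[Localization] | None = None,
    phase: int | None = None,
    is_kinase: bool = False,
) -> ProteinRecord:
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        tissue_evidence=tissue,
        hcc_evidence=hcc,
        go_cc_annotations=go or set(),
        localization_categories=cats or set(),
        cycle_profile=square_profile(accession, phase)
        if phase is not None else None,
        is_kinase=is_kinase,
    )


@pytest.fixture
def make_record():
    return record


@pytest.fixture
def make_profile():
    return square_profile
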