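"""Shared factories for the test suite."""
from __future__ import annotations

import pytest

from phyloprof.formats import ProteinHit, RnaHit, Strand, Truncation

_TRUNC = {
    "no": Truncation.NONE,
    "5'": Truncation.TRUNC5,
    "3'": Truncation.TRUNC3,
    "5'&3'": Truncation.BOTH,
    "none": Truncation.NONE,
    "trunc5": Truncation.TRUNC5,
    "trunc3": Truncation.TRUNC3,
    "both": Truncation.BOTH,
}


def make_rna_hit(
    bit: float,
    trunc: str = "none",
    assembly: str = "ASM_A",
    target: str | None = None,
    e_value: float = 1e-20,
    seq_from: int = 100,
    seq_to: int = 705,
    strand: Strand = Strand.PLUS,
) -> RnaHit:
    return RnaHit(
        target_seq_id=target or f"{assembly}|ctg1",
        assembly_id=assembly,
        model_name="ncRNA-marker",
        bit_score=bit,
        e_value=e_value,
        seq_from=seq_from,
        seq_to=seq_to,
        strand=strand,
        truncation=_TRUNC[trunc],
    )


def make_protein_hit(
    query: str = "q1",
    subject: str = "s1",
    assembly: str = "ASM_A",
    e_value: float = 1e-50,
    bit: float = 210.5,
    pident: float = 55.0,
) -> ProteinHit:
    return ProteinHit(
        query_id=query,
        subject_id=subject,
        subject_assembly_id=assembly,
        bit_score=bit,
        e_value=e_value,
        percent_identity=pident,
    )


@pytest.fixture
def rna_hit_factory():
    return make_rna_hit


@pytest.fixture
def protein_hit_factory():
    return make_protein_hit
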