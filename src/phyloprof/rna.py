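"""Bit-score classification of covariance-model RNA hits.

Hits to the ncRNA covariance model are triaged into three categories by
bit score and truncation state, using cutoffs read off the bit-score
histogram of the search:

* **full_length** — nontruncated, bit score >= 390.0;
* **variant1**    — nontruncated, 310.0 <= bit score < 390.0;
* **variant2**    — nontruncated with 235.0 <= bit score < 310.0, or any
  truncated hit with bit score >= 235.0;
* everything below 235.0 is **unclassified** and treated downstream as no
  ncRNA evidence.

Lower bounds are inclusive, upper bounds exclusive. Note the deliberate
consequence of the truncation rule: a truncated hit is variant2 no matter
how high it scores — truncated alignments cannot attest a full-length gene.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .formats import RnaHit, Truncation

__all__ = [
    "ClassificationThresholds",
    "RnaCategory",
    "AssemblyStatus",
    "AssemblyRnaStatus",
    "classify_hit",
    "assign_assembly_status",
    "call_statuses",
    "score_histogram",
]


@dataclass(frozen=True)
class ClassificationThresholds:
    """Bit-score cutoffs (bits) separating the RNA categories."""

    full_min: float = 390.0
    v1_min: float = 310.0
    v2_min: float = 235.0

    def __post_init__(self) -> None:
        if not (self.full_min > self.v1_min > self.v2_min > 0):
            raise ValueError(
                "thresholds must satisfy full_min > v1_min > v2_min > 0, got "
                f"{self.full_min} / {self.v1_min} / {self.v2_min}"
            )


class RnaCategory(str, Enum):
    FULL_LENGTH = "full_length"
    VARIANT1 = "variant1"
    VARIANT2 = "variant2"
    UNCLASSIFIED = "unclassified"


class AssemblyStatus(str, Enum):
    FULL_LENGTH = "full_length"
    VARIANT1 = "variant1"
    VARIANT2 = "variant2"
    ABSENT = "absent"


#: precedence used to break exact bit-score ties between categories
_CATEGORY_RANK = {
    RnaCategory.FULL_LENGTH: 0,
    RnaCategory.VARIANT1: 1,
    RnaCategory.VARIANT2: 2,
}


@dataclass(frozen=True)
class AssemblyRnaStatus:
    """The single per-assembly ncRNA call derived from all its hits."""

    assembly_id: str
    status: AssemblyStatus
    best_hit: RnaHit | None = None


def classify_hit(
    hit: RnaHit, thresholds: ClassificationThresholds = ClassificationThresholds()
) -> RnaCategory:
    """Assign a hit to exactly one category from (bit_score, truncation).

    Total on valid hits; e-value and coordinates never influence the call.
    """
    bits = hit.bit_score
    if hit.truncation is not Truncation.NONE:
        if bits >= thresholds.v2_min:
            return RnaCategory.VARIANT2
        return RnaCategory.UNCLASSIFIED
    if bits >= thresholds.full_min:
        return RnaCategory.FULL_LENGTH
    if bits >= thresholds.v1_min:
        return RnaCategory.VARIANT1
    if bits >= thresholds.v2_min:
        return RnaCategory.VARIANT2
    return RnaCategory.UNCLASSIFIED


def assign_assembly_status(
    hits: Sequence[RnaHit],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    assembly_id: str | None = None,
) -> AssemblyRnaStatus:
    """Resolve all hits of one assembly to a single status.

    Unclassified hits are dropped; with none remaining the status is
    ``absent``. Otherwise the status is the category of the best remaining
    hit — highest bit score, ties broken by category precedence
    (full_length > variant1 > variant2), then by target sequence id, so the
    call is deterministic and independent of input order.
    """
    ids = {h.assembly_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple assemblies: {sorted(ids)}")
    if assembly_id is None:
        if not ids:
            raise ValueError("assembly_id required when hits is empty")
        assembly_id = next(iter(ids))
    elif ids and next(iter(ids)) != assembly_id:
        raise ValueError(
            f"hits belong to {next(iter(ids))!r}, not {assembly_id!r}"
        )

    classified = [
        (h, cat)
        for h, cat in ((h, classify_hit(h, thresholds)) for h in hits)
        if cat is not RnaCategory.UNCLASSIFIED
    ]
    if not classified:
        return AssemblyRnaStatus(assembly_id, AssemblyStatus.ABSENT, None)
    best_hit, best_cat = min(
        classified,
        key=lambda hc: (-hc[0].bit_score, _CATEGORY_RANK[hc[1]], hc[0].target_seq_id),
    )
    return AssemblyRnaStatus(assembly_id, AssemblyStatus(best_cat.value), best_hit)


def call_statuses(
    hits: Iterable[RnaHit],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> dict[str, AssemblyRnaStatus]:
    """Group hits by assembly and call one status per assembly."""
    by_assembly: dict[str, list[RnaHit]] = defaultdict(list)
    for h in hits:
        by_assembly[h.assembly_id].append(h)
    return {
        asm: assign_assembly_status(grp, thresholds, assembly_id=asm)
        for asm, grp in sorted(by_assembly.items())
    }


def score_histogram(
    hits: Iterable[RnaHit],
    bin_width: float,
    truncated_separately: bool = False,
) -> Mapping[float, int] | tuple[Mapping[float, int], Mapping[float, int]]:
    """Histogram of hit bit scores with half-open bins [edge, edge + width).

    Returns a ``{bin lower edge: count}`` mapping, or with
    ``truncated_separately`` a ``(nontruncated, truncated)`` pair of such
    mappings. This is the histogram used to choose category cutoffs.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")

    def edge(score: float) -> float:
        import math

        return math.floor(score / bin_width) * bin_width

    if not truncated_separately:
        counts: dict[float, int] = defaultdict(int)
        for h in hits:
            counts[edge(h.bit_score)] += 1
        return dict(counts)
    nontrunc: dict[float, int] = defaultdict(int)
    trunc: dict[float, int] = defaultdict(int)
    for h in hits:
        target = nontrunc if h.truncation is Truncation.NONE else trunc
        target[edge(h.bit_score)] += 1
    return dict(nontrunc), dict(trunc)
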