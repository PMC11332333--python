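"""Cohort presence fractions and binary mutual information.

For each protein family, presence (>= 1 member) is crossed with marker
status over the two cohorts to give a 2×2 contingency table with cells
n_xy (x = marker present, y = family present). Two statistics summarise
the table:

* the fractional presence in each cohort,
  f_pos = n11/(n11 + n10) and f_neg = n01/(n01 + n00);
* the mutual information in bits,

      I(X;Y) = Σ_{x,y} p_xy · log2( p_xy / (p(x)·p(y)) ),

  with p_xy = n_xy/N and marginals p(x), p(y) from the cell sums.

Two zero-handling conventions are offered. ``discard`` (the default)
returns *undefined* whenever any logarithm operand is zero or undefined —
i.e. any empty cell kills the statistic; note this silences exactly the
perfect-association tables, which is a real trade-off. ``limit`` applies
the usual 0·log 0 = 0 convention so perfect association scores
min(H(X), H(Y)) bits. Families with undefined MI are kept (flagged and
ranked last), never dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .cohorts import CohortPartition
from .families import ParalogCounts, ProteinFamily

__all__ = [
    "JointCounts",
    "GroupFractions",
    "Direction",
    "ProfileResult",
    "joint_counts",
    "group_fractions",
    "mutual_information",
    "binary_entropy",
    "profile_families",
    "rank_profiles",
    "scatter_data",
    "violin_data",
]


@dataclass(frozen=True)
class JointCounts:
    """2×2 marker × family-presence contingency table.

    ``n_xy`` counts assemblies with marker status x and family presence y
    (1 = present, 0 = absent); excluded assemblies contribute to no cell.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def transpose(self) -> "JointCounts":
        """Swap the roles of X and Y (marker and family)."""
        return JointCounts(n00=self.n00, n01=self.n10, n10=self.n01, n11=self.n11)


@dataclass(frozen=True)
class GroupFractions:
    """Fraction of each cohort carrying >= 1 family member."""

    f_pos: float
    f_neg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_pos <= 1.0 and 0.0 <= self.f_neg <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")


class Direction(str, Enum):
    CORRELATED = "correlated"
    ANTICORRELATED = "anticorrelated"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class ProfileResult:
    family_id: str
    fractions: GroupFractions
    joint: JointCounts
    mi_bits: float | None
    direction: Direction
    rank: int = 0


def joint_counts(family: ProteinFamily, part: CohortPartition) -> JointCounts:
    """Cross family presence with marker status over the two cohorts.

    Excluded assemblies are invisible: members there contribute nothing.
    """
    if not part.positive or not part.negative:
        raise ValueError("both cohorts must be non-empty")
    present = family.assemblies
    n11 = len(part.positive & present)
    n01 = len(part.negative & present)
    return JointCounts(
        n00=len(part.negative) - n01,
        n01=n01,
        n10=len(part.positive) - n11,
        n11=n11,
    )


def group_fractions(jc: JointCounts) -> GroupFractions:
    n_pos = jc.n11 + jc.n10
    n_neg = jc.n01 + jc.n00
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both cohort sizes must be >= 1")
    return GroupFractions(f_pos=jc.n11 / n_pos, f_neg=jc.n01 / n_neg)


def mutual_information(jc: JointCounts, zero_mode: str = "discard") -> float | None:
    """Mutual information of the 2×2 table in bits (log base 2).

    Evaluated as the expanded four-term sum with marginals from the cell
    sums. ``zero_mode="discard"`` returns None if any cell probability (or
    marginal) is zero — the logarithm operand would be zero or undefined.
    ``zero_mode="limit"`` treats 0·log 0 as 0 and returns 0.0 when a
    marginal is degenerate.
    """
    if zero_mode not in ("discard", "limit"):
        raise ValueError(f"zero_mode must be 'discard' or 'limit', got {zero_mode!r}")
    n = jc.n
    if n == 0:
        raise ValueError("empty contingency table")
    p00, p01, p10, p11 = (c / n for c in (jc.n00, jc.n01, jc.n10, jc.n11))
    # marginals: x = marker (rows p0., p1.), y = family (columns p.0, p.1)
    px0, px1 = p00 + p01, p10 + p11
    py0, py1 = p00 + p10, p01 + p11
    terms = (
        (p00, px0 * py0),
        (p01, px0 * py1),
        (p10, px1 * py0),
        (p11, px1 * py1),
    )
    if zero_mode == "discard":
        if any(p == 0.0 for p, _ in terms):
            return None
        return sum(p * math.log2(p / denom) for p, denom in terms)
    total = 0.0
    for p, denom in terms:
        if p > 0.0:  # denom > 0 whenever p > 0
            total += p * math.log2(p / denom)
    # clip the tiny negative residue floating point can leave on
    # exactly-independent tables
    return max(total, 0.0)


def binary_entropy(p: float) -> float:
    """Shannon entropy in bits of a Bernoulli(p) variable."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def _direction(fr: GroupFractions) -> Direction:
    if fr.f_pos > fr.f_neg:
        return Direction.CORRELATED
    if fr.f_pos < fr.f_neg:
        return Direction.ANTICORRELATED
    return Direction.NEUTRAL


def profile_families(
    families: Sequence[ProteinFamily],
    part: CohortPartition,
    zero_mode: str = "discard",
) -> list[ProfileResult]:
    """Compute fractions, MI and direction per family, then rank."""
    results = []
    for fam in families:
        jc = joint_counts(fam, part)
        fr = group_fractions(jc)
        mi = mutual_information(jc, zero_mode=zero_mode)
        results.append(
            ProfileResult(
                family_id=fam.family_id,
                fractions=fr,
                joint=jc,
                mi_bits=mi,
                direction=_direction(fr),
            )
        )
    return rank_profiles(results)


def rank_profiles(results: Iterable[ProfileResult]) -> list[ProfileResult]:
    """Order by MI descending; undefined-MI entries go to the tail.

    Ties break by |f_pos − f_neg| descending, then family id, so ranking
    is deterministic.
    """

    def key(r: ProfileResult):
        gap = abs(r.fractions.f_pos - r.fractions.f_neg)
        undefined = r.mi_bits is None
        return (undefined, -(r.mi_bits or 0.0), -gap, r.family_id)

    ordered = sorted(results, key=key)
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def scatter_data(
    results: Sequence[ProfileResult],
) -> list[tuple[float, float, str]]:
    """(f_neg, f_pos, family_id) coordinates, one point per family."""
    return [
        (r.fractions.f_neg, r.fractions.f_pos, r.family_id) for r in results
    ]


def violin_data(
    pc: ParalogCounts, part: CohortPartition
) -> tuple[list[int], list[int]]:
    """Per-assembly paralog count multisets for each cohort.

    Returns ``(positive_counts, negative_counts)``; excluded assemblies
    are omitted and cohort assemblies missing from the count map count 0.
    """
    pos = sorted(pc.counts.get(asm, 0) for asm in part.positive)
    neg = sorted(pc.counts.get(asm, 0) for asm in part.negative)
    return pos, neg
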