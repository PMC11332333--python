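"""Protein-family construction and per-genome paralog counting.

A family is a named set of (assembly, protein) members, built one of three
ways:

* from reference-query homology hits — one family per query, members are
  all subjects at e-value <= 1e-10 (the cutoff that empirically separates
  likely homologs);
* from a cluster map — one family per cluster representative, clusters
  with fewer than five proteins discarded;
* from profile-HMM hits at a per-model bit-score floor.

Presence for profiling is "count >= 1"; the same member sets drive paralog
counting, so the two analyses cannot drift apart.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, Union

import pandas as pd

from .formats import ClusterMap, ProteinHit

__all__ = [
    "FamilyBuildParams",
    "ProteinFamily",
    "ParalogCounts",
    "families_from_reference_hits",
    "families_from_clusters",
    "family_from_hmm_hits",
    "count_paralogs",
    "presence_matrix_from_families",
]


@dataclass(frozen=True)
class FamilyBuildParams:
    """Filter settings for family construction.

    ``evalue_max`` and per-model ``hmm_bit_min`` cutoffs are inclusive,
    mirroring the upstream search tools' own filter semantics.
    """

    evalue_max: float = 1e-10
    min_cluster_size: int = 5
    hmm_bit_min: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError(f"evalue_max must be > 0, got {self.evalue_max}")
        if self.min_cluster_size < 1:
            raise ValueError(
                f"min_cluster_size must be >= 1, got {self.min_cluster_size}"
            )


@dataclass(frozen=True)
class ProteinFamily:
    """A named set of (assembly_id, protein_id) members."""

    family_id: str
    members: frozenset[tuple[str, str]]

    @property
    def assemblies(self) -> frozenset[str]:
        return frozenset(asm for asm, _ in self.members)


@dataclass(frozen=True)
class ParalogCounts:
    """Per-assembly member counts for one family (0 for non-carriers)."""

    family_id: str
    counts: Mapping[str, int]


def families_from_reference_hits(
    hits: Sequence[ProteinHit],
    params: FamilyBuildParams = FamilyBuildParams(),
) -> list[ProteinFamily]:
    """One family per distinct query id from reference-query hit tables.

    Members are the distinct (assembly, subject) pairs among hits passing
    the e-value cutoff; duplicate alignment records collapse. Queries whose
    hits all fail the cutoff are dropped with a warning. Output order is
    deterministic (sorted by family id) and independent of hit order.
    """
    by_query: dict[str, set[tuple[str, str]]] = {}
    for h in hits:
        members = by_query.setdefault(h.query_id, set())
        if h.e_value <= params.evalue_max:
            members.add((h.subject_assembly_id, h.subject_id))
    families: list[ProteinFamily] = []
    empty: list[str] = []
    for query in sorted(by_query):
        members = by_query[query]
        if members:
            families.append(ProteinFamily(query, frozenset(members)))
        else:
            empty.append(query)
    if empty:
        warnings.warn(
            f"{len(empty)} queries produced no hits at e-value <= "
            f"{params.evalue_max!r} and were dropped: {empty[:5]}...",
            stacklevel=2,
        )
    return families


def families_from_clusters(
    cmap: ClusterMap,
    protein_to_assembly: Union[Mapping[str, str], Callable[[str], str]],
    params: FamilyBuildParams = FamilyBuildParams(),
    on_unmapped: str = "error",
) -> tuple[list[ProteinFamily], list[str]]:
    """One family per cluster representative with enough members.

    Returns ``(families, discarded)`` where ``discarded`` lists the
    representatives of clusters smaller than ``min_cluster_size``. The size
    threshold applies to the protein count of the cluster, before assembly
    resolution.
    """
    if on_unmapped not in ("error", "skip"):
        raise ValueError(f"on_unmapped must be 'error' or 'skip', got {on_unmapped!r}")

    def resolve(protein: str) -> str | None:
        if callable(protein_to_assembly):
            return protein_to_assembly(protein)
        return protein_to_assembly.get(protein)

    families: list[ProteinFamily] = []
    discarded: list[str] = []
    for rep in sorted(cmap.assignments):
        proteins = cmap.assignments[rep]
        if len(proteins) < params.min_cluster_size:
            discarded.append(rep)
            continue
        members: set[tuple[str, str]] = set()
        for protein in proteins:
            asm = resolve(protein)
            if asm is None:
                if on_unmapped == "skip":
                    warnings.warn(
                        f"cluster {rep!r}: member {protein!r} has no assembly "
                        "mapping; skipped",
                        stacklevel=2,
                    )
                    continue
                raise KeyError(
                    f"cluster {rep!r}: member {protein!r} has no assembly mapping"
                )
            members.add((asm, protein))
        if members:
            families.append(ProteinFamily(rep, frozenset(members)))
    return families, discarded


def family_from_hmm_hits(
    hits: Sequence[ProteinHit],
    model: str,
    bit_min: float | None = None,
    params: FamilyBuildParams | None = None,
) -> ProteinFamily:
    """Family of all per-target HMM hits scoring at or above the model floor.

    ``bit_min`` may be given directly or looked up from
    ``params.hmm_bit_min[model]``; a missing cutoff is an error, because
    the floors are model-specific judgment calls that must be explicit.
    """
    if bit_min is None:
        if params is None or model not in params.hmm_bit_min:
            raise ValueError(f"no bit-score cutoff configured for model {model!r}")
        bit_min = params.hmm_bit_min[model]
    members = frozenset(
        (h.subject_assembly_id, h.subject_id)
        for h in hits
        if h.query_id == model and h.bit_score >= bit_min
    )
    if not members:
        warnings.warn(
            f"model {model!r}: no hits at bit score >= {bit_min!r}; family is empty",
            stacklevel=2,
        )
    return ProteinFamily(model, members)


def count_paralogs(
    family: ProteinFamily, universe: Iterable[str]
) -> ParalogCounts:
    """Count distinct member proteins per assembly over the universe.

    Assemblies without a member get an explicit 0; members whose assembly
    lies outside the universe are dropped with a warning.
    """
    universe = set(universe)
    counts: dict[str, int] = {asm: 0 for asm in sorted(universe)}
    stray: set[str] = set()
    for asm, _protein in family.members:
        if asm in universe:
            counts[asm] += 1
        else:
            stray.add(asm)
    if stray:
        warnings.warn(
            f"family {family.family_id!r}: {len(stray)} member assemblies "
            "outside the universe were ignored",
            stacklevel=2,
        )
    return ParalogCounts(family.family_id, counts)


def presence_matrix_from_families(
    families: Sequence[ProteinFamily], universe: Iterable[str]
) -> pd.DataFrame:
    """Assemblies × families matrix of member counts (0 = absent)."""
    rows = sorted(set(universe))
    cols = sorted(f.family_id for f in families)
    matrix = pd.DataFrame(0, index=pd.Index(rows, name="assembly_id"), columns=cols)
    row_pos = {asm: asm for asm in rows}
    for fam in families:
        for asm, _protein in fam.members:
            if asm in row_pos:
                matrix.loc[asm, fam.family_id] += 1
    return matrix
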