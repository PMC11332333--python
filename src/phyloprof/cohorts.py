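"""Marker-positive / marker-negative cohort construction.

Assemblies are sorted into two analysis groups on the species tree: those
carrying a full-length copy of the marker ncRNA gene and those carrying
none of any category. Variant carriers are excluded outright, as are
marker hits falling outside the allowed phylum (treated as likely assembly
or taxonomy errors). The tree is pruned to the smallest subtree (MRCA
clade) containing all marker-positive assemblies, which bounds the
analysis universe.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import dendropy

from .formats import TaxonRecord, parse_newick
from .rna import AssemblyRnaStatus, AssemblyStatus

__all__ = [
    "ExclusionReason",
    "CohortPartition",
    "filter_by_taxon",
    "partition",
    "mrca_subtree",
]


class ExclusionReason(str, Enum):
    VARIANT_CARRIER = "variant_carrier"
    OUTSIDE_TAXON = "outside_taxon"
    NOT_IN_UNIVERSE = "not_in_universe"


_VARIANT_STATUSES = (AssemblyStatus.VARIANT1, AssemblyStatus.VARIANT2)


@dataclass(frozen=True)
class CohortPartition:
    """The two analysis cohorts plus explicit exclusions with reasons.

    ``positive``, ``negative`` and the excluded set are pairwise disjoint;
    their union is the analysis universe.
    """

    positive: frozenset[str]
    negative: frozenset[str]
    excluded: Mapping[str, ExclusionReason] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exc = set(self.excluded)
        if self.positive & self.negative or self.positive & exc or self.negative & exc:
            raise ValueError("cohort sets are not pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.positive | self.negative | frozenset(self.excluded)


def filter_by_taxon(
    statuses: Mapping[str, AssemblyRnaStatus],
    taxonomy: Mapping[str, TaxonRecord],
    allowed_phylum: str,
) -> tuple[dict[str, AssemblyRnaStatus], dict[str, ExclusionReason]]:
    """Drop assemblies outside ``allowed_phylum``.

    Marker carriers (full-length or variant) outside the phylum are
    returned in the exclusion map with reason ``outside_taxon``;
    marker-absent assemblies outside the phylum simply leave the universe.
    Every status assembly must have a taxonomy row.
    """
    missing = sorted(set(statuses) - set(taxonomy))
    if missing:
        raise KeyError(f"assemblies missing from taxonomy table: {missing}")
    retained: dict[str, AssemblyRnaStatus] = {}
    excluded: dict[str, ExclusionReason] = {}
    for asm, st in statuses.items():
        if taxonomy[asm].phylum == allowed_phylum:
            retained[asm] = st
        elif st.status is not AssemblyStatus.ABSENT:
            excluded[asm] = ExclusionReason.OUTSIDE_TAXON
    return retained, excluded


def partition(
    statuses: Mapping[str, AssemblyRnaStatus],
    universe: Iterable[str],
) -> CohortPartition:
    """Sort the analysis universe into the two cohorts.

    full_length → positive; absent (or no status record) → negative;
    variant carriers → excluded. A status for an assembly outside the
    universe is an error.
    """
    universe = frozenset(universe)
    outside = sorted(set(statuses) - universe)
    if outside:
        raise ValueError(f"status records outside the universe: {outside}")
    positive: set[str] = set()
    excluded: dict[str, ExclusionReason] = {}
    for asm, st in statuses.items():
        if st.status is AssemblyStatus.FULL_LENGTH:
            positive.add(asm)
        elif st.status in _VARIANT_STATUSES:
            excluded[asm] = ExclusionReason.VARIANT_CARRIER
    negative = universe - positive - set(excluded)
    return CohortPartition(frozenset(positive), frozenset(negative), excluded)


def _subtree_newick(node: dendropy.Node, is_root: bool = True) -> str:
    if node.is_leaf():
        s = node.taxon.label
        if any(ch in s for ch in " ()[]:;,'"):
            s = "'" + s.replace("'", "''") + "'"
    else:
        s = "(" + ",".join(
            _subtree_newick(c, is_root=False) for c in node.child_nodes()
        ) + ")"
    if not is_root and node.edge.length is not None:
        s += f":{node.edge.length!r}"
    return s


def mrca_subtree(tree: dendropy.Tree, marked_tips: Iterable[str]) -> dendropy.Tree:
    """Return the smallest subtree (MRCA clade) containing ``marked_tips``.

    All tips of the clade are retained, marked or not, and branch lengths
    inside the clade are preserved. Idempotent for a fixed marked set.
    """
    marked = set(marked_tips)
    if not marked:
        raise ValueError("marked tip set is empty")
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    absent = sorted(marked - set(leaves))
    if absent:
        raise ValueError(f"marked tips absent from tree: {absent}")
    if len(marked) == 1:
        node: dendropy.Node = leaves[next(iter(marked))]
    else:
        node = tree.mrca(taxa=[leaves[lbl].taxon for lbl in sorted(marked)])
    return parse_newick(_subtree_newick(node) + ";")


def drop_unknown_tips(
    tree: dendropy.Tree, taxonomy: Mapping[str, TaxonRecord]
) -> set[str]:
    """Report tree tips missing from the taxonomy table (warned, not fatal)."""
    unknown = {leaf.taxon.label for leaf in tree.leaf_node_iter()} - set(taxonomy)
    if unknown:
        warnings.warn(
            f"{len(unknown)} tree tips missing from taxonomy table; "
            "they are dropped from the analysis universe",
            stacklevel=2,
        )
    return unknown
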