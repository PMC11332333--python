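"""Readers and writers for the external formats the pipeline touches.

Covers the tabular outputs of the standard homology-search and clustering
tools (Infernal ``cmsearch --tblout``, BLAST/DIAMOND 12-column tabular,
HMMER ``hmmsearch --tblout``, MMseqs2 ``createtsv`` two-column cluster
maps), newick species trees, assembly taxonomy tables, id→assembly mapping
tables and the pipeline's own presence-matrix TSV.

Conventions:

* coordinates are kept 1-based inclusive exactly as emitted by the search
  tools; no conversion happens at parse time;
* ``#``-prefixed lines and blank lines are comments everywhere;
* every writer/parser pair round-trips (``parse(write(x)) == x``).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, TextIO, Union

import dendropy
import pandas as pd

__all__ = [
    "ParseError",
    "Strand",
    "Truncation",
    "RnaHit",
    "ProteinHit",
    "ClusterMap",
    "TaxonRecord",
    "parse_rna_hits",
    "write_rna_hits",
    "parse_protein_hits",
    "write_protein_hits",
    "parse_hmm_hits",
    "write_hmm_hits",
    "parse_cluster_map",
    "write_cluster_map",
    "parse_newick",
    "write_newick",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_taxonomy",
    "write_taxonomy",
    "read_id_map",
    "write_id_map",
    "prefix_assembly_mapper",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


class Truncation(str, Enum):
    """Truncation state of a covariance-model hit, as flagged by the search tool."""

    NONE = "no"
    TRUNC5 = "5'"
    TRUNC3 = "3'"
    BOTH = "5'&3'"


_TRUNC_TOKENS = {t.value: t for t in Truncation}


@dataclass(frozen=True)
class RnaHit:
    """One covariance-model search hit.

    Coordinates are 1-based inclusive on the target sequence; ``bit_score``
    is the log-odds score in bits; ``truncation`` records whether the
    alignment was clipped at a sequence end.
    """

    target_seq_id: str
    assembly_id: str
    model_name: str
    bit_score: float
    e_value: float
    seq_from: int
    seq_to: int
    strand: Strand
    truncation: Truncation

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score):
            raise ValueError(f"non-finite bit score for hit {self.target_seq_id}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value for hit {self.target_seq_id}")
        if self.seq_from < 1 or self.seq_to < 1:
            raise ValueError(
                f"coordinates must be >= 1 (1-based), got "
                f"{self.seq_from}..{self.seq_to} for {self.target_seq_id}"
            )


@dataclass(frozen=True)
class ProteinHit:
    """One protein homology-search hit (pairwise or profile-HMM).

    ``percent_identity`` is None for profile-HMM hits, whose tabular output
    carries no identity column.
    """

    query_id: str
    subject_id: str
    subject_assembly_id: str
    bit_score: float
    e_value: float
    percent_identity: float | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for hit {self.subject_id}")
        if self.percent_identity is not None and not (
            0.0 <= self.percent_identity <= 100.0
        ):
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


@dataclass(frozen=True)
class ClusterMap:
    """Representative → member assignments from a clustering run.

    Member sets are disjoint across representatives and every representative
    belongs to its own cluster.
    """

    assignments: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rep, members in self.assignments.items():
            if rep not in members:
                raise ValueError(f"representative {rep!r} not in its own cluster")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"member {m!r} assigned to both {seen[m]!r} and {rep!r}"
                    )
                seen[m] = rep


@dataclass(frozen=True)
class TaxonRecord:
    assembly_id: str
    phylum: str
    class_name: str


Source = Union[str, Path, TextIO, Iterable[str]]
AssemblyMapper = Union[Mapping[str, str], Callable[[str], str], None]


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def _resolve_assembly(ident: str, mapper: AssemblyMapper, lineno: int) -> str | None:
    if mapper is None:
        return ident
    if callable(mapper):
        return mapper(ident)
    try:
        return mapper[ident]
    except KeyError:
        return None


def prefix_assembly_mapper(sep: str = "|") -> Callable[[str], str]:
    """Return a mapper that takes the assembly accession as the id prefix
    before ``sep`` (e.g. ``"GCA_000123.1|contig5" → "GCA_000123.1"``)."""

    def mapper(ident: str) -> str:
        return ident.split(sep, 1)[0]

    return mapper


# --- Infernal cmsearch --tblout -------------------------------------------

# Fixed leading fields of the per-target tblout format; the 18th column
# (description of target) may contain spaces and is kept verbatim.
_INFERNAL_NFIELDS = 17


def parse_rna_hits(
    source: Source,
    assembly_of: AssemblyMapper = None,
    dialect: str = "infernal_tblout",
) -> list[RnaHit]:
    """Parse covariance-model search hits from ``--tblout`` columnar text.

    ``assembly_of`` maps a target sequence id to its assembly accession:
    a dict (missing ids raise), a callable (e.g.
    :func:`prefix_assembly_mapper`), or None to use the target id itself.
    """
    if dialect != "infernal_tblout":
        raise ValueError(f"unknown RNA-hit dialect {dialect!r}")
    hits: list[RnaHit] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(None, _INFERNAL_NFIELDS)
        if len(fields) < _INFERNAL_NFIELDS:
            raise ParseError(
                f"line {lineno}: expected at least {_INFERNAL_NFIELDS} fields, "
                f"got {len(fields)}"
            )
        target = fields[0]
        model = fields[2]
        trunc_token = fields[10]
        if trunc_token not in _TRUNC_TOKENS:
            raise ParseError(
                f"line {lineno}: unknown truncation token {trunc_token!r}"
            )
        strand_token = fields[9]
        if strand_token not in ("+", "-"):
            raise ParseError(f"line {lineno}: bad strand {strand_token!r}")
        assembly = _resolve_assembly(target, assembly_of, lineno)
        if assembly is None:
            raise ParseError(
                f"line {lineno}: target sequence {target!r} has no assembly mapping"
            )
        try:
            hit = RnaHit(
                target_seq_id=target,
                assembly_id=assembly,
                model_name=model,
                bit_score=float(fields[14]),
                e_value=float(fields[15]),
                seq_from=int(fields[7]),
                seq_to=int(fields[8]),
                strand=Strand(strand_token),
                truncation=_TRUNC_TOKENS[trunc_token],
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_rna_hits(hits: Iterable[RnaHit], stream: TextIO) -> None:
    """Write hits in the per-target ``--tblout`` layout."""
    stream.write(
        "#target name\taccession\tquery name\taccession\tmdl\tmdl from\t"
        "mdl to\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\t"
        "E-value\tinc\tdescription of target\n"
    )
    for h in hits:
        span = abs(h.seq_to - h.seq_from) + 1
        stream.write(
            f"{h.target_seq_id} - {h.model_name} - cm 1 {span} "
            f"{h.seq_from} {h.seq_to} {h.strand.value} {h.truncation.value} "
            f"1 0.50 0.0 {h.bit_score!r} {h.e_value!r} ! -\n"
        )


# --- BLAST/DIAMOND 12-column tabular --------------------------------------

_TAB12_NFIELDS = 12


def parse_protein_hits(
    source: Source,
    protein_to_assembly: AssemblyMapper = None,
    on_unmapped: str = "error",
    dialect: str = "tabular12",
) -> list[ProteinHit]:
    """Parse 12-column tabular protein homology hits.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore. Columns 4-10 are validated as
    numeric but not retained. Duplicate (query, subject) alignment records
    are preserved; deduplication is the family builder's job.

    ``on_unmapped`` controls what happens when a subject protein has no
    assembly mapping: ``"error"`` raises, ``"skip"`` drops the record with
    a warning.
    """
    if dialect != "tabular12":
        raise ValueError(f"unknown protein-hit dialect {dialect!r}")
    if on_unmapped not in ("error", "skip"):
        raise ValueError(f"on_unmapped must be 'error' or 'skip', got {on_unmapped!r}")
    hits: list[ProteinHit] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != _TAB12_NFIELDS:
            raise ParseError(
                f"line {lineno}: expected {_TAB12_NFIELDS} columns, got {len(fields)}"
            )
        try:
            # validate the alignment-geometry columns even though they are
            # not retained past parsing
            for idx in (3, 4, 5, 6, 7, 8, 9):
                float(fields[idx])
            pident = float(fields[2])
            evalue = float(fields[10])
            bits = float(fields[11])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        subject = fields[1]
        assembly = _resolve_assembly(subject, protein_to_assembly, lineno)
        if assembly is None:
            if on_unmapped == "skip":
                warnings.warn(
                    f"line {lineno}: subject {subject!r} has no assembly "
                    "mapping; record skipped",
                    stacklevel=2,
                )
                continue
            raise ParseError(
                f"line {lineno}: subject protein {subject!r} has no assembly mapping"
            )
        try:
            hit = ProteinHit(
                query_id=fields[0],
                subject_id=subject,
                subject_assembly_id=assembly,
                bit_score=bits,
                e_value=evalue,
                percent_identity=pident,
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_protein_hits(hits: Iterable[ProteinHit], stream: TextIO) -> None:
    for h in hits:
        pident = 0.0 if h.percent_identity is None else h.percent_identity
        stream.write(
            f"{h.query_id}\t{h.subject_id}\t{pident!r}\t100\t10\t1\t"
            f"1\t100\t1\t100\t{h.e_value!r}\t{h.bit_score!r}\n"
        )


# --- HMMER hmmsearch --tblout ----------------------------------------------

# 18 fixed fields before the free-text description in the per-target format.
_HMMER_NFIELDS = 18


def parse_hmm_hits(
    source: Source,
    protein_to_assembly: AssemblyMapper = None,
    on_unmapped: str = "error",
    dialect: str = "hmmer_tblout",
) -> list[ProteinHit]:
    """Parse profile-HMM per-target hits.

    Extracts the target id, full-sequence e-value and full-sequence bit
    score; ``query_id`` is the model name. ``percent_identity`` is None
    (the format has no identity column).
    """
    if dialect != "hmmer_tblout":
        raise ValueError(f"unknown HMM-hit dialect {dialect!r}")
    if on_unmapped not in ("error", "skip"):
        raise ValueError(f"on_unmapped must be 'error' or 'skip', got {on_unmapped!r}")
    hits: list[ProteinHit] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(None, _HMMER_NFIELDS)
        if len(fields) < _HMMER_NFIELDS:
            raise ParseError(
                f"line {lineno}: expected at least {_HMMER_NFIELDS} fields, "
                f"got {len(fields)}"
            )
        target = fields[0]
        assembly = _resolve_assembly(target, protein_to_assembly, lineno)
        if assembly is None:
            if on_unmapped == "skip":
                warnings.warn(
                    f"line {lineno}: target {target!r} has no assembly "
                    "mapping; record skipped",
                    stacklevel=2,
                )
                continue
            raise ParseError(
                f"line {lineno}: target protein {target!r} has no assembly mapping"
            )
        try:
            hit = ProteinHit(
                query_id=fields[2],
                subject_id=target,
                subject_assembly_id=assembly,
                bit_score=float(fields[5]),
                e_value=float(fields[4]),
                percent_identity=None,
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hmm_hits(hits: Iterable[ProteinHit], stream: TextIO) -> None:
    stream.write("#target name\taccession\tquery name\taccession\t...\n")
    for h in hits:
        stream.write(
            f"{h.subject_id} - {h.query_id} - {h.e_value!r} {h.bit_score!r} 0.1 "
            f"{h.e_value!r} {h.bit_score!r} 0.1 1.0 1 0 0 0 1 1 1 1 -\n"
        )


# --- MMseqs2-style two-column cluster TSV -----------------------------------


def parse_cluster_map(source: Source) -> ClusterMap:
    """Parse ``representative<TAB>member`` lines into a :class:`ClusterMap`.

    Self-membership lines are accepted (and implied if absent). A member
    appearing under two representatives violates disjointness and raises.
    """
    assignments: dict[str, set[str]] = {}
    owner: dict[str, str] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        rep, member = parts
        if member in owner and owner[member] != rep:
            raise ParseError(
                f"line {lineno}: member {member!r} assigned to both "
                f"{owner[member]!r} and {rep!r}"
            )
        owner[member] = rep
        assignments.setdefault(rep, set()).add(member)
    for rep in assignments:
        if rep in owner and owner[rep] != rep:
            raise ParseError(
                f"representative {rep!r} is also a member of {owner[rep]!r}"
            )
        assignments[rep].add(rep)
    return ClusterMap({rep: frozenset(m) for rep, m in assignments.items()})


def write_cluster_map(cmap: ClusterMap, stream: TextIO) -> None:
    for rep in sorted(cmap.assignments):
        for member in sorted(cmap.assignments[rep]):
            stream.write(f"{rep}\t{member}\n")


# --- newick trees -----------------------------------------------------------


def parse_newick(source: Source) -> dendropy.Tree:
    """Parse a newick tree, requiring unique tip labels.

    Underscores in labels are preserved verbatim (no quoting games).
    ``source`` may be a path, a file object, or raw newick text (anything
    containing ``;`` or ``(``).
    """
    if isinstance(source, str) and (";" in source or "(" in source):
        text = source
    elif isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = "".join(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"bad newick: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
    if dupes:
        raise ParseError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# --- presence matrix TSV -----------------------------------------------------


def write_presence_matrix(matrix: pd.DataFrame, stream: TextIO) -> None:
    """Write an assemblies × families member-count matrix as TSV.

    Rows are assemblies, columns are family ids, cells are nonnegative
    member counts.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("presence matrix has negative cells")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.to_csv(stream, sep="\t", index_label="assembly_id")


def read_presence_matrix(source: Source) -> pd.DataFrame:
    if not isinstance(source, (str, Path)) and not hasattr(source, "read"):
        import io as _stdio

        source = _stdio.StringIO("".join(source))
    matrix = pd.read_csv(source, sep="\t", index_col=0)
    matrix.index.name = "assembly_id"
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ParseError("duplicate row or column labels in presence matrix")
    matrix = matrix.astype(int)
    if (matrix.to_numpy() < 0).any():
        raise ParseError("presence matrix has negative cells")
    return matrix


# --- taxonomy and id-mapping TSVs -------------------------------------------


def read_taxonomy(source: Source) -> dict[str, TaxonRecord]:
    """Read a 3-column assembly taxonomy TSV (assembly_id, phylum, class)."""
    records: dict[str, TaxonRecord] = {}
    header_seen = False
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        if not header_seen:
            header_seen = True
            if parts[0] == "assembly_id":
                continue
        asm, phylum, class_name = parts
        if asm in records:
            raise ParseError(f"line {lineno}: duplicate assembly {asm!r}")
        records[asm] = TaxonRecord(asm, phylum, class_name)
    return records


def write_taxonomy(records: Mapping[str, TaxonRecord] | Iterable[TaxonRecord], stream: TextIO) -> None:
    stream.write("assembly_id\tphylum\tclass\n")
    if isinstance(records, Mapping):
        records = records.values()
    for rec in sorted(records, key=lambda r: r.assembly_id):
        stream.write(f"{rec.assembly_id}\t{rec.phylum}\t{rec.class_name}\n")


def read_id_map(source: Source) -> dict[str, str]:
    """Read a headerless two-column TSV mapping an id to its assembly."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        ident, asm = parts
        if ident in mapping and mapping[ident] != asm:
            raise ParseError(
                f"line {lineno}: id {ident!r} mapped to both "
                f"{mapping[ident]!r} and {asm!r}"
            )
        mapping[ident] = asm
    return mapping


def write_id_map(mapping: Mapping[str, str], stream: TextIO) -> None:
    for ident in sorted(mapping):
        stream.write(f"{ident}\t{mapping[ident]}\n")
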