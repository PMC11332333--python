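"""Seeded synthetic cohorts, trees, families and mock search-output files.

The generator emulates the statistical structure the analysis assumes:
two cohorts of genome assemblies on a random bifurcating species tree,
marker-positive assemblies concentrated in a few monophyletic clades
(mirroring a marker scattered across distinct clades of one phylum),
protein families whose presence is Bernoulli per assembly with
cohort-conditional probabilities, and paralog counts of 1 + Poisson(mean)
for present families. Decoy out-of-phylum taxa and variant carriers are
injected deliberately so every exclusion path is exercised.

``emit_fixtures`` writes the whole input set in the real tools' formats
(covariance-model tblout, 12-column protein hits, per-target HMM hits,
cluster TSV, newick, taxonomy and id-map TSVs) so the full pipeline can
run from files and be checked against the recorded ground truth.

All randomness flows from the single integer seed in :class:`SimSpec`
through per-stage child streams; there is no hidden global state.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

import dendropy

from . import formats
from .cohorts import CohortPartition, ExclusionReason
from .rna import AssemblyStatus

__all__ = [
    "PlantedFamily",
    "SimSpec",
    "SimTruth",
    "SimCohort",
    "simulate_cohort",
    "plant_families",
    "emit_fixtures",
    "simulate",
    "FIXTURE_FILES",
]

#: file names written by emit_fixtures
FIXTURE_FILES = {
    "rna_hits": "rna_hits.tblout",
    "seq2asm": "seq2asm.tsv",
    "protein_hits": "protein_hits.tsv",
    "prot2asm": "prot2asm.tsv",
    "clusters": "clusters.tsv",
    "hmm_hits": "hmm_hits.tblout",
    "tree": "tree.nwk",
    "taxonomy": "taxonomy.tsv",
    "truth_matrix": "truth_matrix.tsv",
    "truth": "truth.json",
}

#: default bit-score floor used for the synthetic HMM fixture family
HMM_FIXTURE_BIT_MIN = 50.0


@dataclass(frozen=True)
class PlantedFamily:
    """A family with known cohort-conditional presence probabilities."""

    family_id: str
    p_given_pos: float
    p_given_neg: float
    paralog_mean: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_given_pos <= 1.0 and 0.0 <= self.p_given_neg <= 1.0):
            raise ValueError("presence probabilities must lie in [0, 1]")
        if self.paralog_mean < 0:
            raise ValueError("paralog_mean must be >= 0")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study.

    ``n_pos``/``n_neg`` are the cohort sizes; ``planted`` families carry
    known (p_given_pos, p_given_neg); ``n_null_families`` adds families
    with equal presence probability ``null_presence`` in both cohorts.
    With ``clade_structure`` the marker-positive tips occupy at most
    ``n_clades`` monophyletic groups. Decoy out-of-phylum taxa and variant
    carriers exercise the exclusion paths.
    """

    n_pos: int
    n_neg: int
    n_null_families: int = 0
    planted: Sequence[PlantedFamily] = ()
    clade_structure: bool = True
    seed: int = 0
    n_clades: int = 3
    n_variant_carriers: int = 2
    n_decoy_taxa: int = 2
    null_presence: float = 0.5
    null_paralog_mean: float = 0.0
    allowed_phylum: str = "Bacillota"
    decoy_phylum: str = "Pseudomonadota"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.n_null_families < 0 or self.n_variant_carriers < 0 or self.n_decoy_taxa < 0:
            raise ValueError("counts must be nonnegative")
        if not (0.0 <= self.null_presence <= 1.0):
            raise ValueError("null_presence must lie in [0, 1]")
        if self.n_clades < 1:
            raise ValueError("n_clades must be >= 1")
        ids = [p.family_id for p in self.planted]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate planted family ids")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded alongside the generated data."""

    statuses: Mapping[str, AssemblyStatus]
    universe: frozenset[str]
    partition: CohortPartition
    matrix: pd.DataFrame | None = None
    family_probs: Mapping[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class SimCohort:
    spec: SimSpec
    tree: dendropy.Tree
    statuses: Mapping[str, AssemblyStatus]
    taxonomy: Mapping[str, formats.TaxonRecord]
    truth: SimTruth


# --- random bifurcating trees (nested-tuple representation) -----------------

Node = Union[str, tuple]


def _build_tree(leaves: list[Node], rng: np.random.Generator) -> Node:
    if len(leaves) == 1:
        return leaves[0]
    k = int(rng.integers(1, len(leaves)))
    return (_build_tree(leaves[:k], rng), _build_tree(leaves[k:], rng))


def _leafset(node: Node) -> frozenset[str]:
    if isinstance(node, str):
        return frozenset((node,))
    out: frozenset[str] = frozenset()
    for child in node:
        out |= _leafset(child)
    return out


def _containing_clade_tips(node: Node, marked: frozenset[str]) -> frozenset[str]:
    """Brute-force smallest clade containing ``marked``: descend while one
    child still holds the whole marked set."""
    if isinstance(node, str):
        return frozenset((node,))
    for child in node:
        if marked <= _leafset(child):
            return _containing_clade_tips(child, marked)
    return _leafset(node)


def _to_newick(node: Node, rng: np.random.Generator, is_root: bool = True) -> str:
    if isinstance(node, str):
        s = node
    else:
        s = "(" + ",".join(_to_newick(c, rng, is_root=False) for c in node) + ")"
    if not is_root:
        length = round(float(rng.exponential(0.1)) + 1e-4, 6)
        s += f":{length!r}"
    return s


def _shuffled(items: list, rng: np.random.Generator) -> list:
    order = rng.permutation(len(items))
    return [items[i] for i in order]


# --- cohort simulation ------------------------------------------------------

_IN_PHYLUM_CLASSES = ("Bacilli", "Clostridia", "Negativicutes")


def simulate_cohort(spec: SimSpec) -> SimCohort:
    """Generate the tree, per-assembly marker statuses, taxonomy and truth.

    Fully reproducible from ``spec.seed``; running twice yields identical
    output.
    """
    rng = np.random.default_rng([spec.seed, 0])

    pos = [f"POS_{i:04d}" for i in range(spec.n_pos)]
    neg = [f"NEG_{i:04d}" for i in range(spec.n_neg)]
    var = [f"VAR_{i:04d}" for i in range(spec.n_variant_carriers)]
    dec = [f"DEC_{i:04d}" for i in range(spec.n_decoy_taxa)]

    statuses: dict[str, AssemblyStatus] = {}
    for a in pos:
        statuses[a] = AssemblyStatus.FULL_LENGTH
    for a in neg:
        statuses[a] = AssemblyStatus.ABSENT
    for i, a in enumerate(var):
        statuses[a] = AssemblyStatus.VARIANT1 if i % 2 == 0 else AssemblyStatus.VARIANT2
    for a in dec:
        statuses[a] = AssemblyStatus.FULL_LENGTH  # out-of-phylum marker hit

    taxonomy: dict[str, formats.TaxonRecord] = {}
    for i, a in enumerate(pos + neg + var):
        taxonomy[a] = formats.TaxonRecord(
            a, spec.allowed_phylum, _IN_PHYLUM_CLASSES[i % len(_IN_PHYLUM_CLASSES)]
        )
    for a in dec:
        taxonomy[a] = formats.TaxonRecord(a, spec.decoy_phylum, "Gammaproteobacteria")

    # marker-positive tips grouped into <= n_clades monophyletic units
    shuffled_pos = _shuffled(pos, rng)
    if spec.clade_structure:
        n_groups = min(spec.n_clades, spec.n_pos)
        cuts = sorted(
            rng.choice(np.arange(1, spec.n_pos), size=n_groups - 1, replace=False)
        ) if n_groups > 1 else []
        groups, start = [], 0
        for cut in list(cuts) + [spec.n_pos]:
            groups.append(shuffled_pos[start:cut])
            start = cut
        units: list[Node] = [_build_tree(g, rng) for g in groups]
    else:
        units = list(shuffled_pos)
    units += neg + var + dec
    root = _build_tree(_shuffled(units, rng), rng)
    if isinstance(root, str):  # single assembly overall
        root = (root,)
    newick = _to_newick(root, rng) + ";"
    tree = formats.parse_newick(newick)

    truth = _derive_truth(spec, root, statuses, taxonomy)
    return SimCohort(spec, tree, statuses, taxonomy, truth)


def _derive_truth(
    spec: SimSpec,
    root: Node,
    statuses: Mapping[str, AssemblyStatus],
    taxonomy: Mapping[str, formats.TaxonRecord],
) -> SimTruth:
    """Expected analysis outcome, computed with plain set logic and a
    brute-force clade search (independent of the pipeline's tree code)."""
    in_phylum = {
        a for a in statuses if taxonomy[a].phylum == spec.allowed_phylum
    }
    positive = frozenset(
        a
        for a in statuses
        if statuses[a] is AssemblyStatus.FULL_LENGTH and a in in_phylum
    )
    if not positive:
        raise ValueError("simulation produced no in-phylum marker-positive assembly")
    clade_tips = _containing_clade_tips(root, positive)
    universe = frozenset(clade_tips & in_phylum)

    excluded: dict[str, ExclusionReason] = {}
    for a, st in statuses.items():
        if st is AssemblyStatus.ABSENT:
            continue
        if a not in in_phylum:
            excluded[a] = ExclusionReason.OUTSIDE_TAXON
        elif st in (AssemblyStatus.VARIANT1, AssemblyStatus.VARIANT2):
            excluded[a] = (
                ExclusionReason.VARIANT_CARRIER
                if a in universe
                else ExclusionReason.NOT_IN_UNIVERSE
            )
    negative = frozenset(universe - positive - set(excluded))
    part = CohortPartition(positive, negative, excluded)
    return SimTruth(statuses=dict(statuses), universe=universe, partition=part)


# --- family planting --------------------------------------------------------


def _family_list(spec: SimSpec) -> list[PlantedFamily]:
    fams = list(spec.planted)
    width = max(4, len(str(max(spec.n_null_families - 1, 0))))
    for i in range(spec.n_null_families):
        fams.append(
            PlantedFamily(
                f"null_{i:0{width}d}",
                spec.null_presence,
                spec.null_presence,
                spec.null_paralog_mean,
            )
        )
    ids = [f.family_id for f in fams]
    if len(ids) != len(set(ids)):
        raise ValueError("null family ids collide with planted ids")
    return fams


def plant_families(spec: SimSpec, cohort: SimCohort) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-assembly member counts for every family.

    Presence is Bernoulli with probability p_given_pos for in-phylum
    marker-positive assemblies and p_given_neg for everything else; a
    present family has 1 + Poisson(paralog_mean) members, so presence
    always implies count >= 1.
    """
    rng = np.random.default_rng([spec.seed, 1])
    fams = _family_list(spec)
    positive = cohort.truth.partition.positive
    assemblies = sorted(cohort.statuses)
    data: dict[str, list[int]] = {}
    probs: dict[str, tuple[float, float]] = {}
    for fam in fams:
        counts = []
        for asm in assemblies:
            p = fam.p_given_pos if asm in positive else fam.p_given_neg
            if rng.random() < p:
                counts.append(1 + int(rng.poisson(fam.paralog_mean)))
            else:
                counts.append(0)
        data[fam.family_id] = counts
        probs[fam.family_id] = (fam.p_given_pos, fam.p_given_neg)
    matrix = pd.DataFrame(
        data, index=pd.Index(assemblies, name="assembly_id")
    ).sort_index(axis=1)
    truth = replace(cohort.truth, matrix=matrix, family_probs=probs)
    return matrix, truth


# --- fixture emission -------------------------------------------------------


def _round1(x: float) -> float:
    return round(float(x), 1)


def _emit_rna_fixture(
    cohort: SimCohort, rng: np.random.Generator
) -> tuple[list[formats.RnaHit], dict[str, str]]:
    hits: list[formats.RnaHit] = []
    seq2asm: dict[str, str] = {}
    model = "ncRNA-marker"

    def add(asm: str, seq_no: int, bits: float, trunc: formats.Truncation) -> None:
        seq_id = f"{asm}|ctg{seq_no}"
        seq2asm[seq_id] = asm
        start = int(rng.integers(1, 100_000))
        strand = formats.Strand.PLUS if rng.random() < 0.5 else formats.Strand.MINUS
        frm, to = (start, start + 599) if strand is formats.Strand.PLUS else (
            start + 599,
            start,
        )
        hits.append(
            formats.RnaHit(
                target_seq_id=seq_id,
                assembly_id=asm,
                model_name=model,
                bit_score=bits,
                e_value=float(10.0 ** rng.uniform(-60, -5)),
                seq_from=frm,
                seq_to=to,
                strand=strand,
                truncation=trunc,
            )
        )

    for asm, st in sorted(cohort.statuses.items()):
        if st is AssemblyStatus.FULL_LENGTH:
            add(asm, 1, _round1(rng.uniform(390.0, 480.0)), formats.Truncation.NONE)
            if rng.random() < 0.3:  # secondary weaker hit; best-hit rule wins
                add(asm, 2, _round1(rng.uniform(100.0, 380.0)), formats.Truncation.NONE)
        elif st is AssemblyStatus.VARIANT1:
            add(asm, 1, _round1(rng.uniform(310.0, 389.9)), formats.Truncation.NONE)
        elif st is AssemblyStatus.VARIANT2:
            if rng.random() < 0.5:
                trunc = (
                    formats.Truncation.TRUNC5
                    if rng.random() < 0.5
                    else formats.Truncation.TRUNC3
                )
                add(asm, 1, _round1(rng.uniform(235.0, 460.0)), trunc)
            else:
                add(asm, 1, _round1(rng.uniform(235.0, 309.9)), formats.Truncation.NONE)
        else:  # absent; sometimes a sub-threshold spurious hit
            if rng.random() < 0.3:
                add(asm, 1, _round1(rng.uniform(20.0, 234.5)), formats.Truncation.NONE)
    return hits, seq2asm


def emit_fixtures(
    cohort: SimCohort,
    matrix: pd.DataFrame,
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write the complete mock input file set; returns name → path.

    Every file parses with :mod:`phyloprof.formats`, and running the
    pipeline on them reproduces the recorded truth exactly: the emitted
    bit scores respect the category thresholds per status, family members
    get e-values <= 1e-10, and rejected decoy hits get e-values above it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cohort.spec.seed, 2])
    paths = {k: out / v for k, v in FIXTURE_FILES.items()}

    rna_hits, seq2asm = _emit_rna_fixture(cohort, rng)
    with open(paths["rna_hits"], "w") as fh:
        formats.write_rna_hits(rna_hits, fh)
    with open(paths["seq2asm"], "w") as fh:
        formats.write_id_map(seq2asm, fh)

    # proteins: one fresh id per (assembly, family, copy); per-assembly counter
    prot2asm: dict[str, str] = {}
    counters: dict[str, int] = {}

    def new_protein(asm: str) -> str:
        counters[asm] = counters.get(asm, 0) + 1
        pid = f"{asm}~p{counters[asm]:04d}"
        prot2asm[pid] = asm
        return pid

    membership: dict[str, list[tuple[str, str]]] = {}
    for fam in sorted(matrix.columns):
        members = []
        for asm in matrix.index:
            for _ in range(int(matrix.loc[asm, fam])):
                members.append((asm, new_protein(asm)))
        membership[fam] = members

    assemblies = sorted(cohort.statuses)
    protein_hits: list[formats.ProteinHit] = []
    for fam in sorted(membership):
        for i, (asm, pid) in enumerate(membership[fam]):
            evalue = 1e-10 if i == 0 else float(10.0 ** rng.uniform(-180, -10.5))
            protein_hits.append(
                formats.ProteinHit(
                    query_id=fam,
                    subject_id=pid,
                    subject_assembly_id=asm,
                    bit_score=_round1(rng.uniform(80, 500)),
                    e_value=evalue,
                    percent_identity=_round1(rng.uniform(30, 100)),
                )
            )
        for _ in range(2):  # decoys above the cutoff: must be filtered out
            asm = assemblies[int(rng.integers(0, len(assemblies)))]
            protein_hits.append(
                formats.ProteinHit(
                    query_id=fam,
                    subject_id=new_protein(asm),
                    subject_assembly_id=asm,
                    bit_score=_round1(rng.uniform(20, 60)),
                    e_value=float(10.0 ** rng.uniform(-9, -3)),
                    percent_identity=_round1(rng.uniform(20, 40)),
                )
            )
    with open(paths["protein_hits"], "w") as fh:
        formats.write_protein_hits(protein_hits, fh)

    # cluster map mirroring the family memberships, plus an undersized decoy
    assignments: dict[str, frozenset[str]] = {}
    for fam, members in membership.items():
        proteins = sorted(pid for _, pid in members)
        if proteins:
            assignments[proteins[0]] = frozenset(proteins)
    small = [new_protein(assemblies[0]) for _ in range(2)]
    assignments[small[0]] = frozenset(small)
    with open(paths["clusters"], "w") as fh:
        formats.write_cluster_map(formats.ClusterMap(assignments), fh)

    # profile-HMM fixture for the first family: members above the floor,
    # decoys below it
    hmm_model = sorted(membership)[0] if membership else None
    hmm_hits: list[formats.ProteinHit] = []
    if hmm_model is not None:
        for asm, pid in membership[hmm_model]:
            hmm_hits.append(
                formats.ProteinHit(
                    query_id=hmm_model,
                    subject_id=pid,
                    subject_assembly_id=asm,
                    bit_score=_round1(rng.uniform(HMM_FIXTURE_BIT_MIN + 10, 300)),
                    e_value=float(10.0 ** rng.uniform(-80, -15)),
                )
            )
        for _ in range(3):
            asm = assemblies[int(rng.integers(0, len(assemblies)))]
            hmm_hits.append(
                formats.ProteinHit(
                    query_id=hmm_model,
                    subject_id=new_protein(asm),
                    subject_assembly_id=asm,
                    bit_score=_round1(rng.uniform(5, HMM_FIXTURE_BIT_MIN - 0.2)),
                    e_value=float(10.0 ** rng.uniform(-4, -1)),
                )
            )
    with open(paths["hmm_hits"], "w") as fh:
        formats.write_hmm_hits(hmm_hits, fh)

    with open(paths["prot2asm"], "w") as fh:
        formats.write_id_map(prot2asm, fh)
    with open(paths["tree"], "w") as fh:
        fh.write(formats.write_newick(cohort.tree) + "\n")
    with open(paths["taxonomy"], "w") as fh:
        formats.write_taxonomy(cohort.taxonomy, fh)
    with open(paths["truth_matrix"], "w") as fh:
        formats.write_presence_matrix(matrix, fh)

    truth = cohort.truth
    payload = {
        "seed": cohort.spec.seed,
        "allowed_phylum": cohort.spec.allowed_phylum,
        "statuses": {a: s.value for a, s in sorted(truth.statuses.items())},
        "universe": sorted(truth.universe),
        "partition": {
            "positive": sorted(truth.partition.positive),
            "negative": sorted(truth.partition.negative),
            "excluded": {
                a: r.value for a, r in sorted(truth.partition.excluded.items())
            },
        },
        "family_probs": {
            f: list(p) for f, p in sorted(truth.family_probs.items())
        },
        "hmm_model": hmm_model,
        "hmm_bit_min": HMM_FIXTURE_BIT_MIN,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def simulate(spec: SimSpec) -> tuple[SimCohort, pd.DataFrame, SimTruth]:
    """Convenience wrapper: cohort + planted families in one call."""
    cohort = simulate_cohort(spec)
    matrix, truth = plant_families(spec, cohort)
    return replace(cohort, truth=truth), matrix, truth
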