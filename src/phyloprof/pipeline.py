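"""End-to-end orchestration: parsed search output → ranked profile report.

Stages: parse RNA hits → classify per-assembly statuses → taxonomic
filter → prune tree to the marker clade → partition cohorts → build
protein families → contingency tables → fractions + mutual information →
rank. Stages communicate through the documented TSV/JSON artifacts, every
run writes a manifest with stage counts, and a rerun with identical
inputs and config is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Union

from . import formats
from .cohorts import (
    CohortPartition,
    ExclusionReason,
    filter_by_taxon,
    mrca_subtree,
    partition,
)
from .families import (
    FamilyBuildParams,
    families_from_clusters,
    families_from_reference_hits,
    family_from_hmm_hits,
    presence_matrix_from_families,
)
from .rna import AssemblyStatus, ClassificationThresholds, call_statuses
from .stats import ProfileResult, profile_families

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_profile", "write_report"]

logger = logging.getLogger("phyloprof")

_PathLike = Union[str, Path]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs of one profiling run."""

    rna_hits: _PathLike
    seq2asm: _PathLike
    protein_hits: _PathLike
    prot2asm: _PathLike
    tree: _PathLike
    taxonomy: _PathLike
    out_dir: _PathLike
    clusters: _PathLike | None = None
    hmm_hits: _PathLike | None = None
    family_source: str = "reference_hits"  # reference_hits | clusters | hmm
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    family_params: FamilyBuildParams = field(default_factory=FamilyBuildParams)
    allowed_phylum: str = "Bacillota"
    zero_mode: str = "discard"
    universe_mode: str = "pruned_subtree"  # pruned_subtree | whole_phylum

    def __post_init__(self) -> None:
        if self.family_source not in ("reference_hits", "clusters", "hmm"):
            raise ValueError(f"unknown family_source {self.family_source!r}")
        if self.universe_mode not in ("pruned_subtree", "whole_phylum"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        if self.zero_mode not in ("discard", "limit"):
            raise ValueError(f"unknown zero_mode {self.zero_mode!r}")

    @classmethod
    def from_fixture_dir(cls, fixture_dir: _PathLike, out_dir: _PathLike, **kw) -> "RunConfig":
        """Point a config at a directory written by the synthetic generator."""
        from .simulate import FIXTURE_FILES

        d = Path(fixture_dir)
        return cls(
            rna_hits=d / FIXTURE_FILES["rna_hits"],
            seq2asm=d / FIXTURE_FILES["seq2asm"],
            protein_hits=d / FIXTURE_FILES["protein_hits"],
            prot2asm=d / FIXTURE_FILES["prot2asm"],
            tree=d / FIXTURE_FILES["tree"],
            taxonomy=d / FIXTURE_FILES["taxonomy"],
            clusters=d / FIXTURE_FILES["clusters"],
            hmm_hits=d / FIXTURE_FILES["hmm_hits"],
            out_dir=out_dir,
            **kw,
        )


@dataclass
class RunManifest:
    """Input digests, config echo, and per-stage counts."""

    input_digests: dict[str, str]
    config: dict
    counts: dict[str, int]

    def check_consistency(self) -> None:
        c = self.counts
        if c["positive"] + c["negative"] + c["excluded_in_universe"] != c["universe"]:
            raise PipelineError(
                "manifest inconsistency: cohorts do not add up to the universe"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"


@contextmanager
def _stage(name: str) -> Iterator[None]:
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    logger.info("stage %s: done", name)


def _sha256(path: _PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run_profile(config: RunConfig) -> tuple[list[ProfileResult], RunManifest]:
    """Execute the full analysis and write the report artifacts.

    Writes ``profile.tsv``, ``cohorts.json``, ``presence_matrix.tsv`` and
    ``manifest.json`` into ``config.out_dir``. Deterministic given inputs
    and config.
    """
    counts: dict[str, int] = {}

    with _stage("parse_rna_hits"):
        seq2asm = formats.read_id_map(config.seq2asm)
        rna_hits = formats.parse_rna_hits(config.rna_hits, assembly_of=seq2asm)
        counts["rna_hits_parsed"] = len(rna_hits)

    with _stage("classify"):
        statuses = call_statuses(rna_hits, config.thresholds)
        for st in AssemblyStatus:
            counts[f"status_{st.value}"] = sum(
                1 for s in statuses.values() if s.status is st
            )

    with _stage("taxonomy_filter"):
        taxonomy = formats.read_taxonomy(config.taxonomy)
        statuses, taxon_excluded = filter_by_taxon(
            statuses, taxonomy, config.allowed_phylum
        )
        counts["excluded_outside_taxon"] = len(taxon_excluded)

    with _stage("prune_tree"):
        positive = {
            a
            for a, s in statuses.items()
            if s.status is AssemblyStatus.FULL_LENGTH
        }
        if not positive:
            raise PipelineError(
                "stage prune_tree: no marker-positive assemblies inside the "
                "allowed phylum; cannot define cohorts"
            )
        tree = formats.parse_newick(config.tree)
        if config.universe_mode == "pruned_subtree":
            subtree = mrca_subtree(tree, positive)
            clade_tips = formats.tip_labels(subtree)
        else:
            clade_tips = {
                a
                for a, rec in taxonomy.items()
                if rec.phylum == config.allowed_phylum
            }
        unknown = clade_tips - set(taxonomy)
        if unknown:
            logger.warning(
                "%d universe tips missing from taxonomy; dropped", len(unknown)
            )
        clade_tips -= unknown
        universe = {
            a
            for a in clade_tips
            if taxonomy[a].phylum == config.allowed_phylum
        }
        for a in clade_tips - universe:
            taxon_excluded.setdefault(a, ExclusionReason.OUTSIDE_TAXON)
        counts["universe"] = len(universe)

    with _stage("partition"):
        in_universe = {a: s for a, s in statuses.items() if a in universe}
        part = partition(in_universe, universe)
        excluded = dict(part.excluded)
        counts["excluded_in_universe"] = len(excluded)
        # carriers inside the phylum but outside the pruned clade
        for a, s in statuses.items():
            if a not in universe and s.status is not AssemblyStatus.ABSENT:
                excluded.setdefault(a, ExclusionReason.NOT_IN_UNIVERSE)
        excluded.update(taxon_excluded)
        part = CohortPartition(part.positive, part.negative, excluded)
        counts["positive"] = len(part.positive)
        counts["negative"] = len(part.negative)
        counts["excluded_total"] = len(excluded)

    with _stage("build_families"):
        prot2asm = formats.read_id_map(config.prot2asm)
        discarded: list[str] = []
        if config.family_source == "reference_hits":
            hits = formats.parse_protein_hits(
                config.protein_hits, protein_to_assembly=prot2asm
            )
            families = families_from_reference_hits(hits, config.family_params)
        elif config.family_source == "clusters":
            if config.clusters is None:
                raise PipelineError("stage build_families: clusters path not set")
            cmap = formats.parse_cluster_map(config.clusters)
            families, discarded = families_from_clusters(
                cmap, prot2asm, config.family_params
            )
        else:
            if config.hmm_hits is None:
                raise PipelineError("stage build_families: hmm_hits path not set")
            hmm_hits = formats.parse_hmm_hits(
                config.hmm_hits, protein_to_assembly=prot2asm
            )
            models = sorted({h.query_id for h in hmm_hits})
            families = [
                family_from_hmm_hits(hmm_hits, m, params=config.family_params)
                for m in models
            ]
            families = [f for f in families if f.members]
        counts["families_built"] = len(families)
        counts["families_discarded"] = len(discarded)

    with _stage("profile"):
        results = profile_families(families, part, zero_mode=config.zero_mode)
        counts["families_undefined_mi"] = sum(
            1 for r in results if r.mi_bits is None
        )

    manifest = RunManifest(
        input_digests={
            name: _sha256(path)
            for name, path in (
                ("rna_hits", config.rna_hits),
                ("seq2asm", config.seq2asm),
                ("protein_hits", config.protein_hits),
                ("prot2asm", config.prot2asm),
                ("tree", config.tree),
                ("taxonomy", config.taxonomy),
            )
        },
        config={
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        counts=counts,
    )
    manifest.check_consistency()

    with _stage("write_report"):
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(results, out / "profile.tsv")
        with open(out / "cohorts.json", "w") as fh:
            json.dump(
                {
                    "positive": sorted(part.positive),
                    "negative": sorted(part.negative),
                    "excluded": {
                        a: r.value for a, r in sorted(part.excluded.items())
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        matrix = presence_matrix_from_families(families, universe)
        with open(out / "presence_matrix.tsv", "w") as fh:
            formats.write_presence_matrix(matrix, fh)
        with open(out / "manifest.json", "w") as fh:
            fh.write(manifest.to_json())

    return results, manifest


def write_report(results: list[ProfileResult], path: _PathLike) -> None:
    """Ranked profile TSV; floats printed with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write(
            "family_id\tf_pos\tf_neg\tn11\tn10\tn01\tn00\tmi_bits\tdirection\trank\n"
        )
        for r in results:
            mi = "NA" if r.mi_bits is None else _fmt(r.mi_bits)
            jc = r.joint
            fh.write(
                f"{r.family_id}\t{_fmt(r.fractions.f_pos)}\t"
                f"{_fmt(r.fractions.f_neg)}\t{jc.n11}\t{jc.n10}\t{jc.n01}\t"
                f"{jc.n00}\t{mi}\t{r.direction.value}\t{r.rank}\n"
            )
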