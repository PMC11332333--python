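"""Parsers and writers for the external tool formats."""
from __future__ import annotations

import io

import numpy as np
import pytest

from phyloprof import formats
from phyloprof.formats import (
    ClusterMap,
    ParseError,
    ProteinHit,
    RnaHit,
    Strand,
    TaxonRecord,
    Truncation,
)

from conftest import make_protein_hit, make_rna_hit


def _tblout_line(
    target="ASM_A|ctg1",
    model="ncRNA-marker",
    seq_from=100,
    seq_to=705,
    strand="+",
    trunc="no",
    score="412.3",
    evalue="1.2e-80",
    desc="some description with spaces",
):
    return (
        f"{target} - {model} - cm 1 600 {seq_from} {seq_to} {strand} {trunc} "
        f"1 0.43 0.0 {score} {evalue} ! {desc}\n"
    )


class TestParseRnaHits:
    def test_empty_and_comment_only_streams(self):
        assert formats.parse_rna_hits(io.StringIO("")) == []
        assert formats.parse_rna_hits(io.StringIO("# a\n# b\n# c\n")) == []

    def test_single_fixture_line(self):
        (hit,) = formats.parse_rna_hits(io.StringIO(_tblout_line()))
        assert hit.bit_score == 412.3
        assert hit.truncation is Truncation.NONE
        assert (hit.seq_from, hit.seq_to) == (100, 705)
        assert hit.strand is Strand.PLUS
        assert hit.e_value == 1.2e-80
        assert hit.model_name == "ncRNA-marker"

    @pytest.mark.parametrize(
        "token,expected",
        [
            ("no", Truncation.NONE),
            ("5'", Truncation.TRUNC5),
            ("3'", Truncation.TRUNC3),
            ("5'&3'", Truncation.BOTH),
        ],
    )
    def test_truncation_tokens(self, token, expected):
        (hit,) = formats.parse_rna_hits(io.StringIO(_tblout_line(trunc=token)))
        assert hit.truncation is expected

    def test_unknown_truncation_token_names_line(self):
        stream = io.StringIO("# header\n" + _tblout_line(trunc="maybe"))
        with pytest.raises(ParseError, match="line 2.*maybe"):
            formats.parse_rna_hits(stream)

    def test_short_line_names_line_number(self):
        with pytest.raises(ParseError, match="line 1"):
            formats.parse_rna_hits(io.StringIO("a b c\n"))

    def test_description_free_text_does_not_shift_fields(self):
        line = _tblout_line(desc="Bacillus sp. chromosome, complete genome")
        (hit,) = formats.parse_rna_hits(io.StringIO(line))
        assert hit.bit_score == 412.3

    def test_assembly_mapping_dict_and_prefix_rule(self):
        line = _tblout_line(target="GCA_1|ctg9")
        (hit,) = formats.parse_rna_hits(
            io.StringIO(line), assembly_of={"GCA_1|ctg9": "GCA_1"}
        )
        assert hit.assembly_id == "GCA_1"
        (hit,) = formats.parse_rna_hits(
            io.StringIO(line), assembly_of=formats.prefix_assembly_mapper("|")
        )
        assert hit.assembly_id == "GCA_1"

    def test_unmapped_target_raises(self):
        with pytest.raises(ParseError, match="no assembly mapping"):
            formats.parse_rna_hits(io.StringIO(_tblout_line()), assembly_of={})

    def test_scientific_notation_variants(self):
        for ev in ("1e-10", "1.0E-10", "2.5e-101"):
            (hit,) = formats.parse_rna_hits(io.StringIO(_tblout_line(evalue=ev)))
            assert hit.e_value == float(ev)


class TestParseProteinHits:
    LINE = "q1\ts1\t87.5\t200\t25\t1\t1\t200\t5\t204\t1e-50\t210.5\n"

    def test_empty_stream(self):
        assert formats.parse_protein_hits(io.StringIO("")) == []

    def test_single_line_values(self):
        (hit,) = formats.parse_protein_hits(io.StringIO(self.LINE))
        assert hit.e_value == 1e-50
        assert hit.bit_score == 210.5
        assert hit.percent_identity == 87.5

    def test_duplicate_alignments_preserved(self):
        hits = formats.parse_protein_hits(io.StringIO(self.LINE + self.LINE))
        assert len(hits) == 2

    def test_wrong_column_count(self):
        with pytest.raises(ParseError, match="line 1.*12 columns"):
            formats.parse_protein_hits(io.StringIO("a\tb\tc\n"))

    def test_unmapped_subject_error_vs_skip(self):
        with pytest.raises(ParseError, match="no assembly mapping"):
            formats.parse_protein_hits(io.StringIO(self.LINE), protein_to_assembly={})
        with pytest.warns(UserWarning, match="skipped"):
            hits = formats.parse_protein_hits(
                io.StringIO(self.LINE), protein_to_assembly={}, on_unmapped="skip"
            )
        assert hits == []


class TestParseHmmHits:
    LINE = (
        "t1 - modelA - 3.2e-40 87.2 0.1 1e-39 86.0 0.1 "
        "1.0 1 0 0 0 1 1 1 1 description here\n"
    )

    def test_empty_and_comments(self):
        assert formats.parse_hmm_hits(io.StringIO("")) == []
        assert formats.parse_hmm_hits(io.StringIO("#only\n#comments\n")) == []

    def test_record_extraction(self):
        (hit,) = formats.parse_hmm_hits(io.StringIO(self.LINE))
        assert hit.query_id == "modelA"
        assert hit.subject_id == "t1"
        assert hit.bit_score == 87.2
        assert hit.e_value == 3.2e-40
        assert hit.percent_identity is None


class TestClusterMap:
    def test_grouping_with_self_membership(self):
        cmap = formats.parse_cluster_map(io.StringIO("A\tA\nA\tB\nC\tC\n"))
        assert cmap.assignments == {"A": frozenset("AB"), "C": frozenset("C")}

    def test_empty(self):
        assert formats.parse_cluster_map(io.StringIO("")).assignments == {}

    def test_disjointness_violation(self):
        with pytest.raises(ParseError, match="both"):
            formats.parse_cluster_map(io.StringIO("A\tB\nC\tB\n"))

    def test_member_also_other_representative(self):
        with pytest.raises(ParseError):
            formats.parse_cluster_map(io.StringIO("A\tB\nB\tC\n"))

    def test_constructor_enforces_invariants(self):
        with pytest.raises(ValueError, match="not in its own cluster"):
            ClusterMap({"A": frozenset("B")})


class TestNewick:
    def test_four_tips(self):
        tree = formats.parse_newick("((A,B),(C,D));")
        assert formats.tip_labels(tree) == {"A", "B", "C", "D"}

    def test_duplicate_tip_error(self):
        with pytest.raises(ParseError, match="duplicate"):
            formats.parse_newick("((A,B),(A,C));")

    def test_unbalanced_parentheses(self):
        with pytest.raises(ParseError):
            formats.parse_newick("((A,B),(C,D;")

    def test_underscores_preserved(self):
        tree = formats.parse_newick("((ASM_1,ASM_2),ASM_3);")
        assert "ASM_1" in formats.tip_labels(tree)

    def test_write_read_round_trip(self):
        text = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.01);"
        tree = formats.parse_newick(text)
        again = formats.parse_newick(formats.write_newick(tree))
        assert formats.write_newick(again) == formats.write_newick(tree)


class TestRoundTrips:
    """parse(write(x)) == x on seeded random instances."""

    def test_rna_hits(self):
        rng = np.random.default_rng(101)
        for _ in range(100):
            hits = [
                make_rna_hit(
                    bit=round(float(rng.uniform(10, 500)), 1),
                    trunc=str(rng.choice(["no", "5'", "3'", "5'&3'"])),
                    assembly=f"ASM_{rng.integers(0, 20):03d}",
                    target=f"ASM_X|ctg{i}",
                    e_value=float(10.0 ** rng.uniform(-80, -2)),
                    seq_from=int(rng.integers(1, 10000)),
                    seq_to=int(rng.integers(1, 10000)),
                    strand=Strand.PLUS if rng.random() < 0.5 else Strand.MINUS,
                )
                for i in range(int(rng.integers(0, 6)))
            ]
            buf = io.StringIO()
            formats.write_rna_hits(hits, buf)
            parsed = formats.parse_rna_hits(
                io.StringIO(buf.getvalue()),
                assembly_of={h.target_seq_id: h.assembly_id for h in hits},
            )
            assert parsed == hits

    def test_protein_hits(self):
        rng = np.random.default_rng(102)
        for _ in range(100):
            hits = [
                make_protein_hit(
                    query=f"q{rng.integers(0, 5)}",
                    subject=f"s{i}",
                    assembly=f"ASM_{rng.integers(0, 9)}",
                    e_value=float(10.0 ** rng.uniform(-100, -1)),
                    bit=round(float(rng.uniform(20, 900)), 1),
                    pident=round(float(rng.uniform(0, 100)), 1),
                )
                for i in range(int(rng.integers(0, 6)))
            ]
            buf = io.StringIO()
            formats.write_protein_hits(hits, buf)
            parsed = formats.parse_protein_hits(
                io.StringIO(buf.getvalue()),
                protein_to_assembly={h.subject_id: h.subject_assembly_id for h in hits},
            )
            assert parsed == hits

    def test_hmm_hits(self):
        hits = [
            ProteinHit("modelA", f"t{i}", f"ASM_{i}", bit_score=50.0 + i, e_value=10.0**-i)
            for i in range(1, 5)
        ]
        buf = io.StringIO()
        formats.write_hmm_hits(hits, buf)
        parsed = formats.parse_hmm_hits(
            io.StringIO(buf.getvalue()),
            protein_to_assembly={h.subject_id: h.subject_assembly_id for h in hits},
        )
        assert parsed == hits

    def test_cluster_map(self):
        rng = np.random.default_rng(103)
        for _ in range(100):
            n_clusters = int(rng.integers(1, 6))
            assignments, counter = {}, 0
            for c in range(n_clusters):
                size = int(rng.integers(1, 7))
                members = [f"p{counter + i}" for i in range(size)]
                counter += size
                assignments[members[0]] = frozenset(members)
            cmap = ClusterMap(assignments)
            buf = io.StringIO()
            formats.write_cluster_map(cmap, buf)
            assert formats.parse_cluster_map(io.StringIO(buf.getvalue())) == cmap

    def test_presence_matrix(self):
        import pandas as pd

        rng = np.random.default_rng(104)
        for _ in range(100):
            nr, nc = int(rng.integers(1, 8)), int(rng.integers(1, 6))
            matrix = pd.DataFrame(
                rng.integers(0, 5, size=(nr, nc)),
                index=pd.Index([f"ASM_{i}" for i in range(nr)], name="assembly_id"),
                columns=[f"fam_{j}" for j in range(nc)],
            )
            buf = io.StringIO()
            formats.write_presence_matrix(matrix, buf)
            parsed = formats.read_presence_matrix(io.StringIO(buf.getvalue()))
            assert parsed.equals(matrix)

    def test_taxonomy_and_id_map(self):
        records = {
            "ASM_1": TaxonRecord("ASM_1", "Bacillota", "Bacilli"),
            "ASM_2": TaxonRecord("ASM_2", "Pseudomonadota", "Gammaproteobacteria"),
        }
        buf = io.StringIO()
        formats.write_taxonomy(records, buf)
        assert formats.read_taxonomy(io.StringIO(buf.getvalue())) == records

        mapping = {"p1": "ASM_1", "p2": "ASM_2"}
        buf = io.StringIO()
        formats.write_id_map(mapping, buf)
        assert formats.read_id_map(io.StringIO(buf.getvalue())) == mapping


class TestCommentTolerance:
    """Prepending comments/blank lines never changes a parse result."""

    PREFIX = "# comment\n\n   \n# another\n"

    def test_all_line_parsers(self):
        cases = [
            (formats.parse_rna_hits, _tblout_line()),
            (formats.parse_protein_hits, TestParseProteinHits.LINE),
            (formats.parse_hmm_hits, TestParseHmmHits.LINE),
            (formats.parse_cluster_map, "A\tA\nA\tB\n"),
            (formats.read_id_map, "p1\tASM_1\n"),
        ]
        for parser, body in cases:
            plain = parser(io.StringIO(body))
            prefixed = parser(io.StringIO(self.PREFIX + body))
            assert prefixed == plain


class TestDomainTypeInvariants:
    def test_rna_hit_rejects_bad_values(self):
        with pytest.raises(ValueError):
            make_rna_hit(bit=float("nan"))
        with pytest.raises(ValueError):
            make_rna_hit(bit=100.0, e_value=-1.0)
        with pytest.raises(ValueError):
            make_rna_hit(bit=100.0, seq_from=0)

    def test_protein_hit_rejects_bad_values(self):
        with pytest.raises(ValueError):
            make_protein_hit(e_value=-1e-10)
        with pytest.raises(ValueError):
            make_protein_hit(pident=120.0)
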