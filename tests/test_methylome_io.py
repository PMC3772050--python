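"""Context annotation, pseudo-genome construction and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmrkit import (
    Genome,
    MethylomeTable,
    SNPRecord,
    annotate_contexts,
    build_pseudo_genome,
    context_frame,
    read_cytosine_table,
    read_features,
    write_cytosine_table,
)

dna = st.text(alphabet="ACGT", min_size=3, max_size=60)


class TestAnnotateContexts:
    @pytest.mark.parametrize(
        "seq, pos, strand, context",
        [
            ("ACGTT", 1, "+", "CG"),
            ("ACAGT", 1, "+", "CHG"),
            ("ACTTT", 1, "+", "CHH"),
            ("TTCGAA", 3, "-", "CG"),  # G read as C on the reverse complement
            ("TTGAA", 2, "-", "CHH"),
            ("CTGAA", 2, "-", "CHG"),
        ],
    )
    def test_context_rules(self, seq, pos, strand, context):
        ctx = annotate_contexts(Genome({"c": seq}))
        assert ctx[("c", pos, strand)] == context

    def test_edge_cytosines_skipped_when_unresolvable(self):
        # trailing C has no following base; C before N has undefined H
        ctx = annotate_contexts(Genome({"c": "ACNTC"}))
        assert ("c", 4, "+") not in ctx
        assert ("c", 1, "+") not in ctx
        # but a C directly followed by G is CG even at position L-2
        ctx2 = annotate_contexts(Genome({"c": "ACG"}))
        assert ctx2[("c", 1, "+")] == "CG"

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            Genome({})
        with pytest.raises(ValueError):
            Genome({"c": "ACXT"})

    @given(dna)
    def test_reverse_complement_mirror(self, seq):
        """Annotating the reverse complement mirrors positions and strands."""
        from Bio.Seq import Seq

        fwd = annotate_contexts(Genome({"c": seq}))
        rc = annotate_contexts(Genome({"c": str(Seq(seq).reverse_complement())}))
        L = len(seq)
        mirrored = {
            ("c", L - 1 - p, "+" if s == "-" else "-"): ctx
            for (_, p, s), ctx in rc.items()
        }
        assert fwd == mirrored

    @given(dna)
    def test_cg_contexts_palindromic(self, seq):
        frame = context_frame(Genome({"c": seq}))
        cg = frame[frame["context"] == "CG"]
        assert (cg["strand"] == "+").sum() == (cg["strand"] == "-").sum()


class TestPseudoGenome:
    def test_single_substitution(self):
        g = Genome({"c": "ACGT"})
        out = build_pseudo_genome(g, [SNPRecord("c", 2, "G", "A")])
        assert out["c"] == "ACAT"
        assert g["c"] == "ACGT"  # input untouched

    def test_empty_snp_list_is_identity(self):
        g = Genome({"c": "ACGT"})
        assert build_pseudo_genome(g, [])["c"] == "ACGT"

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="c:2"):
            build_pseudo_genome(Genome({"c": "ACGT"}), [SNPRecord("c", 2, "T", "A")])

    def test_duplicate_snp_rejected(self):
        g = Genome({"c": "ACGT"})
        snps = [SNPRecord("c", 2, "G", "A"), SNPRecord("c", 2, "G", "T")]
        with pytest.raises(ValueError, match="duplicate"):
            build_pseudo_genome(g, snps)

    def test_round_trip_swapping_ref_alt(self):
        g = Genome({"c": "ACGTACGT"})
        snps = [SNPRecord("c", 2, "G", "A"), SNPRecord("c", 5, "C", "T")]
        fwd = build_pseudo_genome(g, snps)
        back = build_pseudo_genome(
            fwd, [SNPRecord(s.chrom, s.pos, s.alt_base, s.ref_base) for s in snps]
        )
        assert back.sequences == g.sequences


class TestCytosineTable:
    def test_file_line_parsed_to_zero_based(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("Chr1\t2\t+\t5\t5\tCG\tCGT\n")
        table = read_cytosine_table(path)
        rec = next(iter(table))
        assert (rec.chrom, rec.pos, rec.strand) == ("Chr1", 1, "+")
        assert (rec.n_meth, rec.n_unmeth, rec.context) == (5, 5, "CG")

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_cytosine_table(path)) == 0

    def test_malformed_and_negative_lines_report_line_number(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("Chr1\t2\t+\t5\t5\tCG\tCGT\nChr1\tXX\t+\t1\t1\tCG\tCGT\n")
        with pytest.raises(ValueError, match="line 2"):
            read_cytosine_table(bad)
        neg = tmp_path / "neg.tsv"
        neg.write_text("Chr1\t2\t+\t-1\t5\tCG\tCGT\n")
        with pytest.raises(ValueError, match="line 1"):
            read_cytosine_table(neg)

    def test_round_trip(self, tmp_path, small_genome):
        frame = context_frame(small_genome)
        rng = np.random.default_rng(0)
        frame["n_meth"] = rng.integers(0, 10, len(frame))
        frame["n_unmeth"] = rng.integers(0, 10, len(frame))
        table = MethylomeTable("s", frame)
        path = tmp_path / "round.tsv"
        write_cytosine_table(table, path, genome=small_genome)
        back = read_cytosine_table(path, genome=small_genome, sample_id="s")
        pd.testing.assert_frame_equal(table.data, back.data)

    def test_context_mismatch_detected_when_strict(self, tmp_path, small_genome):
        path = tmp_path / "m.tsv"
        # Chr1 pos 1 (0-based) is CG on + strand; mislabel as CHH
        path.write_text("Chr1\t2\t+\t5\t5\tCHH\tCTT\n")
        with pytest.raises(ValueError, match="context mismatch"):
            read_cytosine_table(path, genome=small_genome, strict_context=True)


class TestReadFeatures:
    def test_bed_native_coordinates(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("Chr1\t100\t200\tgene1\t.\t+\n")
        fs = read_features(path, kind="gene")
        (f,) = fs.features
        assert (f.start, f.end, f.strand, f.kind) == (100, 200, "+", "gene")

    def test_gff3_converted_to_half_open(self, tmp_path):
        path = tmp_path / "f.gff3"
        path.write_text(
            "##gff-version 3\n"
            "Chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gene1\n"
            "Chr1\tsrc\ttransposable_element\t301\t400\t.\t-\t.\tID=te1\n"
        )
        fs = read_features(path)
        by_id = {f.feature_id: f for f in fs}
        assert (by_id["gene1"].start, by_id["gene1"].end) == (100, 200)
        assert by_id["te1"].kind == "TE"

    def test_kind_filter_on_mixed_gff(self, tmp_path):
        path = tmp_path / "f.gff3"
        path.write_text(
            "Chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "Chr1\tsrc\ttransposable_element\t301\t400\t.\t-\t.\tID=t1\n"
        )
        fs = read_features(path, kind="TE")
        assert [f.feature_id for f in fs] == ["t1"]

    def test_unknown_extension_rejected(self, tmp_path):
        path = tmp_path / "f.xyz"
        path.write_text("x")
        with pytest.raises(ValueError, match="unknown annotation format"):
            read_features(path)
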