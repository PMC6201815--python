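import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from netsplice.annotation import (
    AnnotationError,
    ExpressionTable,
    GenomeAnnotation,
    GtfParseError,
    classify_exons,
    expressed_genes,
    expression_threshold,
    label_u12_introns,
    parse_annotation,
    write_exon_table,
)

from conftest import build_gene, write_gtf_file


class TestParseAnnotation:
    def test_minus_strand_three_exons(self, three_exon_minus_gtf):
        ann = parse_annotation(three_exon_minus_gtf)
        (t,) = [t for _, t in ann.transcripts()]
        assert len(t.introns) == 2
        # exon ordinal 0 is the rightmost exon on the minus strand
        assert t.exons[0].start == 600 and t.exons[0].end == 700
        assert t.exons[0].first and t.exons[-1].last
        # 0-based half-open conversion
        assert t.exons[-1].key == ("chr1", "-", 100, 200)

    def test_intron_intervals(self, three_exon_minus_gtf):
        ann = parse_annotation(three_exon_minus_gtf)
        (t,) = [t for _, t in ann.transcripts()]
        # transcription order on '-' means the first intron is the rightmost gap
        assert [(i.start, i.end) for i in t.introns] == [(400, 600), (200, 300)]
        assert t.introns[0].donor == 599 and t.introns[0].acceptor == 400

    def test_single_exon_no_introns(self, tmp_path):
        path = write_gtf_file(
            tmp_path, [("chr1", "exon", 101, 200, "+", "G1", "T1")]
        )
        ann = parse_annotation(path)
        (t,) = [t for _, t in ann.transcripts()]
        assert t.introns == []
        assert t.exons[0].first and t.exons[0].last

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text('chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "G";\nbroken line\n')
        with pytest.raises(GtfParseError, match="line 2"):
            parse_annotation(path)

    def test_non_integer_coordinates(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\ttest\texon\tx\t100\t.\t+\t.\tg\n")
        with pytest.raises(GtfParseError, match="line 1"):
            parse_annotation(path)

    def test_exon_outside_transcript_bounds(self, tmp_path):
        feats = [
            ("chr1", "transcript", 101, 200, "+", "G1", "T1"),
            ("chr1", "exon", 101, 300, "+", "G1", "T1"),
        ]
        with pytest.raises(AnnotationError, match="outside transcript"):
            parse_annotation(write_gtf_file(tmp_path, feats))

    def test_abutting_exons_rejected(self, tmp_path):
        feats = [
            ("chr1", "exon", 101, 200, "+", "G1", "T1"),
            ("chr1", "exon", 201, 300, "+", "G1", "T1"),
        ]
        with pytest.raises(AnnotationError, match="length < 1"):
            parse_annotation(write_gtf_file(tmp_path, feats))


class TestIntronRoundTrip:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exons_plus_introns_reconstruct_span(self, strand):
        g = build_gene(
            "G", "chr1", strand,
            {"T": [(10, 50), (80, 120), (200, 260), (300, 310)]},
        )
        (t,) = g.transcripts
        pieces = sorted(
            [(e.start, e.end) for e in t.exons] + [(i.start, i.end) for i in t.introns]
        )
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2  # no gap, no overlap
        assert pieces[0][0] == t.start and pieces[-1][1] == t.end


class TestClassifyExons:
    def test_skipped_flag(self, skipped_exon_annotation):
        ann = classify_exons(skipped_exon_annotation)
        exons = {e.key: e for e, _ in ann.unique_exons().values()}
        # brute-force oracle: exon B absent from T2 whose intron spans it
        b = exons[("chr1", "+", 300, 400)]
        assert b.skipped and not b.constitutive
        a = exons[("chr1", "+", 100, 200)]
        assert a.constitutive and not a.skipped

    def test_single_isoform_all_constitutive(self):
        ann = GenomeAnnotation(
            [build_gene("G", "chr1", "+", {"T": [(0, 50), (100, 150), (200, 250)]})]
        )
        classify_exons(ann)
        for e, _ in ann.unique_exons().values():
            assert e.constitutive and not e.skipped

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_alt3ss_two_acceptors(self, strand):
        # same donor-side boundary, different acceptor-side boundary
        if strand == "+":
            isoforms = {"T1": [(0, 50), (100, 200)], "T2": [(0, 50), (120, 200)]}
            altkey = ("chr1", strand, 100, 200)
        else:
            isoforms = {"T1": [(100, 200), (250, 300)], "T2": [(100, 180), (250, 300)]}
            altkey = ("chr1", strand, 100, 200)
        ann = GenomeAnnotation([build_gene("G", "chr1", strand, isoforms)])
        classify_exons(ann)
        exons = {e.key: e for e, _ in ann.unique_exons().values()}
        # oracle: enumerate isoform junction sets -> acceptor differs
        assert exons[altkey].alt3ss
        assert not exons[altkey].alt5ss

    def test_alt5ss_two_donors_plus(self):
        isoforms = {"T1": [(0, 100), (200, 250)], "T2": [(0, 80), (200, 250)]}
        ann = GenomeAnnotation([build_gene("G", "chr1", "+", isoforms)])
        classify_exons(ann)
        exons = {e.key: e for e, _ in ann.unique_exons().values()}
        assert exons[("chr1", "+", 0, 100)].alt5ss

    def test_opposite_strand_overlap_not_flagged(self):
        g1 = build_gene("G1", "chr1", "+", {"T1": [(0, 100)]})
        g2 = build_gene("G2", "chr1", "-", {"T2": [(50, 150)]})
        ann = classify_exons(GenomeAnnotation([g1, g2]))
        for e, _ in ann.unique_exons().values():
            assert not e.overlaps_other_exon

    def test_same_strand_overlap_flagged(self):
        g1 = build_gene("G1", "chr1", "+", {"T1": [(0, 100)]})
        g2 = build_gene("G2", "chr1", "+", {"T2": [(50, 150)]})
        ann = classify_exons(GenomeAnnotation([g1, g2]))
        for e, _ in ann.unique_exons().values():
            assert e.overlaps_other_exon

    def test_identical_shared_exon_not_overlap_flagged(self, skipped_exon_annotation):
        ann = classify_exons(skipped_exon_annotation)
        for e, _ in ann.unique_exons().values():
            assert not e.overlaps_other_exon

    def test_order_invariance(self):
        isoforms = {
            "T1": [(0, 50), (100, 200), (300, 350)],
            "T2": [(0, 50), (300, 350)],
            "T3": [(0, 50), (120, 200), (300, 350)],
        }
        flag_sets = []
        for order in itertools.permutations(isoforms):
            ann = GenomeAnnotation(
                [build_gene("G", "chr1", "+", {k: isoforms[k] for k in order})]
            )
            classify_exons(ann)
            flag_sets.append(
                {
                    e.key: (e.constitutive, e.skipped, e.alt5ss, e.alt3ss)
                    for e, _ in ann.unique_exons().values()
                }
            )
        assert all(fs == flag_sets[0] for fs in flag_sets)

    def test_constitutive_skipped_exclusive(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 6))
            exons = [(100 * i, 100 * i + 50) for i in range(n)]
            isoforms = {"T0": exons}
            for j in range(int(rng.integers(1, 3))):
                drop = int(rng.integers(1, n - 1))
                isoforms[f"T{j+1}"] = [e for k, e in enumerate(exons) if k != drop]
            ann = GenomeAnnotation([build_gene("G", "chr1", "+", isoforms)])
            classify_exons(ann)
            for e, _ in ann.unique_exons().values():
                if e.internal:
                    assert not (e.constitutive and e.skipped)


class TestU12Labels:
    def _annotation(self):
        return GenomeAnnotation(
            [build_gene("G", "chr1", "+", {"T": [(100 * i, 100 * i + 50) for i in range(11)]})]
        )

    def test_empty_list_all_u2(self, tmp_path):
        bed = tmp_path / "u12.bed"
        bed.write_text("")
        ann = label_u12_introns(self._annotation(), bed)
        assert all(
            i.spliceosome_class == "U2" for _, t in ann.transcripts() for i in t.introns
        )

    def test_no_matching_interval_all_u2(self, tmp_path):
        bed = tmp_path / "u12.bed"
        bed.write_text("chr9\t1\t2\tx\t0\t+\n")
        ann = label_u12_introns(self._annotation(), bed)
        assert all(
            i.spliceosome_class == "U2" for _, t in ann.transcripts() for i in t.introns
        )

    def test_off_by_one_not_matched_and_warns(self, tmp_path, caplog):
        bed = tmp_path / "u12.bed"
        bed.write_text("chr1\t51\t100\tx\t0\t+\n")  # true intron is (50,100)
        with caplog.at_level(logging.WARNING, logger="netsplice.annotation"):
            ann = label_u12_introns(self._annotation(), bed)
        assert all(
            i.spliceosome_class == "U2" for _, t in ann.transcripts() for i in t.introns
        )
        assert any("matches no annotated intron" in r.message for r in caplog.records)

    def test_one_exact_match_among_ten(self, tmp_path):
        bed = tmp_path / "u12.bed"
        bed.write_text("chr1\t250\t300\tx\t0\t+\n")
        ann = label_u12_introns(self._annotation(), bed)
        classes = [i.spliceosome_class for _, t in ann.transcripts() for i in t.introns]
        assert classes.count("U12") == 1 and len(classes) == 10


class TestExpressedGenes:
    def test_bimodal_threshold_near_zero(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [2.0 ** rng.normal(-5, 1, 400), 2.0 ** rng.normal(5, 1, 400)]
        )
        table = ExpressionTable(pd.Series(vals, index=[f"t{i}" for i in range(800)]))
        thr, fallback = expression_threshold(table)
        assert not fallback
        assert -1.0 <= thr <= 1.0  # dense grid-search oracle: minimum between modes

    def test_identical_fpkm_triggers_fallback(self):
        table = ExpressionTable(pd.Series([2.0, 2.0, 2.0], index=list("abc")))
        thr, fallback = expression_threshold(table)
        assert fallback and thr == 0.0

    def test_any_transcript_rule(self):
        ann = GenomeAnnotation(
            [
                build_gene("G1", "chr1", "+", {"hi": [(0, 50)], "lo": [(0, 50)]}),
                build_gene("G2", "chr1", "+", {"lo2": [(100, 150)]}),
            ]
        )
        rng = np.random.default_rng(1)
        background = pd.Series(
            np.concatenate([2.0 ** rng.normal(-5, 1, 300), 2.0 ** rng.normal(5, 1, 300)]),
            index=[f"bg{i}" for i in range(600)],
        )
        fpkm = pd.concat(
            [background, pd.Series({"hi": 2.0 ** 6, "lo": 2.0 ** -6, "lo2": 2.0 ** -6})]
        )
        call = expressed_genes(ExpressionTable(fpkm), ann)
        assert "G1" in call.gene_ids and "G2" not in call.gene_ids
        assert ann.genes[0].is_expressed and not ann.genes[1].is_expressed


def test_write_exon_table(tmp_path, skipped_exon_annotation):
    df = write_exon_table(skipped_exon_annotation, tmp_path / "exons.tsv")
    assert (tmp_path / "exons.tsv").exists()
    assert df.skipped.sum() == 1
    assert set(df.columns) >= {"gene_id", "transcript_id", "start", "end", "skipped"}
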