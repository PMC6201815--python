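import numpy as np
import pytest

from netsplice.annotation import GenomeAnnotation, classify_exons
from netsplice.reads import AlignedRead
from netsplice.splicing import (
    IntermediateRecord,
    call_splicing_events,
    classify_intermediates,
    compare_groups,
    events_table,
    find_spliced_reads,
    intermediates_table,
    passing_junctions,
)

from conftest import build_gene


@pytest.fixture
def two_exon_annotation():
    """Exons (100,200) and (300,400) on '+', intron (200,300)."""
    return GenomeAnnotation(
        [build_gene("G", "chr1", "+", {"T": [(100, 200), (300, 400)]})]
    )


@pytest.fixture
def three_exon_annotation():
    return GenomeAnnotation(
        [build_gene("G", "chr1", "+", {"T": [(100, 200), (300, 400), (500, 600)]})]
    )


def spliced_read(left=(180, 200), right=(300, 320), strand="+", **kw):
    return AlignedRead("chr1", strand, (left, right), **kw)


class TestFindSplicedReads:
    def test_valid_read_accepted(self, two_exon_annotation):
        out, summary = find_spliced_reads([spliced_read()], two_exon_annotation)
        assert summary.accepted == 1
        (sr,) = out
        assert sr.junction == ("chr1", "+", 200, 300)
        assert sr.overhang_left == 20 and sr.overhang_right == 20

    def test_short_overhang_rejected(self, two_exon_annotation):
        out, summary = find_spliced_reads(
            [spliced_read(left=(192, 200))], two_exon_annotation
        )
        assert out == [] and summary.rejected["short_overhang"] == 1

    def test_nine_nt_overhang_accepted(self, two_exon_annotation):
        out, _ = find_spliced_reads(
            [spliced_read(left=(191, 200))], two_exon_annotation
        )
        assert len(out) == 1

    def test_mismatch_rejected(self, two_exon_annotation):
        out, summary = find_spliced_reads(
            [spliced_read(mismatch_count=1)], two_exon_annotation
        )
        assert out == [] and summary.rejected["mismatch"] == 1

    def test_multimapped_rejected(self, two_exon_annotation):
        out, summary = find_spliced_reads(
            [spliced_read(is_unique=False)], two_exon_annotation
        )
        assert out == [] and summary.rejected["multimapped"] == 1

    def test_unannotated_gap_rejected(self, two_exon_annotation):
        out, summary = find_spliced_reads(
            [spliced_read(right=(310, 330))], two_exon_annotation
        )
        assert out == [] and summary.rejected["unannotated_junction"] == 1

    def test_contiguous_read_not_spliced(self, two_exon_annotation):
        out, summary = find_spliced_reads(
            [AlignedRead("chr1", "+", ((150, 200),))], two_exon_annotation
        )
        assert out == [] and summary.rejected["unspliced"] == 1

    def test_block_subdivision_invariance(self, two_exon_annotation):
        whole = spliced_read(left=(150, 200), right=(300, 350))
        split = AlignedRead(
            "chr1", "+", ((150, 170), (170, 200), (300, 350))
        )
        out1, _ = find_spliced_reads([whole], two_exon_annotation)
        out2, _ = find_spliced_reads([split], two_exon_annotation)
        assert out1[0].junction == out2[0].junction
        assert out1[0].overhang_left == out2[0].overhang_left

    def test_multi_junction_read(self, three_exon_annotation):
        r = AlignedRead("chr1", "+", ((150, 200), (300, 400), (500, 550)))
        out, summary = find_spliced_reads([r], three_exon_annotation)
        assert summary.accepted == 1
        assert {sr.junction for sr in out} == {
            ("chr1", "+", 200, 300),
            ("chr1", "+", 400, 500),
        }

    def test_primer_artifact_filter(self, two_exon_annotation):
        r = spliced_read(sequence="ACGT" * 9 + "TGGA")
        out, summary = find_spliced_reads(
            [r], two_exon_annotation, exclude_primer_artifacts=True
        )
        assert out == [] and summary.rejected["primer_artifact"] == 1
        out, _ = find_spliced_reads([r], two_exon_annotation)
        assert len(out) == 1


class TestSplicingEvents:
    def test_threshold_boundary(self, two_exon_annotation):
        reads = [spliced_read() for _ in range(3)]
        out, _ = find_spliced_reads(reads, two_exon_annotation)
        (ev,) = call_splicing_events(out)
        assert ev.passes and ev.spliced_read_count == 3

    def test_two_reads_fail(self, two_exon_annotation):
        out, _ = find_spliced_reads(
            [spliced_read(), spliced_read()], two_exon_annotation
        )
        (ev,) = call_splicing_events(out)
        assert not ev.passes

    def test_empty_input(self):
        assert call_splicing_events([]) == []

    def test_passing_junctions_set(self, two_exon_annotation):
        out, _ = find_spliced_reads(
            [spliced_read() for _ in range(4)], two_exon_annotation
        )
        assert passing_junctions(call_splicing_events(out)) == {
            ("chr1", "+", 200, 300)
        }


class TestClassifyIntermediates:
    def _records(self, reads, ann):
        return {r.exon_key: r for r in classify_intermediates(reads, ann)}

    def test_sr_ur_ambiguous(self, three_exon_annotation):
        # middle exon (300,400): terminal base 399
        sr = [
            AlignedRead("chr1", "+", ((180, 200), (300, 400))) for _ in range(5)
        ]
        ur = [AlignedRead("chr1", "+", ((280, 400),)) for _ in range(5)]
        amb = [AlignedRead("chr1", "+", ((320, 400),)) for _ in range(2)]
        recs = self._records(sr + ur + amb, three_exon_annotation)
        rec = recs[("chr1", "+", 300, 400)]
        assert (rec.sr, rec.ur, rec.ambiguous) == (5, 5, 2)
        assert rec.spliced_pct == pytest.approx(50.0)

    def test_below_min_total_undefined(self, three_exon_annotation):
        sr = [AlignedRead("chr1", "+", ((180, 200), (300, 400))) for _ in range(4)]
        ur = [AlignedRead("chr1", "+", ((280, 400),)) for _ in range(4)]
        rec = self._records(sr + ur, three_exon_annotation)[("chr1", "+", 300, 400)]
        assert rec.spliced_pct is None

    def test_read_stopping_at_boundary_ambiguous(self, three_exon_annotation):
        r = AlignedRead("chr1", "+", ((300, 400),))  # exactly the exon
        rec = self._records([r], three_exon_annotation)[("chr1", "+", 300, 400)]
        assert rec.ambiguous == 1 and rec.ur == 0

    def test_first_exon_skipped(self, three_exon_annotation):
        r = AlignedRead("chr1", "+", ((150, 200),))  # ends at first exon terminal
        assert self._records([r], three_exon_annotation) == {}

    def test_read_not_at_terminal_ignored(self, three_exon_annotation):
        r = AlignedRead("chr1", "+", ((300, 399),))
        assert self._records([r], three_exon_annotation) == {}

    def test_minus_strand(self):
        # '-' gene: exons (500,600) first, (300,400) middle, terminal base 300
        ann = GenomeAnnotation(
            [build_gene("G", "chr1", "-", {"T": [(100, 200), (300, 400), (500, 600)]})]
        )
        sr = AlignedRead("chr1", "-", ((300, 400), (500, 520)))
        ur = AlignedRead("chr1", "-", ((300, 420),))
        recs = {r.exon_key: r for r in classify_intermediates([sr, ur], ann)}
        rec = recs[("chr1", "-", 300, 400)]
        assert rec.sr == 1 and rec.ur == 1

    def test_short_overhang_sr_becomes_ambiguous(self, three_exon_annotation):
        r = AlignedRead("chr1", "+", ((195, 200), (300, 400)))
        rec = self._records([r], three_exon_annotation)[("chr1", "+", 300, 400)]
        assert rec.ambiguous == 1 and rec.sr == 0

    def test_conservation(self, three_exon_annotation):
        rng = np.random.default_rng(0)
        reads = []
        for _ in range(200):
            kind = rng.integers(0, 3)
            if kind == 0:
                reads.append(AlignedRead("chr1", "+", ((180, 200), (300, 400))))
            elif kind == 1:
                reads.append(AlignedRead("chr1", "+", ((int(rng.integers(250, 300)), 400),)))
            else:
                reads.append(AlignedRead("chr1", "+", ((int(rng.integers(301, 390)), 400),)))
        rec = self._records(reads, three_exon_annotation)[("chr1", "+", 300, 400)]
        assert rec.sr + rec.ur + rec.ambiguous == 200


class TestSplicedPctRecovery:
    def test_simulator_recovery_within_binomial_error(self):
        from netsplice.simulate import SimulationConfig, make_genome, simulate_mnetseq

        cfg = SimulationConfig(
            seed=11, n_genes=50, exons_per_gene=(6, 6),
            exon_length_log_mean=np.log(28), exon_length_log_sd=0.05,
            exon_length_range=(26, 30), intron_length_log_mean=np.log(150),
            intron_length_log_sd=0.3, intron_length_range=(110, 300),
            short_exon_fraction=0, short_intron_fraction=0, skip_fraction=0,
            alt5_fraction=0, alt3_fraction=0, background_lambda=0.0,
            intermediate_rate=50, peak_fraction=1.0, library_mode="long",
            mode_weight=1.0, pause_per_gene=0, n_snrna=0,
        )
        ann, truth = make_genome(cfg)
        reads = simulate_mnetseq(ann, truth, cfg)
        errs = []
        for rec in classify_intermediates(reads, ann):
            t = truth.exons.get(rec.exon_key)
            if t is None or rec.spliced_pct is None:
                continue
            errs.append(abs(rec.spliced_pct - 100 * t.psi_true))
        assert len(errs) > 150
        # binomial sampling floor at ~50 reads/exon is ~4.4 points; 6 bounds
        # the estimator's own error contribution tightly
        assert np.mean(errs) < 6.0


class TestCompareGroups:
    def _annotation(self):
        # one gene with skipped exon, one with constitutive middle exons
        g1 = build_gene(
            "G1", "chr1", "+",
            {"T1": [(0, 50), (100, 150), (200, 250)], "T2": [(0, 50), (200, 250)]},
        )
        g2 = build_gene("G2", "chr1", "+", {"T3": [(1000, 1050), (1100, 1150), (1200, 1250)]})
        return classify_exons(GenomeAnnotation([g1, g2]))

    def _recs(self, const_vals, skip_vals):
        recs = []
        for v in const_vals:
            recs.append(IntermediateRecord(("chr1", "+", 1100, 1150), int(v), int(100 - v), 0))
        for v in skip_vals:
            recs.append(IntermediateRecord(("chr1", "+", 100, 150), int(v), int(100 - v), 0))
        return recs

    def test_extreme_separation_ks_one(self):
        ann = self._annotation()
        cmp = compare_groups(self._recs([100] * 5, [0] * 5), ann)
        assert cmp.ks_stat == pytest.approx(1.0)

    def test_identical_groups(self):
        ann = self._annotation()
        cmp = compare_groups(self._recs([50] * 5, [50] * 5), ann)
        assert cmp.ks_stat == 0.0 and cmp.ks_p == 1.0

    def test_undefined_with_small_group(self):
        ann = self._annotation()
        cmp = compare_groups(self._recs([50, 60], [50]), ann)
        assert not cmp.defined

    def test_planted_beta_difference_significant(self):
        rng = np.random.default_rng(42)
        a = np.round(100 * rng.beta(8, 2, 200))
        b = np.round(100 * rng.beta(2, 8, 200))
        ann = self._annotation()
        cmp = compare_groups(self._recs(a, b), ann)
        assert cmp.location_p < 0.01
        assert cmp.ks_p < 0.01

    def test_u12_grouping(self):
        g = build_gene(
            "G", "chr1", "+",
            {"T": [(0, 50), (100, 150), (200, 250), (300, 350)]},
        )
        ann = GenomeAnnotation([g])
        classify_exons(ann)
        (_, t), = [(gg, tt) for gg, tt in ann.transcripts()]
        t.introns[0].spliceosome_class = "U12"
        recs = [
            IntermediateRecord(("chr1", "+", 100, 150), 80, 20, 0),
            IntermediateRecord(("chr1", "+", 100, 150), 70, 30, 0),
            IntermediateRecord(("chr1", "+", 200, 250), 50, 50, 0),
            IntermediateRecord(("chr1", "+", 200, 250), 40, 60, 0),
        ]
        cmp = compare_groups(recs, ann, grouping="u2_vs_u12")
        assert len(cmp.values["u12_preceded"]) == 2
        assert len(cmp.values["u2_preceded"]) == 2


def test_tables(three_exon_annotation):
    reads = [spliced_read() for _ in range(3)]
    out, _ = find_spliced_reads(reads, three_exon_annotation)
    ev = call_splicing_events(out)
    assert events_table(ev).loc[0, "reads"] == 3
    recs = classify_intermediates(
        [AlignedRead("chr1", "+", ((280, 400),))], three_exon_annotation
    )
    df = intermediates_table(recs)
    assert df.loc[0, "ur"] == 1
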