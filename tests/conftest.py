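import numpy as np
import pytest

from netsplice.annotation import (
    Exon,
    Gene,
    GenomeAnnotation,
    Transcript,
    parse_annotation,
)
from netsplice.coverage import EndCoverage


def gtf_text(features):
    """features: iterable of (chrom, feature, start1, end1, strand, gene_id, tx_id)."""
    lines = []
    for chrom, feature, start, end, strand, gid, tid in features:
        attrs = f'gene_id "{gid}";'
        if tid:
            attrs += f' transcript_id "{tid}";'
        lines.append(
            f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"


def write_gtf_file(tmp_path, features, name="test.gtf"):
    path = tmp_path / name
    path.write_text(gtf_text(features))
    return path


def build_transcript(tid, chrom, strand, exon_intervals):
    t = Transcript(tid, chrom, strand, [Exon(chrom, s, e, strand) for s, e in exon_intervals])
    t._finalize()
    return t


def build_gene(gid, chrom, strand, isoforms, expressed=True):
    """isoforms: dict tx_id -> list of (start, end)."""
    g = Gene(
        gid, chrom, strand,
        [build_transcript(tid, chrom, strand, ivs) for tid, ivs in isoforms.items()],
        is_expressed=expressed,
    )
    return g


def single_exon_genome(n, length, counts_fn, gap=50, strand="+", chrom="chrT"):
    """n single-exon genes tiled on one chromosome plus coverage from counts_fn(i)."""
    genes = []
    cov = EndCoverage()
    pos = 0
    for i in range(n):
        genes.append(
            build_gene(f"g{i}", chrom, strand, {f"t{i}": [(pos, pos + length)]})
        )
        cov.add_array(chrom, strand, pos, counts_fn(i))
        pos += length + gap
    return GenomeAnnotation(genes), cov


@pytest.fixture
def three_exon_minus_gtf(tmp_path):
    """Single-transcript gene, 3 exons, minus strand (1-based GTF coords)."""
    feats = [
        ("chr1", "gene", 101, 700, "-", "G1", None),
        ("chr1", "transcript", 101, 700, "-", "G1", "T1"),
        ("chr1", "exon", 101, 200, "-", "G1", "T1"),
        ("chr1", "exon", 301, 400, "-", "G1", "T1"),
        ("chr1", "exon", 601, 700, "-", "G1", "T1"),
    ]
    return write_gtf_file(tmp_path, feats)


@pytest.fixture
def skipped_exon_annotation():
    """Two isoforms: T1 has exons A,B,C; T2 skips B."""
    g = build_gene(
        "G1", "chr1", "+",
        {
            "T1": [(100, 200), (300, 400), (500, 600)],
            "T2": [(100, 200), (500, 600)],
        },
    )
    return GenomeAnnotation([g])


def rng(seed=0):
    return np.random.default_rng(seed)
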