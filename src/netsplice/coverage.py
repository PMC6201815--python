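"""Strand-specific single-nucleotide 3'-end coverage and derived statistics.

The central object is :class:`EndCoverage`: a sparse per-(chromosome,
strand) map from position to the number of read 3'-most transcribed bases
at that position, plus the library total used for RPM scaling.  On top of
it sit read-length (footprint) histograms, snRNA class counts, read
average density (RAD), treatment-sensitivity ratios and metagene profiles.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import Exon, GenomeAnnotation, Intron
from .reads import AlignedRead

log = logging.getLogger(__name__)

Region = tuple[str, str, int, int]  # chrom, strand, start, end (half-open)


class EndCoverage:
    """Sparse counts of read 3'-end positions per (chromosome, strand)."""

    def __init__(self, library_total: int = 0):
        self._counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
        self.library_total = library_total
        self.n_skipped_multimapped = 0

    # ---- construction -----------------------------------------------------
    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead]) -> "EndCoverage":
        """Count the 3'-most transcribed base of each accepted read.

        Multi-mapped reads are excluded everywhere; ``library_total`` is
        the number of accepted (unique) reads, so total counts equal the
        library total exactly.
        """
        cov = cls()
        for r in reads:
            if not r.blocks:
                log.warning("read %s has zero blocks; skipped", r.name)
                continue
            if not r.is_unique:
                cov.n_skipped_multimapped += 1
                continue
            cov.add_end(r.chrom, r.strand, r.three_prime_end)
        return cov

    @classmethod
    def from_array(
        cls,
        chrom: str,
        strand: str,
        start: int,
        values: Sequence[int],
        library_total: int | None = None,
    ) -> "EndCoverage":
        cov = cls()
        cov.add_array(chrom, strand, start, values)
        if library_total is not None:
            cov.library_total = library_total
        return cov

    def add_end(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        self._counts[(chrom, strand)][pos] += count
        self.library_total += count

    def add_array(
        self, chrom: str, strand: str, start: int, values: Sequence[int]
    ) -> None:
        c = self._counts[(chrom, strand)]
        total = 0
        for off, v in enumerate(values):
            v = int(v)
            if v > 0:
                c[start + off] += v
                total += v
        self.library_total += total

    # ---- queries ----------------------------------------------------------
    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense count vector over [start, end), genomic order."""
        c = self._counts.get((chrom, strand))
        out = np.zeros(end - start, dtype=np.int64)
        if not c:
            return out
        if len(c) < (end - start):
            for pos, v in c.items():
                if start <= pos < end:
                    out[pos - start] = v
        else:
            for off in range(end - start):
                out[off] = c.get(start + off, 0)
        return out

    def region_total(self, regions: Iterable[Region]) -> int:
        total = 0
        for chrom, strand, start, end in regions:
            c = self._counts.get((chrom, strand))
            if not c:
                continue
            if len(c) < (end - start):
                total += sum(v for p, v in c.items() if start <= p < end)
            else:
                total += sum(c.get(p, 0) for p in range(start, end))
        return total

    def total_counts(self) -> int:
        return sum(sum(c.values()) for c in self._counts.values())

    def rpm(self, count: float) -> float:
        if self.library_total == 0:
            return 0.0
        return count / self.library_total * 1e6

    # ---- export -----------------------------------------------------------
    def to_bedgraph(self, plus_path: str | Path, minus_path: str | Path) -> None:
        for strand, path in (("+", plus_path), ("-", minus_path)):
            with open(path, "w") as out:
                items = []
                for (chrom, s), counts in self._counts.items():
                    if s != strand:
                        continue
                    for pos, v in counts.items():
                        items.append((chrom, pos, v))
                for chrom, pos, v in sorted(items):
                    out.write(f"{chrom}\t{pos}\t{pos + 1}\t{v}\n")


def extract_three_prime_ends(reads: Iterable[AlignedRead]) -> EndCoverage:
    """Alias for :meth:`EndCoverage.from_reads` matching the pipeline verb."""
    return EndCoverage.from_reads(reads)


# ---------------------------------------------------------------------------
# Footprint length histogram
# ---------------------------------------------------------------------------

@dataclass
class LengthHistogram:
    counts: Counter = field(default_factory=Counter)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def modal_length(self) -> int | None:
        if not self.counts:
            return None
        best = max(self.counts.values())
        return min(l for l, c in self.counts.items() if c == best)

    def fraction_in_range(self, lo: int, hi: int) -> float:
        """Proportion of reads with lo <= length <= hi (inclusive bounds)."""
        if self.n == 0:
            return 0.0
        return sum(c for l, c in self.counts.items() if lo <= l <= hi) / self.n


def read_length_histogram(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    window: tuple[int, int] = (0, 150),
    min_first_exon_length: int = 200,
) -> LengthHistogram:
    """Length histogram of reads whose 3' end falls in a TSS-anchored window.

    The window is given in transcription-direction offsets from the TSS,
    inclusive at both ends (the default (0, 150) covers the first 150 nt
    of qualifying first exons; a read ending at +151 is excluded).  Only
    first exons at least ``min_first_exon_length`` nt long qualify.
    """
    lo, hi = window
    eligible: set[tuple[str, str, int]] = set()
    seen: set = set()
    for _, t in annotation.transcripts():
        e = t.exons[0]
        if e.length < min_first_exon_length or e.key in seen:
            continue
        seen.add(e.key)
        tss = e.five_prime_pos
        for off in range(lo, hi + 1):
            pos = tss + off if e.strand == "+" else tss - off
            eligible.add((e.chrom, e.strand, pos))
    hist = LengthHistogram()
    for r in reads:
        if not r.is_unique:
            continue
        if (r.chrom, r.strand, r.three_prime_end) in eligible:
            hist.counts[r.aligned_length] += 1
    if not eligible:
        log.warning("no first exon of length >= %d", min_first_exon_length)
    return hist


# ---------------------------------------------------------------------------
# snRNA class counts
# ---------------------------------------------------------------------------

SnrnaGene = tuple[str, str, int, int, str]  # name, chrom, start, end, strand


@dataclass
class SnrnaResult:
    class_rpm: dict[str, float]
    per_gene_rpm: dict[str, float]
    expressed: set[str]


def count_snrna(
    coverage: EndCoverage,
    snrna_sets: dict[str, list[SnrnaGene]],
    pad: int = 5,
    reference: EndCoverage | None = None,
    min_log2_rpm: float = 1.0,
) -> SnrnaResult:
    """Per-class RPM over expressed snRNA genes.

    Gene intervals are padded by ``pad`` nt on both sides to absorb
    annotation uncertainty.  A gene is expressed when log2(RPM) in the
    reference sample (default: the sample itself) reaches
    ``min_log2_rpm``; class RPM sums expressed members only.
    """
    if reference is None:
        reference = coverage
    per_gene_rpm: dict[str, float] = {}
    expressed: set[str] = set()
    class_rpm: dict[str, float] = {}
    for cls_name, genes in snrna_sets.items():
        if not genes:
            log.warning("snRNA class %s has no genes", cls_name)
            class_rpm[cls_name] = 0.0
            continue
        total = 0.0
        for name, chrom, start, end, strand in genes:
            region = [(chrom, strand, start - pad, end + pad)]
            ref_rpm = reference.rpm(reference.region_total(region))
            if ref_rpm > 0 and np.log2(ref_rpm) >= min_log2_rpm:
                expressed.add(name)
                gene_rpm = coverage.rpm(coverage.region_total(region))
                per_gene_rpm[name] = gene_rpm
                total += gene_rpm
        class_rpm[cls_name] = total
    return SnrnaResult(class_rpm=class_rpm, per_gene_rpm=per_gene_rpm, expressed=expressed)


# ---------------------------------------------------------------------------
# Read average density
# ---------------------------------------------------------------------------

@dataclass
class DensityRecord:
    chrom: str
    strand: str
    start: int
    end: int
    kind: str  # "exon" | "intron"
    tr: int  # total reads after trimming and spliced-read removal
    el: int  # feature length, nt
    rad: float  # tr / (el - 3)


def read_average_density(
    coverage: EndCoverage,
    feature: Exon | Intron,
    spliced_ends: EndCoverage | None = None,
) -> DensityRecord | None:
    """RAD = TR / (EL - 3) for one exon or intron; None when excluded.

    For exons the 3 transcription-3'-most positions are trimmed (5' ss
    intermediates pile up there) and 3'-end counts contributed by spliced
    reads are subtracted; for introns the 3 transcription-5'-most
    positions are trimmed.  Features with EL <= 3 or no remaining reads
    are excluded.
    """
    el = feature.length
    if el <= 3:
        return None
    kind = "exon" if isinstance(feature, Exon) else "intron"
    vec = coverage.window(feature.chrom, feature.strand, feature.start, feature.end)
    if kind == "exon":
        trim = (
            range(el - 3, el) if feature.strand == "+" else range(0, 3)
        )  # transcription-direction last 3
    else:
        trim = (
            range(0, 3) if feature.strand == "+" else range(el - 3, el)
        )  # transcription-direction first 3
    keep = np.ones(el, dtype=bool)
    keep[list(trim)] = False
    counts = vec.copy()
    if kind == "exon" and spliced_ends is not None:
        sub = spliced_ends.window(
            feature.chrom, feature.strand, feature.start, feature.end
        )
        counts = np.maximum(counts - sub, 0)
    tr = int(counts[keep].sum())
    if tr <= 0:
        return None
    return DensityRecord(
        chrom=feature.chrom,
        strand=feature.strand,
        start=feature.start,
        end=feature.end,
        kind=kind,
        tr=tr,
        el=el,
        rad=tr / (el - 3),
    )


# ---------------------------------------------------------------------------
# Treatment sensitivity
# ---------------------------------------------------------------------------

def treatment_ratio(
    a: EndCoverage,
    b: EndCoverage,
    regions: dict[str, list[Region]],
) -> dict[str, float | None]:
    """Per region set, ratio of RPM in library b over library a.

    A zero-RPM denominator yields ``None`` (undefined), never 0.
    """
    out: dict[str, float | None] = {}
    for name, region_list in regions.items():
        rpm_a = a.rpm(a.region_total(region_list))
        rpm_b = b.rpm(b.region_total(region_list))
        out[name] = None if rpm_a == 0 else rpm_b / rpm_a
    return out


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------

Anchor = tuple[str, int, str]  # chrom, position, strand


def metagene_profile(
    coverage: EndCoverage,
    anchors: Sequence[Anchor],
    window: tuple[int, int] = (100, 100),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean RPM per transcription-direction offset around anchors.

    Returns (offsets, values) with offsets -upstream..+downstream.
    Anchors closer than the window to the contig start are skipped.
    """
    up, down = window
    offsets = np.arange(-up, down + 1)
    acc = np.zeros(len(offsets), dtype=float)
    used = 0
    for chrom, pos, strand in anchors:
        if strand == "+":
            start = pos - up
            if start < 0:
                continue
            vec = coverage.window(chrom, strand, start, pos + down + 1)
        else:
            start = pos - down
            if start < 0:
                continue
            vec = coverage.window(chrom, strand, start, pos + up + 1)[::-1]
        acc += vec
        used += 1
    if used == 0:
        return offsets, np.zeros(len(offsets))
    return offsets, np.array([coverage.rpm(v) for v in acc / used])
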