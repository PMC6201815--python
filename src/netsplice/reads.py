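"""Aligned-read model and SAM / BED12 readers and writers.

Reads carry the strand of the *transcribed RNA*.  Library chemistry is
resolved at read time through the ``strandness`` flag: with the default
``"reverse"`` the RNA strand is the opposite of the alignment strand
(common for NET-seq style libraries); with ``"forward"`` they coincide.
Writers apply the same convention symmetrically, so a write/read round
trip with matching strandness is the identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

log = logging.getLogger(__name__)

STRANDNESS_VALUES = ("forward", "reverse")


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def merge_blocks(blocks: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Coalesce abutting blocks so block structure reflects junctions only."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass
class AlignedRead:
    chrom: str
    strand: str  # strand of the transcribed RNA
    blocks: tuple[tuple[int, int], ...]  # ordered, non-overlapping, 0-based half-open
    mismatch_count: int = 0
    is_unique: bool = True
    name: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        for (s, e) in self.blocks:
            if e <= s:
                raise ValueError(f"empty alignment block ({s},{e})")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("alignment blocks overlap or are unordered")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def three_prime_end(self) -> int:
        """Genomic position of the RNA 3'-most transcribed base."""
        if self.strand == "+":
            return self.blocks[-1][1] - 1
        return self.blocks[0][0]

    def merged(self) -> "AlignedRead":
        m = merge_blocks(self.blocks)
        if m == self.blocks:
            return self
        return AlignedRead(
            self.chrom, self.strand, m, self.mismatch_count, self.is_unique,
            self.name, self.sequence,
        )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Reference blocks separated only by N (splice) operations."""
    blocks: list[tuple[int, int]] = []
    ref = pos
    cur_start = None
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            if cur_start is None:
                cur_start = ref
            ref += length
        elif op == 2:  # D consumes reference but is not a junction
            if cur_start is None:
                cur_start = ref
            ref += length
        elif op == 3:  # N: splice junction
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
            ref += length
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, ref))
    return tuple(blocks)


def read_sam(path: str | Path, strandness: str = "reverse") -> Iterator[AlignedRead]:
    if strandness not in STRANDNESS_VALUES:
        raise ValueError(f"strandness must be one of {STRANDNESS_VALUES}")
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks = _blocks_from_cigar(aln.reference_start, aln.cigartuples or [])
            if not blocks:
                log.warning("read %s has no aligned blocks; skipped", aln.query_name)
                continue
            align_strand = "-" if aln.is_reverse else "+"
            rna_strand = (
                align_strand if strandness == "forward" else _flip(align_strand)
            )
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            else:
                unique = aln.mapping_quality > 3
            yield AlignedRead(
                chrom=aln.reference_name,
                strand=rna_strand,
                blocks=blocks,
                mismatch_count=int(nm),
                is_unique=bool(unique),
                name=aln.query_name,
            )


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    chrom_sizes: dict[str, int],
    strandness: str = "reverse",
) -> int:
    if strandness not in STRANDNESS_VALUES:
        raise ValueError(f"strandness must be one of {STRANDNESS_VALUES}")
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name or f"read{i}"
            written_strand = (
                r.strand if strandness == "forward" else _flip(r.strand)
            )
            a.flag = 16 if written_strand == "-" else 0
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 255 if r.is_unique else 0
            cig = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cig.append((3, s - prev_end))
                cig.append((0, e - s))
                prev_end = e
            a.cigartuples = cig
            if r.sequence is not None:
                a.query_sequence = r.sequence
            a.set_tag("NM", int(r.mismatch_count))
            a.set_tag("NH", 1 if r.is_unique else 2)
            out.write(a)
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def read_bed12(path: str | Path, strandness: str = "reverse") -> Iterator[AlignedRead]:
    """Blocked BED reader.

    The score column carries the mismatch count (as written by
    :func:`write_bed12`); reads are assumed uniquely mapped since BED has
    no multi-mapping field.
    """
    if strandness not in STRANDNESS_VALUES:
        raise ValueError(f"strandness must be one of {STRANDNESS_VALUES}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED fields")
            chrom, chrom_start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            rna_strand = f[5] if strandness == "forward" else _flip(f[5])
            yield AlignedRead(
                chrom=chrom,
                strand=rna_strand,
                blocks=blocks,
                mismatch_count=int(f[4]),
                is_unique=True,
                name=f[3],
            )


def write_bed12(
    reads: Iterable[AlignedRead], path: str | Path, strandness: str = "reverse"
) -> int:
    if strandness not in STRANDNESS_VALUES:
        raise ValueError(f"strandness must be one of {STRANDNESS_VALUES}")
    n = 0
    with open(path, "w") as out:
        for i, r in enumerate(reads):
            written_strand = (
                r.strand if strandness == "forward" else _flip(r.strand)
            )
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - r.start) for s, e in r.blocks)
            out.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom, r.start, r.end, r.name or f"read{i}",
                        r.mismatch_count, written_strand, r.start, r.end, "0",
                        len(r.blocks), sizes, starts,
                    )
                )
                + "\n"
            )
            n += 1
    return n


def read_alignments(
    path: str | Path, strandness: str = "reverse"
) -> Iterator[AlignedRead]:
    """Dispatch on file extension (.sam/.bam vs .bed/.bed12)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam"):
        return read_sam(path, strandness=strandness)
    if suffix in (".bed", ".bed12"):
        return read_bed12(path, strandness=strandness)
    raise ValueError(f"unrecognized alignment format: {path}")
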