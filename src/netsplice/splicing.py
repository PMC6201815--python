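"""Spliced-read detection, splicing events, and 5' ss intermediate classification.

A spliced read aligns uniquely with no mismatch, every block gap matches
an annotated intron, and at least 9 nt align on each side of every
junction it spans.  A splicing event passes with >= 3 supporting reads.

5' ss intermediate reads end exactly at an exon's 3'-terminal base; they
are spliced (SR) when ligated across the exon's upstream junction,
unspliced (UR) when contiguously extending into the upstream intron, and
ambiguous when informative of neither (e.g. fully exon-contained).
spliced% = 100 * SR / (SR + UR), defined when SR + UR >= 10.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ExonKey, GenomeAnnotation, IntronKey
from .reads import AlignedRead

log = logging.getLogger(__name__)

DEFAULT_MIN_OVERHANG = 9  # "more than 8 nucleotides across any junction"
DEFAULT_MIN_EVENT_READS = 3
DEFAULT_MIN_TOTAL = 10
DEFAULT_PRIMER_SIGNATURES = ("TGGA", "AGAT")


@dataclass
class SplicedRead:
    read: AlignedRead
    junction: IntronKey  # (chrom, strand, intron start, intron end)
    overhang_left: int
    overhang_right: int


@dataclass
class SplicingEvent:
    junction: IntronKey
    spliced_read_count: int
    passes: bool


@dataclass
class IntermediateRecord:
    exon_key: ExonKey
    sr: int
    ur: int
    ambiguous: int
    min_total: int = DEFAULT_MIN_TOTAL

    @property
    def candidates(self) -> int:
        return self.sr + self.ur + self.ambiguous

    @property
    def spliced_pct(self) -> float | None:
        if self.sr + self.ur < self.min_total:
            return None
        return 100.0 * self.sr / (self.sr + self.ur)


def _junction_spans(
    read: AlignedRead,
    junctions: set[IntronKey],
    min_overhang: int,
) -> list[IntronKey] | None:
    """Junctions a read validly spans, or None if any gap disqualifies it.

    Blocks are merged first so that block subdivision without change of
    aligned bases cannot affect the outcome.
    """
    blocks = read.merged().blocks
    if len(blocks) < 2:
        return []
    spanned: list[IntronKey] = []
    lengths = [e - s for s, e in blocks]
    for i, ((_, gap_start), (gap_end, _)) in enumerate(zip(blocks, blocks[1:])):
        key = (read.chrom, read.strand, gap_start, gap_end)
        if key not in junctions:
            return None
        left = sum(lengths[: i + 1])
        right = sum(lengths[i + 1 :])
        if min(left, right) < min_overhang:
            return None
        spanned.append(key)
    return spanned


@dataclass
class SplicedReadSummary:
    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)


def find_spliced_reads(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    exclude_primer_artifacts: bool = False,
    primer_signatures: Sequence[str] = DEFAULT_PRIMER_SIGNATURES,
) -> tuple[list[SplicedRead], SplicedReadSummary]:
    """Spliced reads (one record per junction spanned) plus rejection tallies.

    With ``exclude_primer_artifacts`` set, reads whose 3'-terminal 4 nt
    match a primer signature are dropped (requires read sequences).
    """
    junctions = annotation.junction_set()
    out: list[SplicedRead] = []
    summary = SplicedReadSummary()
    for r in reads:
        if not r.is_unique:
            summary.rejected["multimapped"] += 1
            continue
        if r.mismatch_count != 0:
            summary.rejected["mismatch"] += 1
            continue
        merged = r.merged()
        if len(merged.blocks) < 2:
            summary.rejected["unspliced"] += 1
            continue
        if exclude_primer_artifacts and r.sequence is not None:
            if r.sequence[-4:].upper() in {s.upper() for s in primer_signatures}:
                summary.rejected["primer_artifact"] += 1
                continue
        spanned = _junction_spans(merged, junctions, min_overhang)
        if spanned is None:
            # distinguish unannotated gap from short overhang for the summary
            if _junction_spans(merged, junctions, 1) is None:
                summary.rejected["unannotated_junction"] += 1
            else:
                summary.rejected["short_overhang"] += 1
            continue
        summary.accepted += 1
        blocks = merged.blocks
        lengths = [e - s for s, e in blocks]
        for i, key in enumerate(spanned):
            out.append(
                SplicedRead(
                    read=merged,
                    junction=key,
                    overhang_left=sum(lengths[: i + 1]),
                    overhang_right=sum(lengths[i + 1 :]),
                )
            )
    return out, summary


def call_splicing_events(
    spliced_reads: Iterable[SplicedRead],
    min_reads: int = DEFAULT_MIN_EVENT_READS,
) -> list[SplicingEvent]:
    by_junction: Counter = Counter()
    for sr in spliced_reads:
        by_junction[sr.junction] += 1
    return [
        SplicingEvent(junction=j, spliced_read_count=c, passes=c >= min_reads)
        for j, c in sorted(by_junction.items())
    ]


def passing_junctions(events: Iterable[SplicingEvent]) -> set[IntronKey]:
    """Set-comparable junction keys for replicate Venn logic."""
    return {e.junction for e in events if e.passes}


# ---------------------------------------------------------------------------
# 5' ss intermediate classification
# ---------------------------------------------------------------------------

def classify_intermediates(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    min_total: int = DEFAULT_MIN_TOTAL,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[IntermediateRecord]:
    """Classify reads ending at internal-exon 3' termini as SR / UR / ambiguous.

    First exons have no upstream junction and are skipped.  SR requires a
    valid spliced alignment across one of the exon's annotated upstream
    junctions; UR requires a contiguous (gap-free) body reaching at least
    1 nt past the exon 5' boundary into the preceding intron; candidates
    fully contained in the exon (or otherwise uninformative) are ambiguous.
    """
    contexts = annotation.internal_exon_contexts()
    junctions = annotation.junction_set()
    terminal_index: dict[tuple[str, str, int], list[ExonKey]] = defaultdict(list)
    for key, ctx in contexts.items():
        if not ctx.upstream_introns:
            continue  # no upstream junction anywhere -> skip
        e = ctx.exon
        terminal_index[(e.chrom, e.strand, e.three_prime_pos)].append(key)

    counts: dict[ExonKey, dict[str, int]] = defaultdict(
        lambda: dict(sr=0, ur=0, ambiguous=0)
    )
    for r in reads:
        if not r.is_unique or r.mismatch_count != 0:
            continue
        keys = terminal_index.get((r.chrom, r.strand, r.three_prime_end))
        if not keys:
            continue
        merged = r.merged()
        for key in keys:
            ctx = contexts[key]
            exon = ctx.exon
            cls = "ambiguous"
            spanned = _junction_spans(merged, junctions, min_overhang)
            if spanned and any(j in ctx.upstream_introns for j in spanned):
                cls = "sr"
            elif len(merged.blocks) == 1:
                if exon.strand == "+" and merged.start < exon.start:
                    cls = "ur"
                elif exon.strand == "-" and merged.end > exon.end:
                    cls = "ur"
            counts[key][cls] += 1

    return [
        IntermediateRecord(
            exon_key=key,
            sr=c["sr"],
            ur=c["ur"],
            ambiguous=c["ambiguous"],
            min_total=min_total,
        )
        for key, c in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    labels: tuple[str, str]
    values: dict[str, np.ndarray]
    location_stat: float | None
    location_p: float | None  # rank-based unpaired location test (Mann-Whitney)
    ks_stat: float | None
    ks_p: float | None
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # label -> (edges, counts)

    @property
    def defined(self) -> bool:
        return self.location_p is not None


GROUPINGS = ("constitutive_vs_skipped", "u2_vs_u12")


def compare_groups(
    records: Iterable[IntermediateRecord],
    annotation: GenomeAnnotation,
    grouping: str = "constitutive_vs_skipped",
    bins: int = 10,
) -> GroupComparison:
    """Compare spliced% distributions between two exon categories.

    ``constitutive_vs_skipped`` uses the exon classification flags;
    ``u2_vs_u12`` splits exons by the spliceosome class of any upstream
    intron.  Both tests need >= 2 defined values per group, otherwise the
    comparison is reported undefined.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    annotation.ensure_classified()
    contexts = annotation.internal_exon_contexts()
    if grouping == "constitutive_vs_skipped":
        labels = ("constitutive", "skipped")

        def which(ctx):
            if ctx.exon.constitutive:
                return "constitutive"
            if ctx.exon.skipped:
                return "skipped"
            return None

    else:
        labels = ("u2_preceded", "u12_preceded")

        def which(ctx):
            classes = {i.spliceosome_class for i in ctx.upstream_introns.values()}
            if "U12" in classes:
                return "u12_preceded"
            if classes:
                return "u2_preceded"
            return None

    values: dict[str, list[float]] = {label: [] for label in labels}
    for rec in records:
        pct = rec.spliced_pct
        if pct is None:
            continue
        ctx = contexts.get(rec.exon_key)
        if ctx is None:
            continue
        group = which(ctx)
        if group is not None:
            values[group].append(pct)

    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    edges = np.linspace(0.0, 100.0, bins + 1)
    histograms = {
        k: (edges, np.histogram(v, bins=edges)[0]) for k, v in arrays.items()
    }
    a, b = (arrays[label] for label in labels)
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(labels, arrays, None, None, None, None, histograms)
    if np.array_equal(np.sort(a), np.sort(b)):
        ks_stat, ks_p = 0.0, 1.0
    else:
        ks = stats.ks_2samp(a, b)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        labels=labels,
        values=arrays,
        location_stat=float(mw.statistic),
        location_p=float(mw.pvalue),
        ks_stat=ks_stat,
        ks_p=ks_p,
        histograms=histograms,
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def events_table(events: Iterable[SplicingEvent]) -> pd.DataFrame:
    rows = [
        dict(
            chrom=e.junction[0],
            strand=e.junction[1],
            start=e.junction[2],
            end=e.junction[3],
            reads=e.spliced_read_count,
            passes=e.passes,
        )
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "reads", "passes"]
    )


def intermediates_table(records: Iterable[IntermediateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        chrom, strand, start, end = r.exon_key
        rows.append(
            dict(
                chrom=chrom, strand=strand, start=start, end=end,
                sr=r.sr, ur=r.ur, ambiguous=r.ambiguous,
                spliced_pct=r.spliced_pct,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "strand", "start", "end", "sr", "ur", "ambiguous", "spliced_pct"],
    )
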