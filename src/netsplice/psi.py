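"""Percent-spliced-in from junction counts, with structural filters,
and intersection of inclusion status with 5' ss peak calls.

psi = ((IJ_up + IJ_down)/2) / (((IJ_up + IJ_down)/2) + EJ)

Internal exons are excluded when they carry alternative 5'/3' splice
sites, overlap another exon on the same strand, are shorter than 100 bp,
or their preceding (transcription-upstream) intron is shorter than 100 bp;
remaining exons additionally need junction coverage (by default, both
inclusion junctions individually >= 5 reads).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import ExonKey, GenomeAnnotation, IntronKey
from .peaks import FIVE_PRIME_SS, Peak

DEFAULT_MIN_JUNCTION_READS = 5
DEFAULT_MIN_EXON_LENGTH = 100
DEFAULT_MIN_INTRON_LENGTH = 100

# exclusion reasons, in the priority order they are assigned
REASON_ALT_SS = "alt_ss"
REASON_OVERLAP = "overlap"
REASON_SHORT_EXON = "short_exon"
REASON_SHORT_INTRON = "short_intron"
REASON_LOW_COVERAGE = "low_coverage"

COVERAGE_RULES = ("inclusion_junctions", "inclusion_vs_exclusion")


@dataclass
class PsiRecord:
    exon_key: ExonKey
    ij_up: int
    ij_down: int
    ej: int
    psi: float | None
    eligible: bool
    reason: str | None  # exclusion reason when not eligible


def _as_junction_counts(junctions) -> dict[IntronKey, int]:
    """Accept a mapping keyed by intron interval or a DataFrame with
    columns (chrom, strand, donor, acceptor, reads)."""
    if isinstance(junctions, Mapping):
        return {tuple(k): int(v) for k, v in junctions.items()}
    df = junctions
    out: dict[IntronKey, int] = {}
    for r in df.itertuples():
        donor, acceptor = int(r.donor), int(r.acceptor)
        if r.strand == "+":
            start, end = donor, acceptor + 1
        else:
            start, end = acceptor, donor + 1
        key = (r.chrom, r.strand, start, end)
        out[key] = out.get(key, 0) + int(r.reads)
    return out


def read_junction_counts(path: str | Path) -> dict[IntronKey, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return _as_junction_counts(df)


def compute_psi(
    junction_counts,
    annotation: GenomeAnnotation,
    min_junction_reads: int = DEFAULT_MIN_JUNCTION_READS,
    min_exon_length: int = DEFAULT_MIN_EXON_LENGTH,
    min_intron_length: int = DEFAULT_MIN_INTRON_LENGTH,
    coverage_rule: str = "inclusion_junctions",
) -> list[PsiRecord]:
    """One PSI record per distinct internal exon.

    ``junction_counts`` maps intron intervals (chrom, strand, start, end)
    to read counts, or is a DataFrame keyed by donor/acceptor positions.
    The exclusion junction count sums every annotated intron that fully
    spans the exon; an exon with no annotated skipping junction simply has
    EJ = 0.
    """
    if coverage_rule not in COVERAGE_RULES:
        raise ValueError(f"coverage_rule must be one of {COVERAGE_RULES}")
    counts = _as_junction_counts(junction_counts)
    annotation.ensure_classified()
    contexts = annotation.internal_exon_contexts()
    junction_keys = annotation.junction_set()

    # skipping junctions: annotated introns fully spanning an exon
    spanning: dict[ExonKey, list[IntronKey]] = {}
    for key, ctx in contexts.items():
        chrom, strand, start, end = key
        spanning[key] = [
            j
            for j in junction_keys
            if j[0] == chrom and j[1] == strand and j[2] <= start and j[3] >= end
        ]

    records: list[PsiRecord] = []
    for key in sorted(contexts):
        ctx = contexts[key]
        exon = ctx.exon
        ups = sorted(ctx.upstream_introns)
        downs = sorted(ctx.downstream_introns)
        ij_up = sum(counts.get(j, 0) for j in ups)
        ij_down = sum(counts.get(j, 0) for j in downs)
        ej = sum(counts.get(j, 0) for j in spanning[key])

        reason = None
        if exon.alt5ss or exon.alt3ss:
            reason = REASON_ALT_SS
        elif exon.overlaps_other_exon:
            reason = REASON_OVERLAP
        elif exon.length < min_exon_length:
            reason = REASON_SHORT_EXON
        elif ups and min(
            ctx.upstream_introns[j].length for j in ups
        ) < min_intron_length:
            reason = REASON_SHORT_INTRON
        else:
            if coverage_rule == "inclusion_junctions":
                covered = min(ij_up, ij_down) >= min_junction_reads
            else:
                covered = (ij_up + ij_down) / 2 >= min_junction_reads and (
                    ej >= min_junction_reads
                )
            if not covered:
                reason = REASON_LOW_COVERAGE

        eligible = reason is None
        psi = None
        if eligible:
            inc = (ij_up + ij_down) / 2
            psi = inc / (inc + ej) if (inc + ej) > 0 else None
            if psi is None:
                eligible = False
                reason = REASON_LOW_COVERAGE
        records.append(
            PsiRecord(
                exon_key=key, ij_up=ij_up, ij_down=ij_down, ej=ej,
                psi=psi, eligible=eligible, reason=reason,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Peak / PSI overlap
# ---------------------------------------------------------------------------

@dataclass
class PsiOverlap:
    peak_exon_psis: np.ndarray  # PSI of eligible exons carrying a 5' ss peak
    n_peak_exons: int
    frac_peak_exons_high_psi: float  # among peak-bearing exons, PSI > threshold
    n_high_psi: int
    n_high_psi_with_peak: int
    frac_high_psi_with_peak: float  # among PSI > threshold exons, carrying a peak
    threshold: float = 0.9


def peak_psi_overlap(
    peaks: Iterable[Peak],
    psi_records: Iterable[PsiRecord],
    psi_threshold: float = 0.9,
) -> PsiOverlap:
    """Intersect consensus 5' ss peaks with PSI-based inclusion status.

    Peaks are matched to exons through the peak position, which by
    construction is the exon's 3'-terminal nucleotide.
    """
    records = [r for r in psi_records if r.eligible and r.psi is not None]
    by_terminal: dict[tuple[str, str, int], PsiRecord] = {}
    for r in records:
        chrom, strand, start, end = r.exon_key
        terminal = end - 1 if strand == "+" else start
        by_terminal[(chrom, strand, terminal)] = r

    peak_positions = {
        (p.chrom, p.strand, p.position) for p in peaks if p.kind == FIVE_PRIME_SS
    }
    peak_psis = [
        r.psi for pos, r in by_terminal.items() if pos in peak_positions
    ]
    high = [
        (pos, r) for pos, r in by_terminal.items() if r.psi > psi_threshold
    ]
    n_high_with_peak = sum(1 for pos, _ in high if pos in peak_positions)
    n_peak = len(peak_psis)
    return PsiOverlap(
        peak_exon_psis=np.asarray(peak_psis, dtype=float),
        n_peak_exons=n_peak,
        frac_peak_exons_high_psi=(
            sum(1 for v in peak_psis if v > psi_threshold) / n_peak if n_peak else 0.0
        ),
        n_high_psi=len(high),
        n_high_psi_with_peak=n_high_with_peak,
        frac_high_psi_with_peak=(n_high_with_peak / len(high) if high else 0.0),
        threshold=psi_threshold,
    )


def psi_table(records: Iterable[PsiRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        chrom, strand, start, end = r.exon_key
        rows.append(
            dict(
                chrom=chrom, strand=strand, start=start, end=end,
                ij_up=r.ij_up, ij_down=r.ij_down, ej=r.ej,
                psi=r.psi, eligible=r.eligible, reason=r.reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "strand", "start", "end", "ij_up", "ij_down", "ej",
            "psi", "eligible", "reason",
        ],
    )
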