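"""Feature-local 3-standard-deviation peak calling.

Two modes share the same threshold rule (raw count >= min_reads, count >=
mean + k_sd * sd, count strictly above the mean):

* splice-site mode tests only the 3'-terminal nucleotide of each eligible
  exon (5' ss intermediate) or intron (3' ss intermediate, released lariat);
* pause mode removes the 3 transcription-3'-most exon positions and the 3
  transcription-5'-most intron positions, recomputes mean/sd on the
  remaining positions, and tests every remaining position.

Mean and standard deviation are the population statistics over every
nucleotide of the feature, zeros included, candidate included.  The strict
count > mean requirement makes zero-variance features peak-free.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import Exon, GenomeAnnotation, Intron
from .coverage import EndCoverage

FIVE_PRIME_SS = "five_prime_ss"
THREE_PRIME_SS = "three_prime_ss"
PAUSE = "pause"


@dataclass
class PeakParams:
    k_sd: float = 3.0
    min_reads: int = 4
    trim_exon_3prime: int = 3  # pause mode only
    trim_intron_5prime: int = 3  # pause mode only

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass
class Peak:
    chrom: str
    strand: str
    position: int
    count: int
    feature_id: str
    feature_kind: str  # "exon" | "intron"
    feature_mean: float
    feature_sd: float
    kind: str  # five_prime_ss | three_prime_ss | pause
    replicate_counts: tuple[int, ...] | None = None

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.chrom, self.strand, self.position, self.kind)


def feature_stats(counts: np.ndarray) -> tuple[float, float]:
    """Population mean and standard deviation of a per-nucleotide count vector."""
    counts = np.asarray(counts, dtype=float)
    return float(counts.mean()), float(counts.std(ddof=0))


def _is_peak(count: int, mean: float, sd: float, params: PeakParams) -> bool:
    return (
        count >= params.min_reads
        and count >= mean + params.k_sd * sd
        and count > mean
    )


def _feature_id(feature: Exon | Intron) -> str:
    kind = "exon" if isinstance(feature, Exon) else "intron"
    return f"{kind}:{feature.chrom}:{feature.start}-{feature.end}({feature.strand})"


def call_ss_peaks(
    coverage: EndCoverage,
    annotation: GenomeAnnotation,
    params: PeakParams | None = None,
) -> list[Peak]:
    """Splicing-intermediate peaks at feature 3'-terminal nucleotides.

    Exon terminals yield five_prime_ss peaks, intron terminals
    three_prime_ss peaks.  Features are exons/introns of expressed genes
    excluding any exon intersecting a different isoform exon (and
    likewise for introns).
    """
    params = params or PeakParams()
    peaks: list[Peak] = []
    for feature, _gene, kind in _eligible_features(annotation):
        vec = coverage.window(feature.chrom, feature.strand, feature.start, feature.end)
        terminal = feature.three_prime_pos - feature.start
        count = int(vec[terminal])
        mean, sd = feature_stats(vec)
        if _is_peak(count, mean, sd, params):
            peaks.append(
                Peak(
                    chrom=feature.chrom,
                    strand=feature.strand,
                    position=feature.three_prime_pos,
                    count=count,
                    feature_id=_feature_id(feature),
                    feature_kind=kind,
                    feature_mean=mean,
                    feature_sd=sd,
                    kind=FIVE_PRIME_SS if kind == "exon" else THREE_PRIME_SS,
                )
            )
    return peaks


def call_pause_peaks(
    coverage: EndCoverage,
    annotation: GenomeAnnotation,
    params: PeakParams | None = None,
) -> list[Peak]:
    """Pause peaks at any non-trimmed position of eligible exons and introns."""
    params = params or PeakParams()
    peaks: list[Peak] = []
    for feature, _gene, kind in _eligible_features(annotation):
        el = feature.length
        if kind == "exon":
            n_trim = min(params.trim_exon_3prime, el)
            trimmed = (
                range(el - n_trim, el) if feature.strand == "+" else range(n_trim)
            )
        else:
            n_trim = min(params.trim_intron_5prime, el)
            trimmed = (
                range(n_trim) if feature.strand == "+" else range(el - n_trim, el)
            )
        keep = np.ones(el, dtype=bool)
        keep[list(trimmed)] = False
        if not keep.any():
            continue
        vec = coverage.window(feature.chrom, feature.strand, feature.start, feature.end)
        kept = vec[keep]
        mean, sd = feature_stats(kept)
        kept_offsets = np.flatnonzero(keep)
        for off in kept_offsets[np.flatnonzero(_vec_is_peak(kept, mean, sd, params))]:
            peaks.append(
                Peak(
                    chrom=feature.chrom,
                    strand=feature.strand,
                    position=feature.start + int(off),
                    count=int(vec[off]),
                    feature_id=_feature_id(feature),
                    feature_kind=kind,
                    feature_mean=mean,
                    feature_sd=sd,
                    kind=PAUSE,
                )
            )
    return peaks


def _vec_is_peak(
    counts: np.ndarray, mean: float, sd: float, params: PeakParams
) -> np.ndarray:
    return (
        (counts >= params.min_reads)
        & (counts >= mean + params.k_sd * sd)
        & (counts > mean)
    )


def _eligible_features(annotation: GenomeAnnotation):
    for exon, gene in annotation.eligible_exons():
        yield exon, gene, "exon"
    for intron, gene in annotation.eligible_introns():
        yield intron, gene, "intron"


def consensus_peaks(peak_sets: Sequence[list[Peak]]) -> list[Peak]:
    """Peaks present at identical (chrom, strand, position, kind) in every set.

    Requires at least two replicate sets; per-replicate counts are
    attached to the surviving peaks.
    """
    if len(peak_sets) < 2:
        raise ValueError("consensus requires at least 2 replicate peak sets")
    indexed = [{p.key: p for p in ps} for ps in peak_sets]
    common = set(indexed[0])
    for idx in indexed[1:]:
        common &= set(idx)
    out = []
    for key in sorted(common):
        first = indexed[0][key]
        out.append(
            Peak(
                chrom=first.chrom,
                strand=first.strand,
                position=first.position,
                count=first.count,
                feature_id=first.feature_id,
                feature_kind=first.feature_kind,
                feature_mean=first.feature_mean,
                feature_sd=first.feature_sd,
                kind=first.kind,
                replicate_counts=tuple(idx[key].count for idx in indexed),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> int:
    """BED6: name = feature id, score = read count."""
    n = 0
    with open(path, "w") as out:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.position, p.strand, p.kind)):
            out.write(
                f"{p.chrom}\t{p.position}\t{p.position + 1}\t{p.feature_id}"
                f"\t{p.count}\t{p.strand}\n"
            )
            n += 1
    return n


def peaks_table(peaks: Iterable[Peak]) -> pd.DataFrame:
    rows = [
        dict(
            chrom=p.chrom,
            strand=p.strand,
            position=p.position,
            count=p.count,
            kind=p.kind,
            feature_id=p.feature_id,
            feature_mean=p.feature_mean,
            feature_sd=p.feature_sd,
            threshold=p.feature_mean + 3.0 * p.feature_sd,
        )
        for p in peaks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "strand", "position", "count", "kind", "feature_id",
            "feature_mean", "feature_sd", "threshold",
        ],
    )
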