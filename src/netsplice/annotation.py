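"""Gene-annotation model.

Parses an Ensembl-dialect GTF into a light object model, derives introns
per transcript, classifies internal exons (constitutive / skipped /
alternative splice site / overlapping), labels U12-type introns from a BED
interval list, and determines expressed genes from a transcript FPKM table.

All internal coordinates are 0-based half-open.  GTF input is read as
1-based closed; BED input as 0-based half-open.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

log = logging.getLogger(__name__)

ExonKey = tuple[str, str, int, int]  # (chrom, strand, start, end)
IntronKey = tuple[str, str, int, int]


class GtfParseError(ValueError):
    """Raised for a syntactically invalid GTF line (message names the line)."""


class AnnotationError(ValueError):
    """Raised when records parse but violate structural invariants."""


@dataclass
class Exon:
    chrom: str
    start: int
    end: int
    strand: str
    index: int = -1  # ordinal in transcription order within its transcript
    first: bool = False
    last: bool = False
    constitutive: bool = False
    skipped: bool = False
    alt5ss: bool = False
    alt3ss: bool = False
    overlaps_other_exon: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def internal(self) -> bool:
        return not (self.first or self.last)

    @property
    def key(self) -> ExonKey:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def three_prime_pos(self) -> int:
        """Genomic position of the exon's 3'-terminal (last transcribed) base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Intron:
    chrom: str
    start: int
    end: int
    strand: str
    spliceosome_class: str = "U2"
    overlaps_other_intron: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> IntronKey:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def donor(self) -> int:
        """First intron base after the 5' splice site, genomic position."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor(self) -> int:
        """Last intron base before the 3' splice site, genomic position."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def three_prime_pos(self) -> int:
        return self.acceptor


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)  # transcription order
    introns: list[Intron] = field(default_factory=list)  # transcription order

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def exon_keys(self) -> set[ExonKey]:
        return {e.key for e in self.exons}

    def derive_introns(self) -> None:
        """Fill ``introns`` with the gaps between consecutive exons.

        Exons must already be in transcription order.  A zero-length gap
        (abutting exons) violates the model and raises AnnotationError.
        """
        genomic = sorted(self.exons, key=lambda e: e.start)
        introns = []
        for a, b in zip(genomic, genomic[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or abut "
                    f"at {a.end}/{b.start}; cannot derive an intron of length < 1"
                )
            introns.append(Intron(self.chrom, a.end, b.start, self.strand))
        if self.strand == "-":
            introns.reverse()
        self.introns = introns

    def _finalize(self) -> None:
        """Sort exons into transcription order, set ordinals and end flags."""
        self.exons.sort(key=lambda e: e.start, reverse=(self.strand == "-"))
        for i, e in enumerate(self.exons):
            e.index = i
            e.first = i == 0
            e.last = i == len(self.exons) - 1
        self.derive_introns()


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    is_expressed: bool = True


class GenomeAnnotation:
    """A set of genes plus the lookups downstream stages need."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = list(genes)
        self._classified = False
        for g in self.genes:
            for t in g.transcripts:
                if t.chrom != g.chrom or t.strand != g.strand:
                    raise AnnotationError(
                        f"transcript {t.transcript_id} does not share "
                        f"chromosome/strand with gene {g.gene_id}"
                    )

    # ---- iteration helpers -------------------------------------------------
    def transcripts(self) -> Iterator[tuple[Gene, Transcript]]:
        for g in self.genes:
            for t in g.transcripts:
                yield g, t

    def junction_set(self) -> set[IntronKey]:
        return {i.key for _, t in self.transcripts() for i in t.introns}

    def unique_exons(self) -> dict[ExonKey, tuple[Exon, Gene]]:
        """First-seen representative per distinct exon interval."""
        out: dict[ExonKey, tuple[Exon, Gene]] = {}
        for g, t in self.transcripts():
            for e in t.exons:
                out.setdefault(e.key, (e, g))
        return out

    def unique_introns(self) -> dict[IntronKey, tuple[Intron, Gene]]:
        out: dict[IntronKey, tuple[Intron, Gene]] = {}
        for g, t in self.transcripts():
            for i in t.introns:
                out.setdefault(i.key, (i, g))
        return out

    def internal_exon_contexts(self) -> dict[ExonKey, "ExonContext"]:
        """Per distinct internal exon: flanking introns across isoforms.

        An exon counts as internal if it is internal in at least one
        transcript.  Flanking introns are collected over every transcript
        in which the exon appears.
        """
        ctxs: dict[ExonKey, ExonContext] = {}
        for g, t in self.transcripts():
            for e in t.exons:
                ctx = ctxs.get(e.key)
                if ctx is None:
                    ctx = ExonContext(exon=e, gene=g)
                    ctxs[e.key] = ctx
                if not e.first and t.introns:
                    up = t.introns[e.index - 1]
                    ctx.upstream_introns.setdefault(up.key, up)
                if not e.last and t.introns:
                    down = t.introns[e.index]
                    ctx.downstream_introns.setdefault(down.key, down)
                if e.internal:
                    ctx.internal_in_any = True
        return {k: c for k, c in ctxs.items() if c.internal_in_any}

    # ---- eligibility for peak calling -------------------------------------
    def ensure_classified(self) -> None:
        if not self._classified:
            classify_exons(self)

    def eligible_exons(self) -> list[tuple[Exon, Gene]]:
        """Distinct exons of expressed genes not intersecting another isoform's exon."""
        self.ensure_classified()
        return [
            (e, g)
            for e, g in self.unique_exons().values()
            if g.is_expressed and not e.overlaps_other_exon
        ]

    def eligible_introns(self) -> list[tuple[Intron, Gene]]:
        self.ensure_classified()
        return [
            (i, g)
            for i, g in self.unique_introns().values()
            if g.is_expressed and not i.overlaps_other_intron
        ]


@dataclass
class ExonContext:
    exon: Exon
    gene: Gene
    upstream_introns: dict[IntronKey, Intron] = field(default_factory=dict)
    downstream_introns: dict[IntronKey, Intron] = field(default_factory=dict)
    internal_in_any: bool = False


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

def _validate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            if fields[2] in ("exon", "transcript", "gene") and fields[6] not in "+-":
                raise GtfParseError(
                    f"{path}: line {lineno}: strand must be '+' or '-' "
                    f"for {fields[2]} features"
                )


def parse_annotation(gtf_path: str | Path) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Transcripts are ordered in transcription direction and introns derived.
    """
    gtf_path = Path(gtf_path)
    _validate_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    tx_bounds: dict[str, tuple[int, int]] = {}
    for f in db.features_of_type("transcript"):
        tx_bounds[f.attributes["transcript_id"][0]] = (f.start - 1, f.end)

    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    gene_order: list[str] = []
    for f in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        t = transcripts.get(tid)
        if t is None:
            t = Transcript(tid, f.seqid, f.strand)
            transcripts[tid] = t
            tx_gene[tid] = gid
            if gid not in gene_order:
                gene_order.append(gid)
        start, end = f.start - 1, f.end
        if tid in tx_bounds:
            lo, hi = tx_bounds[tid]
            if start < lo or end > hi:
                raise AnnotationError(
                    f"exon [{start},{end}) outside transcript {tid} "
                    f"bounds [{lo},{hi})"
                )
        t.exons.append(Exon(f.seqid, start, end, f.strand))

    genes: dict[str, Gene] = {}
    for tid, t in transcripts.items():
        if not t.exons:
            continue
        t._finalize()
        gid = tx_gene[tid]
        g = genes.get(gid)
        if g is None:
            g = Gene(gid, t.chrom, t.strand)
            genes[gid] = g
        g.transcripts.append(t)
    return GenomeAnnotation([genes[gid] for gid in gene_order if gid in genes])


# ---------------------------------------------------------------------------
# Exon classification
# ---------------------------------------------------------------------------

def _flag_overlaps(keys: list[tuple[str, str, int, int]]) -> set[tuple]:
    """Return keys intersecting a *different* interval on the same chrom/strand."""
    flagged: set[tuple] = set()
    by_cs: dict[tuple[str, str], list[tuple[int, int, tuple]]] = defaultdict(list)
    for k in keys:
        chrom, strand, start, end = k
        by_cs[(chrom, strand)].append((start, end, k))
    for ivs in by_cs.values():
        ivs.sort()
        active: list[tuple[int, int, tuple]] = []
        for start, end, k in ivs:
            active = [a for a in active if a[1] > start]
            for a in active:
                flagged.add(a[2])
                flagged.add(k)
            active.append((start, end, k))
    return flagged


def classify_exons(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Set per-exon flags; idempotent and isoform-order invariant.

    constitutive: present (exact interval) in every isoform of its gene.
    skipped: some other isoform of the gene has an intron spanning the exon.
    alt5ss / alt3ss: another isoform of the gene uses a different donor /
      acceptor boundary for an overlapping exon body.
    overlaps_other_exon: intersects a non-identical exon interval anywhere
      on the same strand (and analogously for introns).
    """
    flags: dict[ExonKey, dict[str, bool]] = defaultdict(
        lambda: dict(constitutive=False, skipped=False, alt5ss=False, alt3ss=False)
    )

    for g in annotation.genes:
        iso_sets = [t.exon_keys() for t in g.transcripts]
        iso_introns = [
            [(i.start, i.end) for i in t.introns] for t in g.transcripts
        ]
        gene_keys = set().union(*iso_sets) if iso_sets else set()
        for key in gene_keys:
            chrom, strand, start, end = key
            f = flags[key]
            f["constitutive"] = all(key in s for s in iso_sets)
            for s, intr in zip(iso_sets, iso_introns):
                if key not in s and any(a <= start and b >= end for a, b in intr):
                    f["skipped"] = True
                    break
            for other in gene_keys:
                if other == key:
                    continue
                _, _, ostart, oend = other
                if ostart >= end or oend <= start:
                    continue  # must overlap the exon body
                same_start, same_end = ostart == start, oend == end
                if strand == "+":
                    if same_start and not same_end:
                        f["alt5ss"] = True
                    if same_end and not same_start:
                        f["alt3ss"] = True
                else:
                    if same_end and not same_start:
                        f["alt5ss"] = True
                    if same_start and not same_end:
                        f["alt3ss"] = True

    exon_keys = [e.key for _, t in annotation.transcripts() for e in t.exons]
    overlap_exons = _flag_overlaps(sorted(set(exon_keys)))
    intron_keys = [i.key for _, t in annotation.transcripts() for i in t.introns]
    overlap_introns = _flag_overlaps(sorted(set(intron_keys)))

    for _, t in annotation.transcripts():
        for e in t.exons:
            f = flags[e.key]
            e.constitutive = f["constitutive"]
            e.skipped = f["skipped"]
            e.alt5ss = f["alt5ss"]
            e.alt3ss = f["alt3ss"]
            e.overlaps_other_exon = e.key in overlap_exons
        for i in t.introns:
            i.overlaps_other_intron = i.key in overlap_introns

    annotation._classified = True
    return annotation


# ---------------------------------------------------------------------------
# U12 labelling
# ---------------------------------------------------------------------------

def label_u12_introns(
    annotation: GenomeAnnotation, u12_bed: str | Path
) -> GenomeAnnotation:
    """Label introns exactly matching a BED6 interval (chrom, strand, both ends) as U12."""
    try:
        bed = pd.read_csv(
            u12_bed,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    listed = {
        (r.chrom, r.strand, int(r.start), int(r.end)) for r in bed.itertuples()
    }
    matched: set[IntronKey] = set()
    for _, t in annotation.transcripts():
        for i in t.introns:
            if i.key in listed:
                i.spliceosome_class = "U12"
                matched.add(i.key)
            else:
                i.spliceosome_class = "U2"
    for entry in sorted(listed - matched):
        log.warning("U12 list interval %s matches no annotated intron", entry)
    return annotation


# ---------------------------------------------------------------------------
# Expressed-gene thresholding
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    fpkm: pd.Series  # transcript_id -> FPKM

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected columns transcript_id, FPKM")
        s = pd.Series(
            df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str)
        )
        if (s < 0).any():
            raise ValueError(f"{path}: FPKM values must be non-negative")
        return cls(s)

    def log2_positive(self) -> np.ndarray:
        vals = self.fpkm[self.fpkm > 0]
        return np.log2(vals.to_numpy())


@dataclass
class ExpressionCall:
    gene_ids: set[str]
    threshold: float  # log2-FPKM units, recorded for audit
    used_fallback: bool


DEFAULT_EXPRESSION_THRESHOLD = 0.0  # log2 FPKM, unimodal fallback
_KDE_GRID_POINTS = 512


def expression_threshold(table: ExpressionTable) -> tuple[float, bool]:
    """Local minimum of the log2-FPKM KDE between its two highest modes.

    Falls back to ``DEFAULT_EXPRESSION_THRESHOLD`` with a warning when the
    density is unimodal or degenerate.
    """
    vals = table.log2_positive()
    if len(vals) < 2 or np.unique(vals).size < 2:
        log.warning("degenerate FPKM distribution; using fallback threshold")
        return DEFAULT_EXPRESSION_THRESHOLD, True
    try:
        kde = gaussian_kde(vals, bw_method="silverman")
    except np.linalg.LinAlgError:
        log.warning("singular FPKM distribution; using fallback threshold")
        return DEFAULT_EXPRESSION_THRESHOLD, True
    grid = np.linspace(vals.min(), vals.max(), _KDE_GRID_POINTS)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (
        dens[interior] >= dens[interior + 1]
    )
    maxima = interior[is_max]
    if len(maxima) < 2:
        log.warning("unimodal log2-FPKM density; using fallback threshold")
        return DEFAULT_EXPRESSION_THRESHOLD, True
    top_two = sorted(maxima[np.argsort(dens[maxima])[-2:]])
    lo, hi = top_two
    threshold = float(grid[lo + int(np.argmin(dens[lo : hi + 1]))])
    return threshold, False


def expressed_genes(
    table: ExpressionTable, annotation: GenomeAnnotation
) -> ExpressionCall:
    """A gene is expressed iff any of its transcripts exceeds the threshold.

    Also sets ``Gene.is_expressed`` on the annotation.
    """
    threshold, fallback = expression_threshold(table)
    expressed_tx = set(
        table.fpkm[(table.fpkm > 0) & (np.log2(table.fpkm.where(table.fpkm > 0)) > threshold)].index
    )
    gene_ids: set[str] = set()
    for g in annotation.genes:
        g.is_expressed = any(
            t.transcript_id in expressed_tx for t in g.transcripts
        )
        if g.is_expressed:
            gene_ids.add(g.gene_id)
    return ExpressionCall(gene_ids=gene_ids, threshold=threshold, used_fallback=fallback)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_exon_table(annotation: GenomeAnnotation, path: str | Path) -> pd.DataFrame:
    """One row per (transcript, exon) with classification flags; also returned."""
    annotation.ensure_classified()
    rows = []
    for g, t in annotation.transcripts():
        for e in t.exons:
            rows.append(
                dict(
                    gene_id=g.gene_id,
                    transcript_id=t.transcript_id,
                    chrom=e.chrom,
                    start=e.start,
                    end=e.end,
                    strand=e.strand,
                    index=e.index,
                    first=e.first,
                    last=e.last,
                    constitutive=e.constitutive,
                    skipped=e.skipped,
                    alt5ss=e.alt5ss,
                    alt3ss=e.alt3ss,
                    overlaps_other_exon=e.overlaps_other_exon,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
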