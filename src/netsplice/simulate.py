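"""Synthetic data with planted ground truth for every pipeline stage.

Generates multi-isoform gene annotations (constitutive, skipped, alt-ss,
short exons/introns, U12-labelled introns, snRNA-like genes), nascent
3'-end read alignments (background, 5' ss intermediates whose bodies are
spliced or unspliced according to a planted per-exon fraction, pause and
snRNA spikes, footprint-length mixtures), junction-count tables for PSI,
and protein intensity matrices with group effects and missing-not-at-random
dropouts.  Every generator is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .annotation import Exon, Gene, GenomeAnnotation, Intron, Transcript, ExonKey, IntronKey
from .reads import AlignedRead

CHROM = "chrS"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FootprintComponent:
    mode: float
    sd: float
    lo: int
    hi: int


# protected-fragment mixtures: polymerase-only (~27 nt) and
# polymerase+splicing-complex (~60 nt) components
SHORT_COMPONENT = FootprintComponent(27.0, 4.0, 18, 40)
LONG_COMPONENT = FootprintComponent(60.0, 8.0, 40, 100)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (5, 7)  # inclusive range
    first_exon_length: int = 250
    exon_length_log_mean: float = np.log(80.0)
    exon_length_log_sd: float = 0.55
    exon_length_range: tuple[int, int] = (30, 400)
    intron_length_log_mean: float = np.log(300.0)
    intron_length_log_sd: float = 0.5
    intron_length_range: tuple[int, int] = (110, 2000)
    short_exon_fraction: float = 0.05  # planted exons < 100 nt
    short_intron_fraction: float = 0.05  # planted introns < 100 nt
    skip_fraction: float = 0.5  # per eligible internal exon (alternating)
    alt5_fraction: float = 0.05
    alt3_fraction: float = 0.05
    u12_fraction: float = 0.08
    n_snrna: int = 8
    intergenic_gap: int = 1000
    # read model
    background_lambda: float = 0.05  # 3' ends per transcribed nt
    intermediate_rate: float = 30.0  # expected intermediate reads per planted exon
    peak_fraction: float = 0.9  # internal exons given an intermediate spike
    pause_per_gene: int = 1
    pause_rate: float = 25.0
    snrna_rate: float = 50.0
    treatment_scale: float = 1.0
    mismatch_rate: float = 0.0
    library_mode: str = "long"  # {"short", "long"}
    mode_weight: float = 0.9  # weight of the library mode's own component
    psi_alpha: float = 1.0  # Beta prior of planted spliced/inclusion fraction
    psi_beta: float = 1.0
    strandness: str = "reverse"

    def __post_init__(self) -> None:
        if self.library_mode not in ("short", "long"):
            raise ValueError("library_mode must be 'short' or 'long'")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[1] < self.exons_per_gene[0]:
            raise ValueError("invalid exons_per_gene range")
        if self.exon_length_range[0] < 1 or self.intron_length_range[0] < 1:
            raise ValueError("infeasible length parameters")
        if not 0 <= self.mode_weight <= 1:
            raise ValueError("mode_weight must be in [0,1]")

    @property
    def footprint_weights(self) -> tuple[float, float]:
        """(short component weight, long component weight)."""
        w = self.mode_weight
        return (w, 1 - w) if self.library_mode == "short" else (1 - w, w)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_length_range", "intron_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in asdict(self).items()
        }
        for key in ("exons_per_gene", "exon_length_range", "intron_length_range"):
            d[key] = [int(x) for x in d[key]]
        return d


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

@dataclass
class ExonTruth:
    key: ExonKey
    gene_id: str
    index: int  # transcription-order ordinal in the primary isoform
    psi_true: float  # planted spliced fraction of intermediates
    intermediate_rate: float
    has_peak: bool
    has_skip_junction: bool
    upstream_intron: IntronKey | None
    upstream_exon: ExonKey | None
    downstream_intron: IntronKey | None

    @property
    def inclusion_true(self) -> float:
        """Planted inclusion level realizable by the annotation."""
        return self.psi_true if self.has_skip_junction else 1.0


@dataclass
class SyntheticTruth:
    exons: dict[ExonKey, ExonTruth]
    gene_background: dict[str, float]
    gene_spans: dict[str, tuple[str, str, int, int]]  # gene -> chrom,strand,start,end
    pause_sites: list[tuple[str, str, int, float]]  # chrom, strand, pos, rate
    snrna: dict[str, list[tuple[str, str, int, int, str]]]
    u12_introns: list[IntronKey]
    config: SimulationConfig

    def exon_table(self) -> pd.DataFrame:
        rows = []
        for t in self.exons.values():
            chrom, strand, start, end = t.key
            rows.append(
                dict(
                    gene_id=t.gene_id, chrom=chrom, strand=strand,
                    start=start, end=end, index=t.index,
                    psi_true=t.psi_true, inclusion_true=t.inclusion_true,
                    intermediate_rate=t.intermediate_rate,
                    has_peak=t.has_peak, has_skip_junction=t.has_skip_junction,
                )
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _draw_length(rng, log_mean, log_sd, lo, hi) -> int:
    return int(np.clip(round(rng.lognormal(log_mean, log_sd)), lo, hi))


def make_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Generate a synthetic annotation plus the planted truth table.

    Genes are laid out on a single chromosome with alternating strands.
    Skipping isoforms are planted only on alternating internal exons so
    every inclusion junction is adjacent to at most one variable exon,
    which keeps the planted inclusion level identifiable from junction
    counts.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    genes: list[Gene] = []
    exon_truth: dict[ExonKey, ExonTruth] = {}
    gene_background: dict[str, float] = {}
    gene_spans: dict[str, tuple[str, str, int, int]] = {}
    pause_sites: list[tuple[str, str, int, float]] = []
    u12_introns: list[IntronKey] = []

    cursor = config.intergenic_gap
    for gi in range(config.n_genes):
        gene_id = f"SYNG{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))

        exon_lengths = [config.first_exon_length]
        for _ in range(n_exons - 1):
            if rng.random() < config.short_exon_fraction:
                exon_lengths.append(int(rng.integers(40, 100)))
            else:
                exon_lengths.append(
                    _draw_length(rng, config.exon_length_log_mean,
                                 config.exon_length_log_sd, *config.exon_length_range)
                )
        intron_lengths = []
        for _ in range(n_exons - 1):
            if rng.random() < config.short_intron_fraction:
                intron_lengths.append(int(rng.integers(40, 100)))
            else:
                intron_lengths.append(
                    _draw_length(rng, config.intron_length_log_mean,
                                 config.intron_length_log_sd, *config.intron_length_range)
                )

        # genomic layout: transcription order equals genomic order on '+',
        # reversed on '-'
        tx_exon_lengths = exon_lengths
        tx_intron_lengths = intron_lengths
        if strand == "-":
            genomic_exon_lengths = tx_exon_lengths[::-1]
            genomic_intron_lengths = tx_intron_lengths[::-1]
        else:
            genomic_exon_lengths = tx_exon_lengths
            genomic_intron_lengths = tx_intron_lengths
        intervals: list[tuple[int, int]] = []
        pos = cursor
        for i, elen in enumerate(genomic_exon_lengths):
            intervals.append((pos, pos + elen))
            pos += elen
            if i < len(genomic_intron_lengths):
                pos += genomic_intron_lengths[i]
        gene_end = pos
        cursor = gene_end + config.intergenic_gap
        if strand == "-":
            intervals = intervals[::-1]  # back to transcription order

        def build_transcript(tid: str, ivals: list[tuple[int, int]]) -> Transcript:
            t = Transcript(tid, CHROM, strand,
                           [Exon(CHROM, s, e, strand) for s, e in ivals])
            t._finalize()
            return t

        primary = build_transcript(f"SYNT{gi:04d}.1", intervals)
        transcripts = [primary]
        n_iso = 2

        # skipping isoforms on alternating internal exons
        skip_flags = [False] * n_exons
        for k in range(1, n_exons - 1, 2):
            if rng.random() < config.skip_fraction:
                skip_flags[k] = True
                transcripts.append(
                    build_transcript(
                        f"SYNT{gi:04d}.{n_iso}",
                        [iv for j, iv in enumerate(intervals) if j != k],
                    )
                )
                n_iso += 1

        # alternative splice-site isoforms
        for k in range(1, n_exons - 1):
            s, e = intervals[k]
            if e - s < 60:
                continue
            delta = int(rng.integers(6, 16))
            if rng.random() < config.alt5_fraction:
                alt = list(intervals)
                alt[k] = (s, e - delta) if strand == "+" else (s + delta, e)
                transcripts.append(build_transcript(f"SYNT{gi:04d}.{n_iso}", alt))
                n_iso += 1
            if rng.random() < config.alt3_fraction:
                alt = list(intervals)
                alt[k] = (s + delta, e) if strand == "+" else (s, e - delta)
                transcripts.append(build_transcript(f"SYNT{gi:04d}.{n_iso}", alt))
                n_iso += 1

        gene = Gene(gene_id, CHROM, strand, transcripts)
        genes.append(gene)
        gene_background[gene_id] = config.background_lambda
        gene_spans[gene_id] = (CHROM, strand, primary.start, primary.end)

        # U12 labels on primary-isoform introns
        for intron in primary.introns:
            if rng.random() < config.u12_fraction:
                u12_introns.append(intron.key)

        # pause sites in the promoter-proximal first exon
        first = primary.exons[0]
        for _ in range(config.pause_per_gene):
            off = int(rng.integers(20, 50))
            pos = first.start + off if strand == "+" else first.end - 1 - off
            pause_sites.append((CHROM, strand, pos, config.pause_rate))

        # planted per-exon truth: every exon with a downstream intron can be
        # cleaved at its 5' ss; spliced fraction applies to its upstream side
        for k, exon in enumerate(primary.exons):
            psi = float(rng.beta(config.psi_alpha, config.psi_beta))
            planted = k < n_exons - 1 and rng.random() < config.peak_fraction
            exon_truth[exon.key] = ExonTruth(
                key=exon.key,
                gene_id=gene_id,
                index=k,
                psi_true=psi,
                intermediate_rate=config.intermediate_rate if planted else 0.0,
                has_peak=planted,
                has_skip_junction=skip_flags[k],
                upstream_intron=primary.introns[k - 1].key if k > 0 else None,
                upstream_exon=primary.exons[k - 1].key if k > 0 else None,
                downstream_intron=primary.introns[k].key if k < n_exons - 1 else None,
            )

    # snRNA-like single-exon genes
    snrna: dict[str, list[tuple[str, str, int, int, str]]] = {}
    classes = ["U1", "U2", "U4", "U5"]
    for si in range(config.n_snrna):
        cls = classes[si % len(classes)]
        strand = "+" if si % 2 == 0 else "-"
        length = 160
        start, end = cursor, cursor + length
        cursor = end + config.intergenic_gap
        name = f"SNR_{cls}_{si:02d}"
        t = Transcript(name + ".1", CHROM, strand, [Exon(CHROM, start, end, strand)])
        t._finalize()
        genes.append(Gene(name, CHROM, strand, [t]))
        snrna.setdefault(cls, []).append((name, CHROM, start, end, strand))
        gene_spans[name] = (CHROM, strand, start, end)

    annotation = GenomeAnnotation(genes)
    for _, t in annotation.transcripts():
        for intron in t.introns:
            if intron.key in set(u12_introns):
                intron.spliceosome_class = "U12"
    truth = SyntheticTruth(
        exons=exon_truth,
        gene_background=gene_background,
        gene_spans=gene_spans,
        pause_sites=pause_sites,
        snrna=snrna,
        u12_introns=sorted(set(u12_introns)),
        config=config,
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

def _sample_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Read lengths from the library mode's truncated-normal mixture."""
    if n == 0:
        return np.zeros(0, dtype=int)
    w_short, _ = config.footprint_weights
    pick_short = rng.random(n) < w_short
    out = np.empty(n, dtype=int)
    for comp, mask in ((SHORT_COMPONENT, pick_short), (LONG_COMPONENT, ~pick_short)):
        k = int(mask.sum())
        if k == 0:
            continue
        a = (comp.lo - comp.mode) / comp.sd
        b = (comp.hi - comp.mode) / comp.sd
        u = rng.random(k)
        vals = truncnorm.ppf(u, a, b, loc=comp.mode, scale=comp.sd)
        out[mask] = np.clip(np.round(vals), comp.lo, comp.hi).astype(int)
    return out


def _thinned_poisson(rng_base, rng_thin, lam: float, scale: float) -> int:
    """Poisson draw thinned binomially; the base draw is scale-independent
    so paired runs with a common seed share it (common random numbers)."""
    base = int(rng_base.poisson(lam))
    if scale >= 1.0 or base == 0:
        return base if scale >= 1.0 else (int(rng_thin.binomial(base, scale)) if scale > 0 else 0)
    return int(rng_thin.binomial(base, scale))


def simulate_mnetseq(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    config: SimulationConfig | None = None,
    treatment_scale: float | None = None,
    seed: int | None = None,
) -> list[AlignedRead]:
    """Emit aligned nascent 3'-end reads for the planted truth.

    Components: (a) background reads with 3' ends Poisson per transcribed
    nt and contiguous bodies; (b) intermediate reads ending exactly at
    exon 3'-terminal bases, spliced across the upstream junction with
    probability psi_true, otherwise contiguous into the upstream intron;
    (c) pause-site spikes; (d) snRNA 3'-end spikes.  Intermediate and
    snRNA counts scale with ``treatment_scale`` by binomial thinning of a
    shared base draw, so paired treated/untreated runs with the same seed
    are coupled.
    """
    config = config or truth.config
    scale = config.treatment_scale if treatment_scale is None else treatment_scale
    seed = config.seed if seed is None else seed
    reads: list[AlignedRead] = []
    counter = 0

    def make_read(blocks, strand, mismatches=0) -> AlignedRead:
        nonlocal counter
        counter += 1
        return AlignedRead(
            chrom=CHROM, strand=strand, blocks=blocks,
            mismatch_count=mismatches, is_unique=True, name=f"sim{counter}",
        )

    gene_ids = sorted(truth.gene_spans)
    exons_by_gene: dict[str, list[ExonTruth]] = {}
    for t in truth.exons.values():
        exons_by_gene.setdefault(t.gene_id, []).append(t)

    for gi, gene_id in enumerate(gene_ids):
        chrom, strand, tx_start, tx_end = truth.gene_spans[gene_id]
        rng_counts = np.random.default_rng([int(seed), 11, gi])
        rng_thin = np.random.default_rng([int(seed), 12, gi])
        rng_body = np.random.default_rng([int(seed), 13, gi])

        # --- intermediates at exon 3' termini --------------------------------
        for et in sorted(exons_by_gene.get(gene_id, []), key=lambda t: t.index):
            if et.intermediate_rate <= 0:
                continue
            n = _thinned_poisson(rng_counts, rng_thin, et.intermediate_rate, scale)
            if n == 0:
                continue
            lengths = _sample_lengths(rng_body, n, config)
            spliced_draws = rng_body.random(n) < et.psi_true
            _, _, e_start, e_end = et.key
            e_len = e_end - e_start
            up_exon = et.upstream_exon
            for L, spliced in zip(lengths, spliced_draws):
                L = int(L)
                ext = L - e_len
                if et.upstream_intron is None or ext < 1:
                    # body fits in the exon: uninformative by design
                    if strand == "+":
                        blocks = ((max(e_start, e_end - L), e_end),)
                    else:
                        blocks = ((e_start, min(e_end, e_start + L)),)
                elif spliced and up_exon is not None:
                    _, _, u_start, u_end = up_exon
                    take = min(ext, u_end - u_start)
                    if strand == "+":
                        blocks = ((u_end - take, u_end), (e_start, e_end))
                    else:
                        blocks = ((e_start, e_end), (u_start, u_start + take))
                else:
                    if strand == "+":
                        blocks = ((max(tx_start, e_start - ext), e_end),)
                    else:
                        blocks = ((e_start, min(tx_end, e_end + ext)),)
                mm = 1 if (config.mismatch_rate > 0 and rng_body.random() < config.mismatch_rate) else 0
                reads.append(make_read(blocks, strand, mm))

        # --- background over the transcribed span ----------------------------
        lam = truth.gene_background.get(gene_id, 0.0)
        span = tx_end - tx_start
        n_bg = int(rng_counts.poisson(lam * span)) if lam > 0 else 0
        if n_bg:
            ends = rng_body.integers(tx_start, tx_end, n_bg)
            lengths = _sample_lengths(rng_body, n_bg, config)
            for p, L in zip(ends, lengths):
                p, L = int(p), int(L)
                if strand == "+":
                    blocks = ((max(tx_start, p - L + 1), p + 1),)
                else:
                    blocks = ((p, min(tx_end, p + L)),)
                reads.append(make_read(blocks, strand))

        # --- snRNA 3'-end spikes ---------------------------------------------
        for cls_genes in truth.snrna.values():
            for name, chrom_, s_start, s_end, s_strand in cls_genes:
                if name != gene_id:
                    continue
                n = _thinned_poisson(rng_counts, rng_thin, config.snrna_rate, scale)
                lengths = _sample_lengths(rng_body, n, config)
                for L in lengths:
                    L = int(L)
                    if s_strand == "+":
                        blocks = ((max(s_start, s_end - L), s_end),)
                    else:
                        blocks = ((s_start, min(s_end, s_start + L)),)
                    reads.append(make_read(blocks, s_strand))

    # --- pause-site spikes ---------------------------------------------------
    for pi, (chrom, strand, pos, rate) in enumerate(truth.pause_sites):
        rng_p = np.random.default_rng([int(seed), 14, pi])
        n = int(rng_p.poisson(rate))
        lengths = _sample_lengths(rng_p, n, config)
        for L in lengths:
            L = int(L)
            if strand == "+":
                blocks = ((max(0, pos - L + 1), pos + 1),)
            else:
                blocks = ((pos, pos + L),)
            reads.append(make_read(blocks, strand))
    return reads


def chrom_sizes(truth: SyntheticTruth, margin: int = 1000) -> dict[str, int]:
    end = max(e for _, _, _, e in truth.gene_spans.values()) + margin
    return {CHROM: end}


# ---------------------------------------------------------------------------
# Nucleoplasmic junction counts for PSI
# ---------------------------------------------------------------------------

def simulate_npseq(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    depth: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Junction-count table (chrom, strand, donor, acceptor, reads).

    Inclusion junctions adjacent to a skippable exon draw
    Binomial(depth, psi_true) reads each; junctions between fixed exons
    carry the full depth; the skipping junction draws
    Binomial(depth, 1 - psi_true).
    """
    seed = truth.config.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), 21])
    rows: list[dict] = []

    def junction_row(key: IntronKey, reads: int) -> dict:
        chrom, strand, start, end = key
        donor = start if strand == "+" else end - 1
        acceptor = end - 1 if strand == "+" else start
        return dict(chrom=chrom, strand=strand, donor=donor, acceptor=acceptor, reads=int(reads))

    exons_by_gene: dict[str, list[ExonTruth]] = {}
    for t in truth.exons.values():
        exons_by_gene.setdefault(t.gene_id, []).append(t)

    for gene_id in sorted(exons_by_gene):
        ets = sorted(exons_by_gene[gene_id], key=lambda t: t.index)
        by_index = {t.index: t for t in ets}
        n_exons = len(ets)
        for k in range(n_exons - 1):
            junction = by_index[k].downstream_intron
            if junction is None:
                continue
            left, right = by_index[k], by_index[k + 1]
            variable = None
            if left.has_skip_junction:
                variable = left
            elif right.has_skip_junction:
                variable = right
            if variable is None:
                reads = depth
            else:
                reads = int(rng.binomial(depth, variable.psi_true))
            rows.append(junction_row(junction, reads))
        for et in ets:
            if not et.has_skip_junction:
                continue
            prev_exon = by_index[et.index - 1]
            next_exon = by_index[et.index + 1]
            _, _, p_start, p_end = prev_exon.key
            _, _, n_start, n_end = next_exon.key
            chrom, strand, _, _ = et.key
            if strand == "+":
                skip_key = (chrom, strand, p_end, n_start)
            else:
                skip_key = (chrom, strand, n_end, p_start)
            rows.append(
                junction_row(skip_key, rng.binomial(depth, 1.0 - et.psi_true))
            )
    return pd.DataFrame(rows, columns=["chrom", "strand", "donor", "acceptor", "reads"])


# ---------------------------------------------------------------------------
# Proteomics simulation
# ---------------------------------------------------------------------------

def simulate_proteomics(
    n_proteins: int = 2000,
    n_enriched: int = 0,
    ip_replicates: int = 3,
    mock_replicates: int = 3,
    true_log2fc: float = 2.0,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    noise_sd: float = 0.3,
    missing_max: float = 0.0,
    missing_midpoint: float = 21.0,
    missing_scale: float = 1.0,
    ip_label: str = "S5P",
    mock_label: str = "mock",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intensity matrix (linear scale, NaN = missing) plus per-protein truth.

    log2 intensities are Normal(base_i + true_log2fc * is_ip, noise_sd);
    values are censored with a logistic probability that increases as
    intensity decreases (missing-not-at-random), capped at
    ``missing_max``.
    """
    rng = np.random.default_rng([int(seed), 31])
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    fc = np.zeros(n_proteins)
    fc[:n_enriched] = true_log2fc
    base = rng.normal(base_mean, base_sd, n_proteins)
    cols = [f"{ip_label}_{r + 1}" for r in range(ip_replicates)] + [
        f"{mock_label}_{r + 1}" for r in range(mock_replicates)
    ]
    is_ip = np.array([1] * ip_replicates + [0] * mock_replicates)
    log2x = (
        base[:, None]
        + fc[:, None] * is_ip[None, :]
        + rng.normal(0.0, noise_sd, (n_proteins, len(cols)))
    )
    matrix = pd.DataFrame(np.power(2.0, log2x), index=proteins, columns=cols)
    matrix.index.name = "protein"
    if missing_max > 0:
        p_miss = missing_max / (1.0 + np.exp((log2x - missing_midpoint) / missing_scale))
        mask = rng.random(log2x.shape) < p_miss
        matrix = matrix.mask(mask)
    truth = pd.DataFrame(
        dict(protein=proteins, true_log2fc=fc, is_enriched=fc > 0)
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Deterministic Ensembl-dialect GTF (1-based closed coordinates)."""
    with open(path, "w") as out:
        for g in annotation.genes:
            g_start = min(t.start for t in g.transcripts)
            g_end = max(t.end for t in g.transcripts)
            attrs = f'gene_id "{g.gene_id}";'
            out.write(
                f"{g.chrom}\tnetsplice\tgene\t{g_start + 1}\t{g_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                out.write(
                    f"{g.chrom}\tnetsplice\ttranscript\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    eattrs = tattrs + f' exon_number "{e.index + 1}";'
                    out.write(
                        f"{g.chrom}\tnetsplice\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{eattrs}\n"
                    )


def write_u12_bed(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as out:
        for i, (chrom, strand, start, end) in enumerate(truth.u12_introns):
            out.write(f"{chrom}\t{start}\t{end}\tu12_{i}\t0\t{strand}\n")


def write_junction_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_intensity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")
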