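# netsplice

Analysis toolkit for nascent-RNA 3′-end sequencing of Pol II complexes
(mNET-seq-style data): from strand-specific alignments and a GTF annotation
to splicing-intermediate peak calls, spliced/unspliced intermediate
statistics, percent-spliced-in (PSI) inclusion analysis, snRNA association
counts, Pol II footprint-length histograms, and label-free IP-MS enrichment
tables. A synthetic-data generator with planted ground truth stands in for
deposited sequencing/proteomics data, so every stage is testable offline.

## What it computes

- **`netsplice.annotation`** — GTF parsing (Ensembl dialect, converted to
  0-based half-open), per-transcript intron derivation, internal-exon
  classification (constitutive / skipped / alt-5′ss / alt-3′ss /
  overlapping), exact-interval U12-intron labelling from a BED list, and
  expressed-gene thresholding at the local minimum of the bimodal
  log2-FPKM kernel density.
- **`netsplice.reads` / `netsplice.coverage`** — SAM and BED12 readers and
  writers with a configurable strand-chemistry flag (default `reverse`),
  sparse single-nucleotide 3′-end coverage with RPM scaling, footprint
  length histograms over TSS-anchored windows, padded snRNA class counts
  (expressed at log2 RPM ≥ 1 in a reference sample), read-average density
  RAD = TR/(EL−3) with intermediate-contaminated terminal positions
  trimmed, treatment-sensitivity ratios, and metagene profiles.
- **`netsplice.peaks`** — the feature-local peak caller: a position is a
  peak when its raw count is ≥ 4 reads, at least three population standard
  deviations above the feature mean, and strictly above the mean.
  Splice-site mode tests only exon/intron 3′-terminal nucleotides (5′ ss
  and 3′ ss intermediates); pause mode removes the last 3 exon / first 3
  intron nucleotides and tests every remaining position. Replicate
  consensus keeps peaks identical in (chrom, strand, position, kind)
  across all sets.
- **`netsplice.splicing`** — spliced-read detection (unique, zero
  mismatches, every block gap an annotated intron, ≥ 9 nt aligned on each
  side of every junction), splicing events (≥ 3 reads), and SR/UR
  classification of reads ending at exon 3′ termini, with
  spliced% = 100·SR/(SR+UR) defined at ≥ 10 informative reads, plus
  rank-sum and Kolmogorov–Smirnov group comparisons
  (constitutive vs skipped, U2- vs U12-preceded).
- **`netsplice.psi`** — junction-count PSI with the structural filters
  (alt splice sites, same-strand exon overlap, exon < 100 bp, preceding
  intron < 100 bp, both inclusion junctions ≥ 5 reads) and the
  peak-vs-PSI overlap table.
- **`netsplice.proteomics`** — log2 transform, downshifted-normal
  imputation (shift 1.8 sd, width 0.3 sd), per-sample median centering,
  per-protein t-test against mock (Welch default, pooled toggle),
  Benjamini–Hochberg or permutation FDR, enrichment at q ≤ 0.05 with
  positive fold change, volcano and pairwise scatter tables.
- **`netsplice.simulate`** — deterministic generators for annotations,
  nascent reads (background, intermediates with planted spliced
  fractions, pause and snRNA spikes, 27/60-nt footprint mixtures,
  detergent-treatment scaling via coupled binomial thinning), junction
  counts, and MNAR intensity matrices — each with a planted-truth table.

## CLI

```bash
netsplice all --out-dir run/ --seed 7            # simulate + every stage
netsplice simulate --out-dir run/ --config cfg.yaml
netsplice coverage  --reads run/reads.sam --gtf run/genome.gtf --out-dir run/
netsplice peaks     --reads run/reads.sam --gtf run/genome.gtf --out-dir run/
netsplice splicing  --reads run/reads.sam --gtf run/genome.gtf --out-dir run/
netsplice psi       --junctions run/npseq_junctions.tsv --gtf run/genome.gtf --out-dir run/
netsplice proteomics --matrix run/proteomics.tsv \
    --ip-samples S5P_1,S5P_2,S5P_3 --mock-samples mock_1,mock_2,mock_3 --out-dir run/
```

All artifacts are plain text (GTF, SAM, BED12, bedGraph, TSV); every run
directory carries a `manifest.json` with the configuration, seed, input
and output checksums, and per-stage record counts. Reruns with the same
config and seed are byte-identical.

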