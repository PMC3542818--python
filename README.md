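# nucleoscan

Detection of positioned nucleosomes from single-end sequencing of
MNase-digested mononucleosomal DNA (BAM, SAM or BED6 alignments).

## Method

1. **Center landscape** — each read's 5' end is converted into a discretized
   beta probability distribution over nucleosome-center offsets {68..78} bp
   (forward reads to the right, reverse reads to the left); summing over all
   reads yields a per-base relative probability landscape of centers.
2. **Triangle statistic** — a 200 bp window partitioned 75/50/75 slides
   across the landscape base-by-base; central enrichment is scored as the
   smaller of the odds B/A and B/C — estimated median-unbiasedly via
   incomplete-beta tail inversion, which is stable at small masses —
   divided by the uniform-null odds 2·B_w/(W−B_w) = 50/75.
3. **N-statistic** — a binary decorrelation step keeps a window only if it
   is a strict local maximum over 25 windows left, a tie-tolerant maximum
   over 26 windows right, reaches the cutoff t_c (default 1.7), and has no
   comparable clump of statistics one nucleosome-width away ("insurance"
   sums). Successive calls are therefore at least 26 bp apart.
4. **FDR by read shaking** — every read position is shifted by an
   independent uniform integer in {−73..73}; detection is re-run S times on
   shaken data, and each candidate's FDR is the mean ratio of simulated to
   real exceedance counts at its statistic. Candidates above the cutoff F
   (default 0.01) are dropped.

Outputs are a tab-separated centers table (chrom, center, triangle
statistic, FDR) and a variableStep WIG track of centers vs statistics,
named `[alignment filename]_[datestamp]_[timestamp].{txt,wig}`.

## Command line

```sh
# full pipeline (presets: ce10, mm9, mm10, hg18, hg19; or a 2-column TSV)
nucleoscan run --alignments reads.bam --genome hg19 \
    --window 200 --center-width 50 --tc 1.7 --fdr 0.01 \
    --sims 3 --threads 4 --seed 1 --out results/

# ground-truthed synthetic fixture
nucleoscan simulate --length 50000 --spacing 2500 --reads-per-side 50 \
    --jitter-sd 5 --background 1e-4 --seed 7 --out fixtures/sim

# fit beta offset shapes from read-to-center half-distances (one per line)
nucleoscan calibrate --distances half_distances.txt

# shifted-extended nucleosome coverage as BedGraph
nucleoscan coverage --alignments reads.bed --chrom-lengths chrom.tsv \
    --out coverage.bedgraph
```

`nucleoscan run --help` documents every parameter. A `key=value` config
file can be passed with `--config`; explicit flags take precedence. The
thread count only sizes the worker pool — results are bit-identical for any
`--threads` because chromosomes are processed in overlapping chunks whose
cores tile the genome, and every per-chunk decision is computable locally.

## Package layout

| module | contents |
| --- | --- |
| `formats_io` | SAM/BAM/BED reading, chromosome tables, TXT/WIG writers |
| `center_model` | offset pmf (discretized beta), landscape, shape MLE |
| `triangle` | median-unbiased odds, triangle statistic, window scan |
| `detection` | N-statistic, candidate calls, chunked/parallel scanning |
| `fdr_sim` | read shaking, Monte Carlo FDR, candidate filtering |
| `coverage` | display coverage track, strand histograms, BedGraph |
| `synthetic` | ground-truthed fixture generator (BED/SAM) |
| `cli` | `nucleoscan` entry point and pipeline orchestration |
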