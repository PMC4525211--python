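# chriplex

Desk-scale toolkit for analysing repressive-chromatin-associated lncRNAs:

- **`chriplex.simulate`** — synthetic genomes, annotations, ChRIP count
  tables, conversion pileups, peak sets and gene universes with planted
  ground truth, so every stage is testable offline.
- **`chriplex.enrichment`** — RPKM quantification and the dual pull-down
  enrichment rule (a transcript counts as repressive-chromatin enriched
  only when its fold change over input reaches the threshold, default 2.0
  inclusive, in *both* the H3K27me3 and EZH2 samples), plus an exact
  upper-tail hypergeometric set-overlap test.
- **`chriplex.conversions`** — T-to-C transition calling from pileup-style
  base counts (supporting-read depth ≥ 2 by default), pull-down-specific
  event selection by genomic-key set difference, 12-type substitution
  spectra, and strand-aware mapping of events onto spliced transcripts
  (genomic A>G inside a minus-strand exon is reported as transcript T>C).
- **`chriplex.peaks`** — basal-plus-extension regulatory domains
  (5 kb up / 1 kb down / 1 Mb extension by default), summit-based
  peak-to-gene association with a promoter/distal partition, interval
  intersection, one-sided Fisher gene-set enrichment with BH adjustment,
  and a GA-run-length surrogate motif statistic with an empirical
  shuffle-based p-value.
- **`chriplex.triplex`** — triplex-forming-oligo (TFO) and triplex target
  site (TrTS) scanning under purine / pyrimidine / mixed motif alphabets
  with length, error-rate, consecutive-error and guanine-content
  constraints; Hoogsteen triad matching of TFOs against TrTS purine
  strands; and summit-versus-flank TrTS density with a paired sign test.
- **`chriplex.io` / `chriplex.pipeline` / `chriplex.cli`** — FASTA / GTF /
  BED6+1 / TSV / GMT readers and writers (internal coordinates are always
  0-based half-open) and end-to-end orchestration with a reproducible
  manifest.

## Test

```sh
python -m pytest -q tests/
```

The suite cross-checks every scanner and statistic against independent
brute-force oracles (exhaustive window enumeration, full combinatorial
enumeration of hypergeometric and Fisher tails, quadratic interval scans)
and validates planted-truth recovery on the simulator.

## CLI

```sh
chriplex simulate --seed 1 --outdir sim/
chriplex enrich --counts sim/chrip_counts.tsv --gtf sim/transcripts.gtf \
    --fold 2.0 --outdir enr/
chriplex convert --pileup-ezh2 sim/pileup_ezh2.tsv \
    --pileup-input sim/pileup_input.tsv \
    --pileup-h3k27me3 sim/pileup_h3k27me3.tsv \
    --gtf sim/transcripts.gtf --min-alt-depth 2 --outdir conv/
chriplex triplex tfo --rna rna.fa --out tfo.tsv
chriplex triplex trts --genome sim/genome.fa --bed sim/chop_peaks.bed --out trts.tsv
chriplex triplex density --genome sim/genome.fa --bed sim/chop_peaks.bed \
    --window 200 --out density.tsv
chriplex peaks associate --bed sim/chop_peaks.bed --gtf sim/transcripts.gtf \
    --out assoc.json
chriplex peaks intersect --bed-a sim/chop_peaks.bed --bed-b sim/h3k4me1_peaks.bed
chriplex run --seed 1 --outdir run/        # full pipeline on a fresh simulation
```

Exit codes: 0 success, 2 validation error, 3 stage error.

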