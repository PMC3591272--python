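# utr3end

Analysis of yeast 3′-end reporter libraries: how the sequence downstream of
a gene — its 3′ UTR and terminator region — shapes expression.

The package is written for experiments in which a library of *S. cerevisiae*
strains differ only in the region cloned downstream of a fluorescent
reporter (from the stop codon to the next ORF, up to 1 kb). It covers the
four analyses such an experiment needs, plus synthetic-data generators that
plant recoverable ground truth for each input class:

- **`platereader`** — per-strain expression from plate-fluorometer growth
  curves: background subtraction, outlier masking, automatic lag /
  exponential / linear / stationary phase segmentation, and the production
  measure *P* = ΔF / ∫OD dt (fluorescence produced per cell per second
  during exponential growth), plus a clone-concordance filter.
- **`polya`** — polyadenylation-site mapping from 3′ RACE reads: UMI and
  poly(T) trimming, seed-and-extend mapping against the cloned reference,
  and cleavage-site calling with the first-non-A resolution rule; per-gene
  site profiles with a read-depth flag.
- **`seqfeatures`** — polyA-anchored sequence analysis: window-composition ×
  expression correlation grids with permutation calibration,
  expression-grouped positional G/C profiles, k-mer association, IUPAC motif
  scanning (efficiency/positioning elements), and whole-UTR features.
- **`stats`** — nested-regression F-tests for variance partitioning,
  single-cell gating (median ± k·MAD scatter gates), noise decomposition and
  burst statistics, between-plate correction, and orientation-group
  comparisons.
- **`simulate`** — generators for all four input classes: logistic growth
  with reporter accumulation, poly(A)-tailed reads with heterogeneous
  cleavage sites, sequence libraries with a planted A/T-content → expression
  effect, and gamma-distributed bursty single-cell populations with a spore
  subpopulation.

The central quantitative ideas: the junction between a read's poly(T) tail
and the genome is a cleavage site (resolvable only to the first non-A
upstream); the polyadenylation site with the most reads anchors the
sequence analysis; and under the gamma burst model an isogenic population's
expression is Gamma(a, b), so burst frequency a = mean²/variance = 1/η² and
burst size b = variance/mean = ν are read directly off single-cell moments.

## Worked example

Simulate a plate of strains with known production rates and recover them
(`examples/02_plate_expression.py`):

```
strain      true P  recovered  rel err  window (h)
strain0      0.500      0.493    1.4%   0.0-5.7
strain1      1.000      1.008    0.8%   0.0-7.3
strain2      1.500      1.500    0.0%   0.0-6.0
strain3      2.000      2.008    0.4%   0.0-6.7
```

Each row is one well: the planted production rate, the rate recovered by the
full pipeline (background subtraction → outlier masking → phase segmentation
→ production), and the exponential window used. Despite 1% measurement
noise and spike artefacts the planted rates come back within ~2%.

Locate the sequence signal that drives expression
(`examples/04_scan_at_content.py`):

```
planted window:   30 bp at offset -40
grid peak:        30 bp at offset -40, Pearson r = 0.995
null 95% band:    |r| <= 0.279 (observed peak is outside)
```

The scan correlates window A/T content with expression across the library
for every (window size, position) pair anchored at the main polyA site; the
grid argmax recovers the planted 30-bp window 40 bp upstream of the
cleavage site, far outside the permutation null.

The other examples cover library generation, polyA-site mapping from RACE
reads, burst-statistics extraction, and nested-regression variance
partitioning; each prints the numbers it computes and what they mean.

A thin CLI mirrors the library for shell use:

```bash
utr3end simulate --out-dir sim --seed 1
utr3end plate --plate sim/plate.tsv --layout sim/layout.yaml --out expr.tsv
utr3end polya --fastq sim/reads.fastq --fasta sim/library.fasta \
              --annot sim/library.tsv --out-prefix polya
utr3end scan  --fasta sim/library.fasta --annot sim/library.tsv --out grid.tsv
```

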