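# Methods

`utr3end` reimplements, as a tested library, the computational analysis of a
yeast 3′-end reporter experiment: a library of strains that differ only in
the sequence cloned downstream of a YFP reporter (stop codon to the next ORF,
up to 1 kb), measured in bulk on a plate fluorometer and in single cells by
flow cytometry, with polyadenylation sites mapped by 3′ RACE sequencing.
Because no raw measurements are bundled, every input class has a synthetic
generator with planted ground truth; the test suite closes the loop
generate → process → estimate and checks the truth is recovered.

## Coordinate conventions

Offsets within a cloned sequence are 0-based from the first base after the
stop codon. Windows are half-open `[start, end)`. `cleavage_site` is the
inclusive offset of the last transcribed base (the base 5′ of the poly(A)
tail). Window centre offsets are relative to an anchor (cleavage site or UTR
start); negative means upstream.

## Plate-reader expression

The expression measure is the rate of fluorescence production per cell per
second: fluorescence gained during the exponential growth phase divided by
the time integral of OD over the same window (units a.u.·OD⁻¹·s⁻¹).
Processing steps:

1. **Background subtraction** — media blank for OD; the mCherry-only strain's
   YFP channel (cell autofluorescence) for YFP; the YFP-only strain for
   mCherry. Blank series are aligned by nearest timestamp (within half the
   sampling interval) and interpolated over their valid points, so a masked
   artefact in a blank well cannot leak into every sample well.
2. **Point-outlier masking** — point *i* is masked when it deviates from the
   running median (window `w = 5`) by more than `k = 5` local MADs, applied
   per channel. When the local MAD is zero only exact deviations are flagged.
   More than 10% masked points raises a QC warning.
3. **Phase segmentation** — the smoothed derivative of log(OD + 10⁻⁴)
   (centred moving linear fit over 11 points) defines the exponential phase
   as the longest run at ≥ 0.8× the slope maximum; lag precedes it, the
   stationary phase is the trailing run where the OD derivative falls to
   ≤ 5% of its own maximum, and the linear phase is the remainder. Two
   robustness details matter in practice: the slope maximum is the median of
   the five largest smoothed slopes (a single noisy estimate, typically at a
   shrunken edge window, must not set the threshold), and runs bridge
   sub-threshold gaps of up to two points. With a 5-point smoother and 1%
   measurement noise the slope noise is ~5% of the growth rate and the
   exponential run fragments into 5–9-point pieces; the 11-point smoother
   keeps windows of ~20 points. A curve must reach 3× its (median-of-first-5)
   initial OD, else a no-growth error is raised.
4. **Production** — since dF/dt = P·OD(t) during the window, F is exactly
   linear in the running OD integral I(t). The default estimator is the
   least-squares slope of F against I over the exponential-phase points:
   identical to the defining endpoint ratio (F_end − F_start)/∫OD for clean
   data, but using all ~20 window points instead of two. Before the fit,
   points whose residual from a local-quadratic trend exceeds 5 scaled MADs
   (floored at 10% of the trend, so plain noise is never flagged) are dropped
   per channel — this catches spike artefacts that survive the running-median
   rule on steeply growing series, where a 3× spike sits inside the local
   scatter — and both channels are damped with a centred moving
   local-quadratic fit (exact for locally quadratic trends). The literal
   endpoint form is available as `method="endpoint"`.

YFP is not normalised to mCherry by default; `normalize_mcherry=True`
divides by the mCherry production rate over the same window. Clone
concordance follows an accept-if-two-agree rule: a strain is kept when its
best clone pair differs by at most 15% of the pair mean, and takes that
pair's mean.

## PolyA-site mapping from 3′ RACE

Reads carry a 12-nt random UMI, a poly(T) block (the primer guarantees at
least 18 T's), then the reverse complement of the transcript 3′ end.
Trimming extends the T-run greedily, tolerating one mismatch per 10 nt of
run — but only within the first 18 nt (the primer-guaranteed stretch) and
only when the mismatch is followed by three more T's. Beyond 18 nt every T
could be a genomic A read in reverse complement, so the run extends over
literal T's only; this keeps the poly(T)/genome junction from being chewed
into upstream sequence. Reads with tails under 8 nt or inserts under 20 nt
are rejected with counted reasons.

Mapping uses an exact 15-mer index over both strands of the (tiny) cloned
reference with ungapped extension, at most 2 mismatches, and a uniqueness
margin of 2 mismatches; seeds are taken at offsets 0, 15 and 30, which by
pigeonhole finds every ≤2-mismatch placement of inserts ≥ 45 nt. Indels are
not modelled (no gapped alignment). Reverse-strand placements are rejected:
a genuine 3′ RACE insert is in genomic orientation by construction.

The junction between the poly(T) and the mapped sequence is the cleavage
site. Genomic A's adjacent to the site are absorbed into the tail, so calls
resolve deterministically to the first non-A at or upstream of the true
site — the intrinsic resolution limit of poly(A)-primed mapping. Per-gene
profiles take the main site as the count argmax (ties to the most upstream
position); a gene passes depth when it has strictly more than 1000 reads.
UMI deduplication is off by default and collapses identical (UMI, position)
pairs when enabled.

## Sequence-feature scans

`window_at_content` reports the A/T (or G/C) fraction of a window anchored
at the cleavage site or UTR start; windows truncated at sequence bounds
report the truncated fraction plus a flag, and windows fully outside are
undefined (never 0). The scan grid correlates window composition with
expression (Pearson, linear expression by default) over sizes 10–100 bp and
centre offsets −200…+50 bp in 5-bp steps; cells with fewer than three
contributing constructs or a constant feature are undefined. Family-wise
calibration is by permutation: the null distribution of the grid-wide
max |r| under expression shuffling. No multiple-testing correction is
applied to the grid itself.

Grouped positional G/C profiles split genes into bottom/top expression
quantiles (default 0.2 each) plus the middle, and average the G/C fraction
of 20-bp centred windows per offset. K-mer association uses Spearman rank
correlation (Pearson on tie-averaged ranks) with a joint permutation p-value
(all k-mers re-scored per shuffle, +1-smoothed). Motif scanning matches
IUPAC degenerate patterns exactly, overlaps allowed; the bundled defaults
are the A/T-rich efficiency element (`TAYRTA`, plus the literal `TATATA`)
and the A-rich positioning element (`AAWAAA`), both configurable.

Whole-UTR features include length, composition, and a pairing score: the
maximum number of nested base pairs (Watson-Crick plus G·T wobble, minimum
hairpin loop 3) from a base-pair-maximisation dynamic programme. This is a
declared proxy for folding stability, not a free energy; externally computed
energies can be attached per gene through a hook.

## Single-cell noise and burst statistics

Under the gamma burst model, per-cell expression is Gamma(a, b) with a =
bursts per protein lifetime and b = proteins per burst, so noise
η² = σ²/μ² = 1/a and noise strength ν = σ²/μ = b. The estimators are
burst_frequency = 1/η² and burst_size = ν, with the unbiased (n−1) variance;
the identities ν = η²μ and frequency·size = μ hold to machine precision by
construction. Gating keeps cells within median ± 2.5 scaled MADs (×1.4826)
on both scatter channels — spores form a low-scatter cluster and are removed
by the same rule — with an optional central mCherry band to trim extrinsic
variation. Between-plate correction uses a galactose-insensitive reference
strain: with c_p = (grand mean of reference)/(reference mean on plate p),
means scale as μ′ = μ·c_p and, because η² scales as 1/mean, η′² = η²/c_p and
ν′ = η′²·μ′ (= η²μ, preserved).

The orientation comparison (tandem vs convergent downstream neighbours) uses
a two-sided Mann-Whitney rank-sum test plus a two-sample Kolmogorov-Smirnov
statistic, and per-group Spearman correlations of expression against
intergenic length and any supplied covariates.

The nested-regression F-test fits both models by least squares with an
intercept, requires the reduced predictors to be a column subset of the full
design, and refuses rank-deficient designs. F = ((RSS_r − RSS_f)/Δdf) /
(RSS_f/(n − df_f)) with the upper-tail F probability; a perfect full fit
reports the smallest positive double rather than p = 0.

## The synthetic generators: what they emulate, and what they do not

**Construct library.** Sequences of 200–1000 bp with uniform base
composition (configurable A/T bias), a main cleavage site ≥ 25 bp from the
sequence start, and 0–3 satellite sites with discretised-normal jitter
(sd 15 bp) whose weights leave the main site 50–85% of reads. The planted
effect overwrites a 30-bp window centred 40 bp upstream of the main site
with A/T levels stratified over [0.1, 0.9] across the library (jittered
stratification, so every library covers the compositional range);
expression = β₀ + β₁ · (realised window A/T) + N(0, σ_e), truncated at 0,
with defaults β₀ = 0, β₁ = 8, σ_e = 0.2. The defaults reproduce the
experimental observation the generator stands in for: a continuous span of
more than ten-fold between the lowest- and highest-expressing strains.
Real 3′ ends differ in ways the generator does not model: composition
gradients, motif grammar, secondary structure, and correlated
length/expression effects. Passing recovery tests therefore demonstrates
the pipeline inverts this generative model, not that A/T content is the
only signal in real data.

**Plate curves.** Shared logistic OD (K = 1.2 OD, od₀ = 0.05,
r = 7.7×10⁻⁵ s⁻¹, a ~150-min doubling appropriate to a raffinose-based
medium), fluorophores accumulating as dF/dt = P·OD(t) with no degradation
(both reporters are long-lived), additive backgrounds (media OD offset;
autofluorescence a + b·OD per channel), multiplicative Gaussian noise
(default 1%), and spike artefacts at a configurable rate with magnitudes
drawn U(3, 10) — plate-reader artefacts range from marginal to gross.
Sampling every 20 min over 24 h. Diauxie, evaporation drift, and
settling are not modelled.

**3′ RACE reads.** Cleavage sites drawn from the construct's true
distribution; fragment lengths 60–100 nt; tail lengths 18 + geometric
(mean 25 nt); optional uniform substitution errors and defective short-tail
reads. Ligation/priming biases and indel errors are not modelled.

**Cell populations.** YFP ~ Gamma(a, b) times a lognormal extrinsic factor
(unit mean, configurable CV) shared with the mCherry channel; lognormal
forward/side scatter; a spore fraction with 0.3× scatter and 0.1×
fluorescence. Instrument autofluorescence floors and cell-cycle structure
are not modelled.

## Numerical choices and degenerate inputs

- Pearson/Spearman cells are undefined (`nan`) rather than 0 when fewer than
  3 points contribute or a variable is constant.
- The main-site tie-break is the most upstream position — deterministic and
  conservative for UTR length.
- The no-growth check and phase thresholds operate on robust statistics
  (medians of small sets) so single artefacts cannot flip them.
- All generators accept either an integer seed or a `numpy` `Generator`;
  fixed seeds give bit-identical outputs.
- Log-scale expression tables are exponentiated on load (`expression_scale`
  flag) so in-memory expression is always linear.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run the loop at the study's
scale where that is cheap (85-construct libraries; 50 genes × 10,000 RACE
reads; 20-strain plates; 10⁵-cell populations; 10,000 null regressions at
n = 85) and at reduced scale for auxiliary demonstrations (examples use
2,000 reads/gene and 5×10⁴ cells). Permutation nulls use 300–1000 shuffles.

## Known limitations

- The aligner is ungapped; reads with indels would be rejected rather than
  recovered (acceptable at the error rates simulated).
- The pairing score is a base-pair count, not an energy; it correlates only
  loosely with thermodynamic stability.
- Plate correction assumes a purely multiplicative between-plate effect.
- The FCS binary format is not parsed; single-cell data enter as TSV/CSV
  exports.
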