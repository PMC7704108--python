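# Methods

## Biological model

Sustained TNF-α signalling activates NF-κB; its p65 subunit binds κB sites
genome-wide. Where a κB site sits in a CpG-dense, heavily methylated region,
p65 binding is initially disfavored, and prolonged occupancy recruits
TET-dependent active demethylation. Because the hypomethylated state is
mitotically heritable, it persists after the stimulus is withdrawn and lowers
the activation threshold for the next exposure. The package quantifies the
three observable layers of this model — locus methylation from bisulfite
clones, peak-level methylation dynamics around κB motifs, and the
five-condition expression signature of memory genes — and generates synthetic
data with the same structure.

## Bisulfite clone quantification

Clones are gapless images of a fixed amplicon: bisulfite PCR amplifies a
defined locus, so length differences indicate indels and such clones are
rejected outright rather than realigned. Calls at CpG cytosines are
C → methylated, T → unmethylated, anything else (N, miscalls) → missing;
missing calls enter neither numerator nor denominator of the pooled level.
Only the top strand is modelled. Conversion efficiency is estimated per clone
from non-CpG cytosines; QC defaults (minimum conversion 0.95, maximum
mismatch 0.10) are conventional for bisulfite Sanger work. The pooled locus
level is identical to the call-count-weighted mean of per-CpG levels, which
the tests assert.

## Memory-gene classifier

Thresholds: responsiveness requires a first-induction fold change strictly
above 2 at p < 0.01; memory additionally requires a second/first induction
ratio of at least 1.3 (inclusive) and a second-induction mean FPKM strictly
above 5. The FPKM floor is applied to the second induction because that is
the condition in which memory is asserted. A pseudocount of 1 FPKM enters
every ratio and logarithm, so all statistics are defined for silent genes;
fold-change calls are scale-equivariant up to that pseudocount. The
significance engine is deliberately pluggable: the default two-sided Welch t
on log2(FPKM+1) across replicates is a reasonable desk-scale stand-in for a
count-based differential-expression model, and `call_responsive` accepts
externally computed p-values when one is available. No multiple-testing
correction is applied to the memory criteria; raw p-values are reported.
"Excellent" versus "moderate" memory is not thresholded — the raw
second/first ratio is reported instead.

## Peak module scoring

* **Motif hit.** Log-odds PWM scan against a uniform background on both
  strands; ties break to the leftmost position, then the + strand. The motif
  center of an even-length motif is start + length/2 (integer floor).
* **Flank CpGs.** CpG cytosines with |position − motif center| ≤ 250 bp,
  boundary inclusive.
* **Total methylation.** M = Σ per-CpG levels over covered flank CpGs, in
  methylated-CpG equivalents. CpGs under 5× coverage are excluded, not
  imputed; a peak with zero usable CpGs carries a no-data sentinel and is
  dropped (with a logged count) from methylation-stratified analyses, never
  silently scored 0. By construction M_t0 − ΔM = M_t12 and 0 ≤ M ≤ CpG count.
* **States and groups.** Initially methylated means mean level ≥ 0.50,
  unmethylated < 0.20, both boundaries as stated. The top-demethylation group
  is ΔM strictly greater than Q3 under the type-7 (linear interpolation)
  quantile definition, applied to initially methylated peaks; quantile modes
  cut equal-count bins in sorted order.
* **Gene linking.** Nearest TSS by |motif center − TSS| with a 100 kb cap,
  inclusive; ties break to the smaller gene id; a within-10 kb flag supports
  distance stratification. The cap is a flag because reasonable analyses use
  50 kb as well.
* **Responsive elements.** Induced p65 peaks are those present after 12 h of
  stimulation with no ≥ 1 bp overlap with any unstimulated peak — the
  simplest reproducible presence/absence rule; responsive elements are the
  induced peaks overlapping H3K27ac by ≥ 1 bp. Consensus peak sets merge
  overlapping or bookended intervals from both inductions and drop anything
  overlapping a blacklist.
* **Demethylation profile.** Per-CpG levels are plotted by signed distance to
  the motif center (motif strand orients the axis) and lowess-smoothed
  (span 0.3 by default) onto a fixed grid. The difference curve smooths the
  per-CpG differences t0 − t12 — pointwise pairing is defined at CpGs, and
  smoothing after subtraction avoids grid mismatch between two separate fits.
  At least 10 covered CpGs are required.
* **Signal normalization.** Tracks are first depth-normalized (counts per
  million), then scaled so every sample has the same mean signal at initially
  unmethylated peaks — regions whose occupancy methylation change cannot have
  altered, hence a stable anchor. The operation is idempotent. Occupancy
  change between inductions splits at 1.5-fold (inclusive), an exposed flag.
* **eRNA.** RPKM = count / (peak length in kb × library size in millions);
  group comparisons use a paired two-tailed t-test on log2(RPKM+1)
  differences.

## Synthetic-data generators

All generators are bit-deterministic given the `SimulationConfig` seed;
sub-generators derive fixed offsets from it so stages are independently
reproducible.

* **Clones.** Non-CpG cytosines convert C→T with probability 0.99
  (conversion efficiency); CpG cytosines are retained with their per-site
  methylation probability; every base then suffers a uniform substitution at
  rate 0.001. The CMV-promoter-like locus has 17 CpGs and three κB sites in
  400 bp; the MER11B-like elements have 7 CpGs around one central κB site in
  209 and 166 bp. These loci are synthetic constructions with the documented
  CpG/motif architecture, not genomic sequence.
* **Toy genome.** 1 Mb by default, with 40 peaks embedding the κB consensus
  GGGACTTTCC (PWM replaceable via config). Peaks cycle through low (0–5) and
  high (10–25) flank-CpG density crossed with unmethylated (initial per-CpG
  probability 0.02–0.15) and methylated (0.70–0.95) states. Background CpGs
  are scrubbed so planted flank counts are exact and independently
  recountable. Gene TSSs are placed to span the < 10 kb, 10–100 kb and
  > 100 kb nearest-peak strata.
* **Methylation dynamics.** Level at t12 is
  p0 − g·δ·exp(−|d|/λ), clipped to [0, 1], with δ = 0.6, λ = 300 bp, and the
  genotype multiplier g = 1.0 (WT), 0.95 (TET1-KO), 0.7 (TET3-KO), 0.3
  (TET2-KO), 0.05 (RELA-KO and TET triple KO) — chosen to reproduce the
  qualitative ordering in which demethylation depends mainly on TET2, partly
  on TET3, barely on TET1, and requires p65 binding. The multipliers are
  simulator knobs expressing that ordering, not estimated effect sizes; no
  quantitative genotype effect sizes are available to calibrate against.
  Counts are binomial at 30× coverage per CpG.
* **Occupancy.** Summit signal = 100·exp(−β·M) with β = ln 2 per
  methylated-CpG equivalent, times mean-one lognormal noise (σ = 0.2 on the
  natural-log scale). Multiplicative noise is used because the signal spans
  orders of magnitude across M: it keeps the signal strictly positive and
  preserves the non-increasing ordering of methylation-quintile group means
  on every seeded run, which additive noise of any useful amplitude would
  destroy at high M.
* **Expression.** Three replicates per condition, lognormal around planted
  means with σ = 0.1 in log2 units. Planted memory genes satisfy all three
  classifier criteria with wide margins (second/first ≈ 1.4–3.0); the
  IL32-like control has a 5× elevated recovery baseline but a flat second
  induction; two NF-κB pathway controls respond without memory; ~500
  background genes are flat across conditions.

### What the simulations do and do not show

The generators reproduce the statistical structure the analysis assumes —
binomial count noise, motif-anchored exponential demethylation, exponential
occupancy–methylation coupling, lognormal replicate scatter. They do not
emulate read-level artifacts (mapping bias, incomplete conversion at CpG
sites, fragment-length effects), linkage disequilibrium of methylation
states within reads, peak-calling uncertainty, or a realistic genome
(repeats, CpG islands, strand asymmetries). Passing tests therefore
demonstrate that the estimators and classifiers are correct and well-behaved
under their stated models, not that those models capture every property of
real sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale inputs chosen as the
smallest sizes at which every statistic is stable: 200 clones × 17 CpGs
(≈3,400 calls, binomial 95 % CI of ±1 percentage point at p = 0.906), 40
peaks on a 1 Mb toy chromosome, ~500 background genes. Quantiles use numpy's
default linear interpolation. Lowess uses span 0.3. Degenerate inputs are
handled explicitly: all-equal demethylation values yield an empty top
quartile with a warning; zero-coverage CpGs propagate as no-data sentinels;
all-zero genes are classifiable thanks to the pseudocount.

## Known limitations

Gapless clone comparison rejects indel-bearing clones instead of aligning
them; only top-strand bisulfite chemistry is modelled; the Welch test is an
approximation to count-based differential expression engines; chromosome
names must match exactly between inputs; bedGraph (not bigWig) is the only
track format; hydroxymethylation is not distinguished from methylation.
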