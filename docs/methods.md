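# Methods

## Statistical model of bisulfite m5C calling

Bisulfite treatment deaminates unmethylated cytosine to uracil; m5C resists.
An unmethylated C therefore reads as T except with a small non-conversion
probability ε (incomplete conversion, e.g. residual secondary structure).
At a site with true methylation level m, the probability that a read reports
C is

    P(read C) = m + (1 − m)·ε

i.e. a methylated molecule always reads C and an unmethylated one fails to
convert with probability ε. ε is estimated by pooling all cytosine positions
of an unmethylated spike-in RNA (50 nt, 5 cytosines): ε̂ = Σu / Σn with a
Clopper–Pearson 95 % interval. Calling then tests, per site, the one-sided
exact binomial tail P(X ≥ u | n, ε̂) with Benjamini–Hochberg correction over
all sites with coverage ≥ `min_call_coverage` (default 10). Sites below the
coverage minimum are reported `untested`, not dropped: they remain available
for the unmethylated-C background set. Assumptions: reads are independent,
conversion error is position-independent (no sequence-context error model),
and the spike-in error rate transfers to the genomic RNA.

The caller does not attempt to reproduce any particular published toolkit's
internal statistic; it implements the standard conversion-error binomial
model with every knob exposed.

## Dependence and damage-induction classification

A WT-called site is TRDMT1-dependent when

    fold = ((u_wt + c)/(n_wt + 2c)) / ((u_ko + c)/(n_ko + 2c)) ≥ fold_threshold

with pseudocount c = 0.5 reads (keeps the fold finite when the KO shows no
methylation) and fold_threshold = 2. Dependence is assessed within the
matching damage condition (+damage WT vs +damage KO); damage induction uses
the identical rule on +damage vs −damage counts within one genotype. Sites
called in WT but with zero KO coverage are `unclassifiable`; sites called
only in KO are outside the dependent/independent dichotomy and are kept in a
separate audit label. The fold rule deliberately involves no significance
test of the WT−KO difference: the classification is a threshold on effect
size, as in the study design it follows.

## R-loop peak filtering and overlap

RNaseH destroys genuine DNA:RNA hybrids, so DRIP peaks also present after
RNaseH treatment are artifacts. An untreated peak is removed when the summed
length of its intersections with the (merged) RNaseH peak set is
≥ `removal_overlap_frac` × its own length (default 0.5; 0 selects
any-overlap removal). "Present in" is not otherwise defined operationally,
so the fraction is a declared, configurable choice. A site is *in an R-loop*
when peak.start ≤ pos < peak.end for any surviving peak — point containment,
strand-blind, since DRIP peaks are unstranded.

Enrichment of a site class against the unmethylated-C background (sites with
coverage > 25, methylation ≤ 2ε, never called in any condition) is a
two-sided Fisher exact test on the 2×2 in/out table; the odds ratio uses the
Haldane +0.5 correction only when a cell is zero. Interval machinery is
merge + binary search; the test suite keeps all-pairs and per-base coverage
oracles against it.

## Windowed GC statistics and enrichment grids

Non-overlapping 50 bp windows tile each chromosome from coordinate 0 (the
terminal partial window is dropped; the step is configurable). Per window,
GC skew = (#G − #C)/(#G + #C) and GC fraction = (#G + #C)/window size,
computed on the plus strand and sign-flipped for windows assigned to a
minus-strand transcript, so positive skew always means G-rich on the
transcribed (sense) strand — the R-loop-favouring configuration. Facet
assignment is by largest transcript overlap; windows overlapping no
transcript form the intergenic facet. Windows containing N, or with no G and
no C, have undefined skew and are excluded from grids (counted separately).

The observed set of a facet's grid is its R-loop windows (any overlap with a
surviving peak); the expected set is every non-R-loop window genome-wide,
intergenic included — "the remainder of the genome" read literally — each
expressed on its own sense strand. Cell ratio =
(obs/obs_total)/(exp/exp_total), left NaN where the expected cell is empty
rather than pseudocounted. Default bins: skew 0.1 over [−1, 1], GC 0.05 over
[0, 1] — binning is unavoidable for a ratio surface and these widths resolve
the planted effect sizes without emptying cells at the simulated genome
size.

Context profiles take the ±k (default 10) bases around each site, read
5′→3′ on the site's strand, excluding windows with N or truncated by a
chromosome end. Offset 0 is the methylated C by construction. Top/bottom
comparisons rank called plus-strand sites by methylation fraction with
coverage then coordinate tie-breaks, taking the top and bottom
⌈quantile·N⌉.

## What the synthetic-data generator emulates

The generator reproduces the structure the analysis is designed to detect:

- **Genome**: i.i.d. bases at GC 0.45 (human-like), two 50 kb chromosomes
  (100 kb total keeps every stage seconds-fast while leaving ≈18 000
  transcript cytosines — enough for stable fractions).
- **Transcripts**: 40 × 2 kb, non-overlapping, random fixed strand; placed
  by distributing the free space among the gaps (multinomial), so placement
  is deterministic-feasible.
- **R-loop regions**: 20 × 400 bp inside transcripts (≈10 % of transcript
  bases), resampled to sense-strand GC 0.6, skew +0.4 — the G-rich
  signature of R-loop-prone sequence.
- **m5C sites**: 200 dependent + 200 independent on transcript-strand
  cytosines. A dependent site is forced into an R-loop with probability 0.8
  (the co-localization under test) and otherwise placed uniformly — so
  co-localization 0 is exactly uniform placement, the natural null.
  Dependent levels: damaged WT 0.30, KO 0.02; 70 % of dependent sites are
  damage-induced (undamaged WT 0.02), the rest constitutive (0.30 in both
  WT conditions). Independent sites: 0.20 in every condition. The study
  reports these contrasts only qualitatively (basal vs induced); the
  defaults are declared values chosen to be realistic for damage-induced RNA
  methylation, and all are parameters.
- **Sequence context**: dependent sites get sense-strand flanks (±5 nt)
  resampled with P(G) = 0.6, never overwriting another planted site's C.
- **Counts**: coverage ~ negative binomial, mean 50, dispersion 0.1
  (var = μ + 0.1 μ²; dispersion 0 selects Poisson) — realistic
  overdispersion for RNA-seq-derived coverage; unconverted reads binomial
  under the conversion model above with ε = 0.005; spike-in coverage mean
  2000. The spike-in's real-experiment mass ratio (1:40 000) only motivates
  treating its coverage as a free parameter; counts are emitted per base.
- **DRIP peaks**: untreated = R-loop regions with ±20 bp boundary jitter
  plus 10 artifact peaks placed clear of R-loops; RNaseH-treated = the
  artifact peaks alone.

Not emulated: read-level errors and alignment, sequence-context-dependent
conversion failure, RNA secondary structure (heat denaturation treated as
fully effective), overlapping or spliced transcripts, chromosome-scale
composition heterogeneity. Passing tests therefore demonstrate correctness
of the statistical machinery and recoverability of planted structure — not
robustness to alignment artifacts or context-dependent conversion biases in
real libraries.

## Numerical and degenerate-input choices

- All coordinates 0-based half-open, including count-table positions.
- ε = 0 makes any unconverted read decisive (p = 0); the caller handles it
  without special-casing via the exact tail.
- Pseudocount folds are scale-invariant only at c = 0; c = 0.5 trades exact
  invariance for finiteness at zero KO counts.
- Best-site thresholds are strict inequalities (coverage 25 or methylation
  exactly 10 % do not qualify).
- Ranking ties break by coverage, then (chrom, pos), making every ranked
  subset deterministic.
- Grid cells with empty expected proportion are flagged NaN, never divided.
- Outputs carry no timestamps and floats are written with a fixed format,
  so identical config + seed reproduces every file byte-for-byte.

## Problem sizes

Default simulations are 100 kb genomes with ~18 000 assayed cytosines and
400 planted sites; calibration checks use 5000 null sites, power and
classifier checks 1000–2000 sites per class. These sizes give the binomial
standard errors the assertions rely on (e.g. ±0.01 on a fraction of 2000)
while keeping a full pipeline run near one second.

## Known limitations

- The unmethylated-C background definition (coverage > 25, meth ≤ 2ε, never
  called) is one reasonable operationalization of "unmethylated C sites";
  the factor is configurable.
- The expected set of the enrichment grid mixes facets; an alternative
  (facet-restricted expected) is a one-line change but is not the literal
  "remainder of the genome".
- The RNaseH removal fraction is a declared convention; published overlap
  percentages are sensitive to it.
- The classifier threshold is a pure fold rule; near-threshold sites at low
  coverage are noisy by design, which the parameter-recovery tests quantify
  at coverage 100.
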