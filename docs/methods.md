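# Methods

This note records the models, parameter choices and numerical decisions
behind `dmrkit`, in the spirit of a methods appendix.

## Coordinates and containers

All internal coordinates are 0-based half-open. Cytosine reports (1-based)
and GFF3 (1-based closed) are converted at the file boundary; BED is native.
A methylome is a per-cytosine table keyed by (chromosome, position, strand)
with methylated/unmethylated read counts and a CG/CHG/CHH context label.
Symmetric CG sites are deliberately kept as two strand-specific records,
because the differential test is applied per cytosine; collapsing the two
strands before testing would roughly double per-site coverage and is a
legitimate alternative we do not take (the pipeline's published description
operates on per-cytosine counts).

Context assignment: a forward-strand C is CG if followed by G, CHG if
followed by H,G, CHH if followed by H,H (H ∈ {A,T,C}); a reverse-strand
cytosine is a G on the forward strand, with its context read on the reverse
complement. Cytosines whose one or two context bases run off the chromosome
or hit an N have undefined context and are dropped rather than guessed.

## DMC / DMR calling

Per cytosine, a two-tailed Fisher's exact test on the 2×2 count table. The
two-tailed p is defined by point-probability summation: all tables with the
observed margins whose hypergeometric point probability is ≤ the observed
one (relative slack 1e-12 for floating-point ties). The pmf is computed in
log space over the whole support via `gammaln`; for count tables repeated
across sites (common at 15× depth) p-values are computed once per unique
table. The implementation is checked against two independent routes: exact
integer-arithmetic enumeration (tests and acceptance script) and
`scipy.stats.fisher_exact` (property test).

Cytosines are tested only when covered by ≥ `min_cov` (default 4) reads in
both samples. The published procedure does not state a coverage floor; a
floor is needed because the exact test has essentially no power below ~4
reads and untestable sites would otherwise dilute the window statistics.
The value is configurable.

Windowing: per chromosome, context and direction, 200-bp windows advance in
50-bp steps anchored at the chromosome origin (the origin choice is
arbitrary and only shifts window phase by < 1 step). A window holding ≥ 3
DMCs ("more than 2") qualifies; overlapping qualifying windows are unioned
before trimming each union to [first DMC, last DMC + 1). Anchors separated
by a gap strictly less than 100 bp merge, left to right (a single pass is
already stable; merging is idempotent). Final filters: length ≥ 100 bp,
≥ 5 DMCs, and |Δ| ≥ 0.30/0.15/0.10 for CG/CHG/CHH, where Δ is the
difference in weighted methylation — Σ n_meth / Σ (n_meth + n_unmeth) —
pooled over *all* covered context cytosines in the region. Pooling over all
cytosines rather than DMCs only is the robust reading of an "absolute
methylation difference" over a region; a DMC-only mode is available
(`delta_mode="dmc"`).

Hypo- and hypermethylated cytosines are windowed separately, so a DMR
always has a direction; swapping the input samples flips every direction
but changes no p-value, boundary or |Δ| (tested).

## Metagene / meta-TE profiles

Feature bodies are rescaled to 40 fractional bins; 2-kb flanks use fixed
100-bp bins (bin counts are presentation choices, configurable). Minus-
strand features are orientation-flipped so upstream is always 5′. Features
whose flanks run off the chromosome contribute truncated flanks. Per-bin
levels pool counts across features (Σ meth / Σ total); mean-of-feature-
means is available (`pooling="features"`). Bins with zero covered cytosines
are reported as NaN with n = 0, never zero-filled.

Size stratification uses fixed breakpoints at 1/2/3/4 kb producing five
groups; group 1 is the "< 1 kb" class, so a feature exactly at a breakpoint
falls in the upper group. Whether the original five groups were fixed or
quantile bins is not documented; a quantile constructor
(`SizeGroupSpec.from_quantiles`) is provided.

## DMR annotation

Categories are exclusive with TE > gene precedence (TEs are the primary
RdDM targets and TEs inside genes should count as TE); precedence is
configurable. Overlap means ≥ 1 shared bp (`min_overlap` configurable).
Distances of intergenic DMRs use the DMR midpoint to the nearest gene start
codon (feature start for +, end − 1 for −), signed negative when the DMR
lies upstream in the gene's own orientation; the summary reports the
fraction within 1.5 kb upstream ("promoter" fraction, interval [−1500, 0)).

## Intron retention

The Audic–Claverie point probability is evaluated in log space; it equals a
negative-binomial pmf with r = x + 1 and p = N₁/(N₁+N₂), which provides the
independent cross-check in the tests. The two-sided p is 2·min(lower tail,
upper tail) capped at 1, with the infinite upper tail summed in blocks
until terms fall below 1e-15 of the running sum. Note the test conditions
on x, so it is *not* exactly invariant under swapping (x, N₁) ↔ (y, N₂);
that symmetry holds only for the point probability at equal depths. At
x = y and N₁ = N₂ both tails are exactly ½ and the p-value caps at 1 (up to
~1e-14 float summation error).

"Read coverage" is interpreted as the fraction of intron bases covered by
≥ 1 read in the putatively retaining (mutant) sample; the event filter is
strict (> 0.95, so exactly 95% does not qualify). BH FDR is applied across
all tested introns, not per gene, and events must be mutant-up. The test
itself is two-sided as the conventional reading; one-sidedness would only
relax q-values by ≤ 2× and is absorbed by the direction filter.

## Segregation tests

Pearson chi-square without continuity correction (the convention for
segregation counts); a Yates-corrected variant is exposed for the two-class
case. Zero expected classes and zero totals are errors.

## Synthetic data

The methylome simulator emulates the count-level structure of a single-
plant WGBS pair: random genome at GC fraction 0.36 (Arabidopsis-like),
per-cytosine coverage ~ Poisson(15) per sample (the 15–18× range of typical
studies), and bisulfite non-conversion at rate 0.004 (within the usual
0.3–0.5% band) modelled as a floor on the observed methylation probability,
m' = m + (1 − m)·err — non-conversion can only inflate apparent
methylation. Context baselines default to CG 0.20 / CHG 0.05 / CHH 0.02
for background and CG 0.80 / CHG 0.50 / CHH 0.10 inside TE intervals, a
qualitative emulation of plant methylome profiles, not fitted values.
Planted DMRs shift sample B's true methylation by ±Δ inside their interval
for their context; feasibility (baseline ± Δ ∈ [0, 1]) is validated at
configuration time. One seeded generator drives all draws, so outputs are
byte-identical for a given config and seed.

What the simulator does **not** model: read-level errors and mapping bias,
spatial autocorrelation of methylation outside planted intervals,
partially methylated domains, coverage dips at repeats, or biological
replicates. Passing the recovery benchmarks therefore demonstrates the
correctness and calibration of the *procedure* on idealised counts, not
expected performance on real libraries.

The intron simulator draws x ~ Poisson(μ), y ~ Poisson(μ·f·N₂/N₁) with
f the planted fold change (1 for nulls); default library sizes 48.3M and
49.6M reads emulate a realistic two-library comparison. Null introns get
covered fractions ~ Uniform(0.2, 1), planted ones their configured value
(default 1.0).

## Benchmark problem sizes

The recovery benchmarks run on a 1-Mb genome with 100 planted 400-bp CG
DMRs (Δ = 0.4, hyper) and on 5000 introns with 50 planted five-fold
retention events — large enough that recall and null counts are stable
(recall ≈ 0.91–0.95 across seeds; null runs typically yield 0 DMRs and 0
events), while a full benchmark completes in seconds.

A note on the flat-profile check: per-bin z-scores of a uniform methylome
profile are asymptotically standard normal, so "every bin within 2 SE"
fails with probability → 1 as the bin count grows, for any correct
implementation. The flatness test therefore applies the two-sigma criterion
with a Bonferroni family-wise bound over the number of bins and additionally
requires ≥ 90% of bins within 2 SE (nominal 95%).

## Known limitations

- No biological replicates: the Fisher-per-cytosine design compares exactly
  two methylomes, as in single-plant studies; it cannot separate
  biological variability from treatment effects.
- The DMR caller is threshold-based, not smoothing- or HMM-based; very
  sparse contexts (CHH at low depth) lose power at the 4-read floor.
- Intron counting from alignments is out of scope; the primary input is a
  precomputed per-intron count table.
- The pseudo-genome builder performs single-base substitutions only (no
  indels).
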