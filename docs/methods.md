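# Methods

This note documents the models behind `meioscan`, the defaults and why they
were chosen, the numerical conventions, and what the simulator-based test
suite does and does not establish about real data.

## Data model

Haploid isolates are genotyped at ordered markers; each call is parent-1
(P1), parent-2 (P2) or missing.  Physical marker order (1-based bp,
strictly increasing within a chromosome, chromosomes never interleaved) is
authoritative; the genetic coordinate (cM, non-decreasing) is optional
metadata used only by the QTL scan.  Duplicate positions on a chromosome are
rejected because the phase-run logic requires a strict order.  BED output
converts to 0-based half-open coordinates; everything else stays 1-based
inclusive.

The VCF importer phases progeny by parentage: only biallelic sites where the
two parent samples are fixed for different alleles are informative; progeny
calls matching parent 1 or parent 2 become P1/P2, anything else (het,
no-call) becomes missing.  No imputation or de novo phasing is performed.

## Crossover calling

A crossover is a change of parental phase supported by at least `min_run`
(default 5) consecutive informative markers of each parent on both sides of
the breakpoint.  The rule is applied as *mask-then-count*: maximal
same-parent runs shorter than `min_run` are treated as genotyping noise and
set to missing — all sub-threshold runs of a pass simultaneously, iterated
to a fixed point, so equal-parent runs flanking a masked island merge into
one longer run.  One event is then recorded at each boundary between
consecutive surviving runs of different parent.  Consequences of this
definition, chosen deliberately:

- isolated miscalls inside a long run never break it;
- double crossovers separated by fewer than `min_run` markers are
  undetectable by design (they are indistinguishable from noise);
- every recorded breakpoint has ≥ `min_run` markers of each parent on its
  two sides after noise removal.

Missing calls are transparent — runs continue across them — because missing
data should neither manufacture nor destroy switches.  The alternative
(runs broken at missing calls, each informative block processed separately)
is exposed as `break_on_missing=True`.

The breakpoint is localized to the interval between the last marker of the
upstream run and the first marker of the downstream run; its floor-midpoint
`mid_bp` is the point used for window assignment.  The midpoint is the
unbiased choice absent any information inside the interval.  A chromosome
offering fewer than `2*min_run` informative markers for an isolate cannot
support an event and is logged as underpowered.

The test suite checks the caller against an independent naive list-based
implementation of the same definition on thousands of random short
sequences, plus monotonicity in `min_run` and a parity invariant
(event count ≡ start-phase ≠ end-phase, mod 2).

## Hotspot detection

The genome is tiled with non-overlapping windows (default 10 kb, last
window truncated); each event is assigned to exactly one window by
`mid_bp`.  The null is a genome-wide Poisson with λ estimated over *all*
windows, zero counts included.  The hotspot threshold is the smallest k ≥ 1
with exact upper tail P(X ≥ k) < α (default 10⁻⁴), computed by summation —
no normal approximation.  Adjacent significant windows are reported as
separate hotspots (window-granular, matching how such scans are usually
reported); `merge=True` offers interval merging.  λ is reported at full
precision; note that rounding λ before thresholding can shift the threshold
by one count when the tail probability is near α (e.g. λ = 0.23 gives k = 4
with tail 9.7·10⁻⁵, while λ = 0.2374 gives k = 5 because the k = 4 tail is
1.09·10⁻⁴).

Fold enrichment is count/λ per window; the genome share is hotspot bp over
genome bp; HCO counts an isolate's events whose midpoints fall in any
hotspot window.  SNP density in hotspot vs background windows is compared
with a one-way ANOVA on per-window marker counts.

## Population statistics

TCO (per-isolate total), HCO, and COchr (per chromosome) come from the
called events.  Correlations are Pearson with two-sided t-transform
p-values.  The mating-type comparison uses Welch's t-test (no equal-variance
assumption; the choice matters with unequal group sizes); segregation of the
two mating-type alleles is a 1-df χ² against 1:1.  No multiple-testing
correction is applied across this handful of summary tests.

## QTL mapping

Traits are per-isolate crossover counts (TCO, HCO, each COchr), treated as
Gaussian in the regression, as interval mapping conventionally does; counts
at these means are far from degenerate and the permutation threshold is in
any case distribution-free.  At each position of a 1 cM grid the expected
parent-2 genotype probability is computed from the nearest informative
flanking markers via the Haldane map function (no interference assumed in
the probability model; Markov inheritance makes nearest-flank conditioning
exact, which the tests verify against exhaustive path enumeration).  With
no informative marker on a chromosome the probability falls back to 0.5.

LOD = (n/2)·log₁₀(RSS₀/RSS₁).  The genome-wide threshold is the (1−α)
quantile (α = 0.05) of the maximum LOD over phenotype permutations
(default 1000); permuting the phenotype only preserves marker LD exactly.
Peaks are local maxima above the threshold separated by LOD-1 valleys; each
peak gets

- a LOD-1 support interval (grid positions with LOD ≥ peak−1), converted to
  bp by linear interpolation between flanking markers;
- an additive effect = (parent-2 mean − parent-1 mean)/2, computed as half
  the regression slope on the dosage at the peak (sign convention:
  parent 2 minus parent 1);
- R² = 100·(1 − RSS₁/RSS₀) at the peak.

Per-chromosome traits are labelled *cis-prone* when the peak lies on the
trait's own chromosome and *trans* otherwise; TCO/HCO peaks are labelled
n/a.  Hotspot association reports the hotspot overlapping the physical CI,
or the nearest one within 50 kb ("near to …"), or "/".

Full composite interval mapping à la WinQTLCart is not re-implemented
bit-for-bit.  The default is plain interval mapping; `cim=True` enables a
CIM-lite surrogate: up to 5 background marker covariates chosen by greedy
forward selection, dropped within a 10 cM window of the test position.  For
a single planted QTL both modes agree (tested); the surrogate exists to
absorb polygenic background on multi-QTL data.

## The simulator

The simulator generates the statistical structure the analysis assumes, so
every stage can be tested against known truth without external data.  Per
isolate and chromosome the crossover count is Poisson(λ) (ν = 1) or a
stationary gamma-renewal process with shape ν on the genetic axis
(variance/mean ≈ 1/ν < 1, i.e. crossover interference; the first arrival is
drawn from the equilibrium delay — U·Gamma(ν+1, 1/ν) — so the expected
count stays λ).  Positions map through a piecewise-constant intensity:
uniform by default, or concentrated into declared hotspot windows.  The
starting phase is uniform and alternates at each crossover; marker calls
read the phase off at marker positions; genotyping noise (independent
symmetric flips, then dropouts) is applied to the call grid only, never to
the returned truth.  Isolates are independent gametes — no tetrad
structure, matching single-spore sampling — and zero-crossover
(achiasmatic) chromosomes are allowed.

Crossover-modifier (controller) loci: each isolate draws the controller
allele Bernoulli(½) before crossover placement; carriers of the parent-2
allele have the target chromosome's λ multiplied by (1+β).  The
controller's own chromosome is then phase-flipped wholesale if needed so
the phase at the controller position reports the drawn allele — this
preserves the crossover point process while keeping the controller fully
linked to its flanking markers, and gives carriers exactly (1+β)× the
target rate (tested).  One controller per chromosome is supported.  The
mating-type locus simply records the phase at its position as A1/A2.

The simulated genetic map is pos_cM = 100·λ·pos_bp/length: a chromosome's
map length in cM is 100× the expected crossovers per gamete, consistent
with gamete-level mapping.

### Default demonstration conditions

- Genome: nine pseudo-chromosomes of 6.00, 5.40, 5.00, 4.60, 4.20, 3.80,
  3.30, 2.70, 2.23 Mb (37.23 Mb total).
- 110 isolates; 500 markers per chromosome, evenly spaced (a test-scale
  stand-in for a dense expression-marker map).
- λ per chromosome 1.80, 1.45, 1.25, 1.05, 0.85, 0.65, 0.45, 0.30, 0.25 —
  decreasing with length, spanning the 0.25–1.80 crossovers/chromosome
  range typical of such panels and summing to ≈ 8 per meiosis.
- 64 hotspot windows of 10 kb at 60× intensity, spread over all
  chromosomes except chr7 (kept hotspot-free as a recombination-suppressed
  chromosome).
- One cis modifier (chr1, β = 0.8 targeting chr1) and one trans modifier
  (chr2, β = 0.8 targeting chr3); with these rates each explains on the
  order of 10–15% of its target trait's variance.  A mating-type locus on
  chr2 with no effect on rates (null).
- ν = 1 (no interference) keeps the null Poisson-simple; interference is
  exercised separately in tests.

### What the simulator does not emulate

Gene conversion / non-crossovers, sequence-level variation (marker grid
only), spore-viability or selection bias, tetrad correlations, clustered or
allele-biased genotyping error, and real marker spacing irregularity.
Passing tests therefore demonstrate correctness of the algorithms under the
stated generative model, not robustness to every artifact of RNA-seq-derived
genotyping.

## Numerical choices

- Poisson tails via exact `scipy.stats.poisson.sf`; threshold search is a
  linear scan from k = 1.
- LOD via the correlation identity RSS₁ = RSS₀(1−r²), with r² capped at
  1−10⁻¹² to keep LOD finite on degenerate fits; zero-variance dosage rows
  get LOD 0; constant phenotypes yield an all-zero profile with a warning.
- The scan grid runs from the first to the last marker cM per chromosome at
  the configured step, with the chromosome end appended if the step
  overshoots; CI endpoints are grid positions (no sub-grid interpolation).
- Peak tie-breaks: candidates are taken in decreasing LOD order; a
  candidate is accepted only if a LOD-1 valley separates it from every
  accepted peak on its chromosome, so a flat plateau yields one peak whose
  CI spans the plateau.
- cM→bp conversion by linear interpolation between flanking markers
  (clamped at chromosome ends).
- Simulated crossover positions are rounded to integer bp, clipped to
  [1, length−1] and de-duplicated (collisions are vanishingly rare at Mb
  scale).
- Permutation thresholds use `numpy.quantile` (linear interpolation) over
  the permuted maximum-LOD sample; all randomness flows from explicit
  `numpy.random.default_rng` seeds, and the pipeline fans one config seed
  out to per-trait permutation seeds deterministically.

## Validation problem sizes

The stochastic test-suite checks run at these sizes, chosen to make the
checks sharp at desk scale: caller-vs-oracle on 1000 random ≤20-marker
sequences; an error-free round trip at 9 chromosomes × 110 isolates × 500
markers; noise robustness over 100 seeded populations at 1% call error
(excess events per isolate-chromosome < 0.01); planted-hotspot recovery in
≥95/100 seeded runs; QTL null calibration over 200 replicates with
200-permutation thresholds; and recovery of a planted modifier explaining
≈25% of variance (λ_target = 2, β = 1, n = 110) with the true location
inside the LOD-1 CI in ≥80/100 replicates.

## Known limitations

- Double crossovers within `min_run` markers are invisible; at sparse
  marker density the called landscape is a lower bound and hotspot
  midpoints smear by up to half the marker spacing.
- The hotspot null ignores local marker-density variation; windows with few
  markers are under-powered rather than corrected.
- Plain interval mapping fits one QTL at a time; closely linked QTLs of the
  same trait are resolved only when a LOD-1 valley separates them.
- LOD-1 support intervals are approximate confidence intervals; their
  coverage is near but not exactly 95% and degrades for weak effects.
- The additive-effect sign depends on the parent-labelling convention and
  is not comparable across differently-phased datasets.
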