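# Methods

This note documents the model behind `pairsv`, the defaults and why they
are what they are, what the synthetic generator does and does not emulate,
and the numerical and design choices made where the design was open.

## Signal model

### Insert-size model and anomaly categories

A paired-end fragment aligned to the reference yields two reads whose
*innermost* coordinates bound the unsequenced middle of the fragment.  The
insert observation used throughout is this innermost gap,
`l = right − left` (for 2×100 bp reads at fragment size 300 the gap is
~100 bp).  Cut-offs `LC`/`UC` are empirical percentiles at `α/2` and
`1 − α/2` computed by linear interpolation between order statistics
(`numpy.percentile` default) — deterministic and directly testable against
a sort-based oracle.  `α` defaults to 0.01, the working point at which the
normal-theory cut-off sits 2.58 σ from the mean; the suite verifies this
convergence.  Models are fitted per read group when tags are present
(libraries in one run can have very different spreads), with the first
10⁶ observations per library (configurable) for bounded memory; below
1000 observations a warning flag is set.

Classification of a mapped pair depends only on chromosome equality,
strand configuration, mapping order and `l` against `[LC, UC]`, and is
total: every configuration lands in exactly one of seven categories.
Ties in mapping order (identical leftmost coordinates) count as right
order.  Mate-pair (jumping) libraries are handled by flipping both strands
before classification — the documented convention switch — after which the
paired-end rules apply unchanged.  Pairs with `l < LC` indicate insertions
shorter than the library spread can resolve; they are tallied and dropped,
insertion calling being out of scope.  Pairs with mapping quality below a
floor (default 1, i.e. only mapq 0 is dropped) are excluded before
classification because multi-mappers reported at mapq 0 seed spurious
categories; the floor is configuration, not dogma.

### Clustering

Two same-category pairs support the same junction pair when both anchors
(innermost coordinates; forward end / reverse start) agree within
`D = UC − LC`, which equals `2 z_{1−α/2} σ` for a normal library.  The
cluster set is the transitive closure of this relation.  It is computed by
union-find inside a sweep sorted on the first anchor: only pairs within
`D` on the sorted axis can be related, so candidate edges form a sliding
window and the result is exactly the closure, independent of input order.
(A single-pass sweep keeping only running extrema was considered and
rejected: it cannot merge two open groups bridged by a later pair, so it
does not reproduce the closure; the suite checks exact equivalence against
a quadratic oracle.)  Each pair belongs to one component; components with
`S ≥ 2` are emitted.

### Breakpoint intervals

A side supported by forward reads has all innermost anchors at or left of
the junction, and no anchor can lag it by more than `UC` (a larger gap
would not have been sequenced as one concordant-in-donor fragment), so the
junction lies in `[max x⁺, min x⁺ + UC)`; a reverse-supported side mirrors
this as `(max x⁻ − UC, min x⁻]`.  Interval width is weakly decreasing in
`S`.  Intervals are clipped at chromosome bounds.  Clusters whose two
intervals overlap each other are flagged unreliable rather than deleted —
their junctions are not separable — and are routed to the undefined bin.

### Confidence tiers

Quality per read is `min(mapping quality, mean base quality)`; a cluster is
tier 1 when some member pair has both reads ≥ 30 (99.9 % base-call
accuracy), tier 2 at ≥ 20 (99 %), else lower.  Support tiers are
`high [10–50)`, `medium [5–10)`, `low` below 5, and `special` when the
one-sided Poisson tail `P(X ≥ S)` at rate = mean coverage falls below
10⁻⁴ — such clusters usually sit in collapsed repeats.  Length tiers (span
between predicted interval midpoints, intra-chromosomal categories only):
`special ≥ 1 Mb`, `high [1 kb, 1 Mb)`, `medium [500 bp, 1 kb)`, and `low`
below 500 bp (added so the scale is total); inter-chromosomal clusters have
no defined span (`n/a`).

## Read depth

Windows are fixed-size (default 100 bp — small enough to resolve kilobase
events, large enough to keep Poisson noise workable at 30–45×).  Each
mapped read, including one-end-anchored ones, increments the single window
holding the largest share of its bases; 50/50 ties go left for
determinism.  Windows with > 50 % N bases are masked.  GC correction is
the median-ratio adjustment `r̃ᵢ = rᵢ · m / m_GC(i)` with 1 % GC bins;
bins with fewer than 50 windows (configurable) or zero median are masked —
their medians are not stable.  The transform `y = √r̃ − √median(r̃)`
approximately stabilises Poisson variance and centres copy-neutral windows
at 0; at 30× a hemizygous loss (15×) gives `y ≈ √15 − √30 ≈ −1.6` and a
single-copy gain (45×) `y ≈ +1.2`, comfortably past the ±0.4 calling
thresholds, which are exposed as configuration.

Segmentation treats `y` as a sparse piecewise-constant vector and runs
backward elimination over breakpoints: starting from a breakpoint between
every adjacent window, the lowest-scoring breakpoint — two-sample statistic
`|mean_L − mean_R| / (σ √(1/n_L + 1/n_R))` against a global robust noise
scale `σ = MAD(Δy)/√2` — is removed until all survivors score at least
`T`.  `T` (default 5.0) is the one sensitivity knob: high enough that a
10⁴-window null signal stays a single segment, low enough that a 50-window
step at signal-to-noise 3 scores ≈ 21 and is kept; the synthetic-step suite
(changepoints within ±2 windows, F1 ≥ 0.9 over 20 seeds) pins this choice.
An exactly constant signal short-circuits to one segment; a noise-free
signal keeps every level change.  Segments tile the unmasked windows of
each chromosome; edge windows (half-covered by construction) often form
short terminal LOSS artifacts — they are genuine signal features of finite
chromosomes, not bugs, and are too short to support calls.

## Interpretation rules

Unbalanced classes require depth support, balanced classes its absence.
A region supports a state when at least 50 % of its segment-covered length
(and at least 3 windows of span) carries that state; shorter regions are
depth-undeterminable and rely on read pairs alone (a distance cluster over
such a region can only be a putative deletion).  "Equal" breakpoints mean
overlapping prediction intervals (tolerance 0 by default — the intervals
already encode the uncertainty).

Combinations are matched before single-cluster rules, greedily by
descending total support: a distance cluster participating in a copy- or
cut-paste combination must not be consumed by the deletion rule first.
Triangles (three clusters pairwise sharing one locus each) yield
translocations; pairs sharing exactly one locus plus a GAIN yield
insertion-type gains, recording both the copied region (the two unshared
loci) and the insertion point (the shared locus); forward/reverse ori
clusters sharing both loci with neutral depth yield inversions.

One genuine ambiguity: for an intra-chromosomal cut-paste, moving segment
`[s,e]` rightwards past `[e,p]` produces the *identical* donor molecule as
moving `[e,p]` leftwards past `[s,e]`, and both readings produce the same
two distance + one order clusters.  The reported source region is, by
convention, the narrower distance-cluster span — translocated segments are
typically small relative to their displacement.

Somatic subtraction removes a tumour cluster when *one* anomalous normal
pair of the same category lies within `D` of any member on both anchors.
This is deliberately stricter than requiring a normal cluster (`S ≥ 2`):
a single read pair is already evidence that the junction exists in the
germline, and the asymmetry suppresses false somatic calls at the price of
sensitivity to subclonal events shared at trace level.

The repeat cascade applies only to calls that lack depth or combination
support.  A call is caught when any predicted breakpoint interval — not a
midpoint — intersects a track, the conservative reading since the junction
is only localised to the interval.  The cascade order SD → SSR → TE is
exclusive; TE filtering uses elements above 90 % family identity (young
elements still able to confound unique alignment), with the value column
read as a plain identity fraction by default or as RepeatMasker
milli-divergence (`identity = 1 − div/1000`) via a switch.

## Synthetic data

The generator emulates: a uniform-coverage paired-end library (fragment
length normal, default 300 ± 30 bp, truncated at twice the 100 bp read
length; default 30×), exact reference-coordinate alignments obtained by
mapping reads back through the donor's block structure, junction-spanning
reads emitted unmapped (what a strict unique mapper does), uniform base
qualities (default phred 40, with an optional low-quality fraction for
tier logic), and reference GC controlled per 1 kb block (exact count per
block, random arrangement).  All eleven rearrangement classes are
constructed by block surgery, so junctions, expected anomaly categories
and expected depth states are known exactly.

It deliberately does **not** emulate sequencing errors, PCR duplicates,
mappability structure, repeat-induced multi-mapping, mate-pair
chemistry (handled as a classifier convention, not simulated), or diploid
heterozygosity (donors are effectively haploid; heterozygous depth ratios
are exercised separately by mixture fixtures in the suite).  Passing tests
therefore demonstrate the correctness of the algorithmic chain under clean
alignments — classification, closure clustering, interval prediction,
normalisation, segmentation, rule interpretation, subtraction, filtering —
not robustness to alignment artefacts, which on real data is exactly what
the quality tiers and the repeat cascade exist to absorb.

At `α = 0.01`, roughly 0.5 % of an SV-free library is distance-labelled by
construction; two such tail pairs occasionally co-locate within `D`, so a
handful of S = 2 putative/undefined calls per tens of megabases of
simulated genome is expected background, and the somatic and end-to-end
suites assert on defined calls and planted loci accordingly.

## Problem sizes

The suite and the acceptance script run entirely on simulated data sized
for a single core: 50–650 kb genomes at 30×, 100-replicate breakpoint
capture, 20-seed segmentation studies, 100-instance clustering-oracle
comparisons.  These sizes were chosen so every statistical check has
comfortable power while the whole suite completes in well under a minute
of compute per criterion; nothing in the method depends on genome scale
except linear run time.

## Known limitations

* Diploidy and subclonal fractions are not modelled; overlapping variants
  on homologous chromosomes can interleave clusters.
* Combination search is pairwise/triple; deeper co-localisation graphs
  (e.g. chains of nested events) fall back to their component calls.
* Depth support uses segment majority over the *span* of a call, which for
  very large events mixes the event with its flanks less than 50 % — the
  fraction threshold is configurable.
* Insertion detection from small-insert pairs is out of scope by design.
* The backward-elimination segmenter assumes roughly homoscedastic noise
  after the square-root transform; strong wave artefacts (e.g. unremoved
  library bias) would need an explicit covariate model.
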