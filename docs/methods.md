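# Methods

`replidyn` analyzes single-molecule replication dynamics from sequential
analog pulse labeling. Cells incorporate EdU for a short pulse (default 7
min) and BrdU for a longer one (default 15 min); on each sequenced molecule
a replication fork leaves an ordered EdU→BrdU segment pair whose orientation
encodes the fork's direction of travel, whose BrdU length over the pulse
duration measures fork speed, and whose arrangement across diverging or
converging fork pairs marks initiation and termination sites. The package
implements the downstream analytics on such fork calls, driven either by
real fork-call BEDs or by a built-in simulator with known ground truth.

## The simulator

The generator is deliberately minimal — the simplest process that produces
every feature the downstream analyses consume.

**Origins.** A homogeneous Poisson process per replication-timing domain,
with intensity `origin_rate_per_bp` (default 1/50 kb, matching typical
inter-origin spacings in fly cells) scaled per timing group
(defaults 1.33/1.11/0.89/0.67 for groups 0–3, i.e. the earliest domains
carry ~2× the intensity of the latest — the ratio reported for early vs
late origin densities). All origins fire at t = 0. Constant-time firing is a
simplification: it makes segment kinematics exactly predictable
(EdU length = v·t_EdU, BrdU length = v·t_BrdU for an unclipped fork), which
is what lets tests assert kinematics exactly. Real firing is
asynchronous; no mechanistic claim is made.

**Forks.** Each origin emits a leftward and a rightward fork. Per-fork speed
is the chromatin-state speed at the origin times lognormal noise (σ = 0.05).
Default speeds put euchromatic states (1–5) at 970 bp/min — the bulk rate
implied by an N50-based estimate over a 15-min pulse — heterochromatic
states (0, 6–8) 1.25× faster, and state 9 in between, reproducing the
observed het > eu track-length ordering. Converging fronts stop where they
meet (the speed-weighted midpoint of the gap; the plain midpoint for equal
speeds). A termination is recorded only when the meeting falls inside the
BrdU phase — an earlier meeting leaves no BrdU continuity and real callers
would not report it. Analog segments shorter than `min_analog_bp` (200 bp)
are below any realistic detection floor and the fork is not emitted.

**Reads.** One molecule per emitted fork: length lognormal (median 50 kb,
σ = 0.6, floor 15 kb — the read-length floor typical of analog detection),
placed to cover the analog segments with at least 1 bp of flank on each
side. Origins are restricted to a margin (max analog span × 1.2) from
chromosome ends so clean forks never abut a molecule or chromosome end;
consequently every BrdU-at-read-end record is an injected defect, which is
what makes filter accounting exact.

**Defects.** Injected mutually exclusively per fork: negative stall codes
−1/−2/−3/−4 at rates 0.07/0.03/0.05/0.03, or a BrdU-at-read-end truncation
at rate 0.35, else clean. The totals give a retained fraction near 0.47,
the same order as the published unfiltered→filtered accounting. Exclusivity
is what lets the QC report's per-reason counts be compared to the injected
counts exactly.

**Direction bias.** Inside a configured bias region exactly one fork of
each pair is emitted, rightward with probability p, planting an expected
window RFD of 2p−1; elsewhere both forks are emitted and RFD is balanced by
construction. Every record stays linked to a ground-truth origin.

**Annotations.** Chromatin states 0–9 tile the genome in exponential blocks
(mean 50 kb; weights give ~45% euchromatin, ~35% heterochromatin, ~20%
state 9). Timing domains (mean 250 kb) carry groups 0–3 and are chopped
into ~100-bp scored segments (group base scores 3.0/2.0/1.2/0.5 plus
Gaussian noise, floored above zero so log-scale analyses are defined).
Genes are non-overlapping with exponential gaps and lognormal lengths; the
zero-RPKM fraction (default 0.3) is constructed exactly. ORC-like peaks are
offset from true origins by a signed exponential with median 6,309 bp (the
reported origin-to-nearest-ORC2 median, used here as a planted parameter).
A small blacklist and event calls (origin calls where both diverging forks
were emitted; termination calls at recorded meetings) complete the fixture
set.

**What the simulator does not emulate.** Signal-level noise, base-resolution
analog probabilities, sequencing error, asynchronous firing, copy-number
structure, and mappability gaps. Passing recovery tests therefore shows the
*analytics* are correct and unbiased under the stated generative model, not
that they are robust to every artifact of real nanopore data.

## Filtering and track metrics

Calls with negative stall codes are rejected (−1 termination, −2
segmentation error, −3 read end, −4 indel proximity), as are calls whose
BrdU segment abuts a read end (length censored) — operationalized as exact
abutment, with a configurable slack defaulting to 0 bp. Origin-linked calls
whose only flag is code −1 can be retained (initiation rule): with
sequential labeling, BrdU following EdU still marks reliable progression.
The filter is a pure partition: every record is retained or rejected with
exactly one reason (stall codes take precedence, then BrdU-at-end, then
zero EdU).

Ratios (BrdU/EdU length) above 100 are flagged as outliers and excluded
from ratio summaries only; length summaries are computed on the full
retained set. On unclipped constant-speed tracks the ratio equals the pulse
ratio 15/7 ≈ 2.14; collision and end clipping shortens BrdU preferentially
and pulls the observed median below that — the same direction as the
published median of 1.50 against a 15/7 schedule. N50 is the largest L such
that segments ≥ L hold at least half the total length (so N50 ≥ median);
the fork progression rate is N50 / pulse minutes, reported to 0.1 bp/min.
Percentile trimming (1st–99th, linear interpolation between order
statistics) is applied to distribution exports only, never to summary
statistics.

## Windows, RFD and coverage

Fixed non-overlapping windows (default 100 kb; the last window of a
chromosome may be short). Each fork is counted once, in the window holding
its call start (`assign="overlap"` counts per overlapped window instead).
RFD = (R−L)/(R+L) per window; windows with no forks export NA, never 0,
because 0 asserts balance. RFD uses the unfiltered call set by default,
with a flag for the filtered set. Chromosome coverage is the union length
of fork intervals over the chromosome length. Strong-bias windows are
called at |RFD| ≥ 0.8 with ≥ 10 forks; both thresholds are configurable
since no published cutoff exists.

## Events

Origin/termination calls are standardized to 200-bp events around the call
midpoint (floor for odd spans; clipped at 0 near chromosome starts and
flagged). Inter-event distances are consecutive midpoint differences per
chromosome in kb. Replicate overlap counts A-side events hitting any
(optionally expanded) B event; a symmetric Jaccard export exists because a
one-sided count is a modeling choice. The expected mappable-origin count is
floor(mappable bp / mean spacing). The repeated-sampling simulation draws
n_draws site indices uniformly with replacement from n_sites and counts
repeats as draws minus distinct sites — the definition consistent with the
closed form n − m(1−(1−1/m)^n) (≈278.1 at m = 3,593, n = 1,513; the
alternative "sites hit twice or more" definition gives ≈242 and was
rejected). Origin clusters: fraction of origins inside any 40-kb span
holding ≥ 3 origins. Nearest-peak distances use event and peak midpoints;
the null re-places the per-chromosome event counts uniformly (no blacklist
exclusion in this analysis; a flag exists), distances are exported as
log10(d+1), and observed vs pooled-null means are compared with a Welch
t-test.

## Chromatin and timing integration

States 1–5 are euchromatin, 0 and 6–8 heterochromatin, 9 silent — a strict
partition. State assignment uses strict containment: adjacent same-state
intervals are merged first (otherwise a track inside one biological block
split across records would be wrongly excluded), then a track is assigned
iff its BrdU interval lies inside a single block; boundary-spanning tracks
are excluded. Length quintiles use stable ties on (length, chrom, start);
within each quintile overlapping tracks are merged before computing
per-state bp proportions; "abundance normalization" divides a proportion by
the state's genomic fraction, so 1.0 means no enrichment.

Timing windows (30 kb) take the dominant group by cumulative segment
overlap (tie → lowest group, flagged); tracks map to the window of greatest
overlap (tie → leftmost, flagged). The length–timing correlation is Pearson
on log10 scales with nonpositive values excluded and counted. Timing
quartiles come from segment-record score quantiles (a bp-weighted
alternative is flagged) with adjacent same-quartile merging; event density
per category is count / category bp × 100 kb, assigning events by center
overlap and tallying discarded centers, so density × bp / 100 kb sums back
to the assigned event count.

A note on the simulator's called origins: an origin call requires both
diverging forks to survive the minimum-analog rule, and collisions clip
forks preferentially where origins are dense. The *called* set therefore
under-represents high-intensity regions, compressing density ratios; the
density-recovery tests use ground-truth origins through the same event
pipeline for exactly this reason.

## Transcription

Per track, mean RPKM over overlapping genes with RPKM > 0 (≥ 1 bp overlap;
zero-RPKM genes are excluded before overlap). Orientation: a rightward fork
over a minus-strand gene, or leftward over plus-strand, is head-on; the
inverse co-directional; both strands overlapped → mixed (kept in the
all-tracks correlation, excluded from orientation strata); no expressed
gene → none. The four classes partition tracks, and flipping every gene
strand swaps head-on and co-directional exactly. Correlations are Pearson
on raw values per stratum (all / chromatin categories / orientations) with
undersized or degenerate strata skipped and noted; quintile comparisons are
two-sided rank-sum tests on the expression-qualifying set.

## Permutation enrichment

Observed statistic: overlapping bp between a factor's peaks and the merged
event intervals (peaks counted with multiplicity). The null shuffles peaks
uniformly, preserving count and the exact length multiset, per source
chromosome by default (a genome-wide flag exists), rejecting blacklist
overlaps, and — for tiling-array peaks — redrawing until ≥ 99% of peaks
match their source probe density within 0.1 probes/kb (retry cap 1,000,
then accept with a per-peak flag). Empirical p is two-sided with add-one
correction, p = min(1, 2·(min(#null ≥ obs, #null ≤ obs)+1)/(N+1)), so the
attainable floor at N = 1,000 is 2/1001; enrichment is log2((obs+1)/(mean
null+1)) with the 1-bp pseudo-count making zero-overlap factors
representable and log2 = 0 exactly when observed equals expected.
Adjustment across a panel is Bonferroni by default with a
Benjamini–Hochberg mode (the two conventions coexist in the literature
this follows; neither is asserted as canonical). Peaks are canonically
sorted before shuffling so results are independent of record order.

Numerical core: intervals are mapped to a single absolute coordinate axis
(chromosome offsets) and overlap queries use prefix sums over the merged
reference with binary search — O(log n) per query — which keeps 50 factors
× 1,000 permutations in seconds on one core.

## Problem sizes and tolerances

Tests run the default toy genome (2 × 5 Mb, ~200 origins, ~300 fork
records, seconds per simulation); recovery tests scale to 40–70 Mb genomes
(~1,000–2,000 tracks), chosen as the smallest sizes at which the planted
effects (speed ratio 1.25×, bias p = 0.8, intensity ratio 2×) are separated
from sampling noise by a comfortable margin (3 SE, or 15% for the density
ratio). Monte-Carlo assertions use 3-standard-error bands; exact-agreement
tests (oracle equivalence, determinism, multiset preservation) use
equality. The nearest-ORC recovery uses sparse origins (1/200 kb) because
with offsets comparable to inter-origin spacing the nearest peak is often a
neighbor's, which biases the recovered median low — a property of the
geometry, not of the estimator.

## Known limitations

- The simulator's called origin/termination sets are thinned by collision
  physics in a density-dependent way (see above); analyses of *called*
  events at high origin density inherit that bias.
- Chromatin-state medians in the tens of kb reported for broad-category
  comparisons in the source literature likely describe read lengths rather
  than BrdU track lengths (they exceed the global BrdU median several-fold);
  the package computes and labels both (`length` for BrdU tracks,
  `read_length` carried alongside) rather than resolving the ambiguity.
- The raw per-direction fork-BED adapter pins a 9-column layout that is a
  documented assumption, not a published format.
- Empirical p-values are bounded below by 2/(N+1); panels needing smaller p
  need more permutations.
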