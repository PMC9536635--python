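# Methods

`forkasym` re-implements, as a tested library, a strand-aware analysis of
how DNA replication organisation shapes UV damage formation, nucleotide
excision repair, and somatic mutation asymmetry. This note records the
models and procedures, the defaults and why they were chosen, and what
the synthetic data do and do not establish.

## Coordinate and strand conventions

All intervals are 0-based half-open (BED). Mutation catalogs arrive
1-based and are converted at the parser. Read tables are BED6-shaped
pandas DataFrames. "Plus/Watson" is the reference forward strand.

Fork polarity at a replication initiation zone: windows right of the
zone center are replicated by a rightward fork, for which the plus
strand is the **lagging**-strand template and the minus strand the
**leading**-strand template; roles mirror on the left. The convention is
self-consistent (flipping both side and strand preserves the role) and
all asymmetry summaries are expressed in it.

## Damage-seq processing

The sequencing polymerase stops immediately 3' of a UV lesion, so the
lesion dinucleotide occupies the two bases 5' of the read start in read
orientation. Each read is reduced to a 10-base window with the lesion at
read-orientation positions 5–6: for a plus-strand read `[s, e)` the
window is `[s-6, s+4)` (lesion at `s-2, s-1`), for a minus-strand read
`[e-4, e+6)` (lesion at `e, e+1`, reported reverse-complemented).
Windows off a chromosome end are dropped and tallied. Reads are
deduplicated by `(chrom, start, end, strand)` — strand is part of the
key because every downstream analysis is strand-resolved and a
position-only key would merge opposite-strand lesions (the position-only
variant is available and its effect quantified in the tests). Windows
whose site is not one of TT, TC, CT, CC are discarded as damage-free.
The minus-strand offset arithmetic is locked by an enumeration oracle in
the test suite.

## Window grids and counting

Meta-profiles use grids of `b` adjacent windows of `a` bases centered on
source regions. The span start is `int((start+end)/2 - a/2 - a(b-1)/2)`
with integer truncation, computed exactly in integer arithmetic;
bit-identity with the floating-point form is asserted against an oracle.
Expanded spans that leave their chromosome are dropped; any two
overlapping spans are **both** dropped, so opposite-signal regions
cannot cancel each other. A read increments every window it overlaps by
at least 1 bp (the `bedtools intersect` rule), on its own strand.
RPKM is `count * 1e9 / (window_length * library_size)` and is applied
per cell before averaging over regions; when all windows share one
length the alternative order differs only by a constant, and
normalising first keeps per-region values interpretable on their own.

## Context-matched read simulation

Damage and repair counts are confounded by sequence composition, so each
real library is paired with a simulated one: the real reads are profiled
(per-position nucleotide frequencies per read length, plus the length
distribution, in read orientation) and random genomic reads are drawn to
match by rejection sampling. A candidate (position, strand, length) is
accepted with probability proportional to the background-corrected
likelihood ratio `prod_i p_i(b_i)/q(b_i)` divided by its maximum, where
`q` is the base composition of the sampling space. The correction by `q`
is what makes the accepted reads' per-position marginals equal the model
in expectation when the background is positionally independent; an
uncorrected likelihood converges to background-times-model instead. On
compositionally heterogeneous genomes the match is approximate (the
mixture induces positional correlations); the frequency-matching
contract is therefore validated on a homogeneous background, and the
residual deviation on the default heterogeneous genome is about 0.02
total variation per position.

An optional anchor imposes a hard 2-mer constraint at a fixed
read-orientation position (negative positions count from the 3' end).
Both assay simulations in the pipeline are anchored at the lesion:
damage windows at positions 5–6, excision fragments 5–6 nt from the 3'
end. Anchoring the excision simulation as well — the fragment
demonstrably contains the lesion at that offset — makes the two
simulations respond identically to local composition skew, so their
ratio cancels in the normalized repair rate; an unanchored excision
simulation tracks skew more weakly than the anchored damage simulation
and leaks sequence asymmetry into the repair signal. Sampling can also
be restricted to sequenced input-DNA fragments (`background_reads`),
in which case every simulated read lies within a supplied fragment.
Simulation is deterministic per seed.

## Replication timing and domains

Early and late S-phase nascent-DNA reads are counted in 50-kb bins by
read midpoint, depth-normalised to reads per bin per million, and
combined as `log2((early+1)/(late+1))`. Domains are called by smoothing
with a centered moving average (10 bins), thresholding at zero (ERD
above, LRD below; a smoothed value of exactly zero — an even window
straddling a clean step — takes the raw bin's sign), bridging gaps of at
most 1 bin, and discarding runs under 4 bins (200 kb). Each remaining
boundary is then refined by a least-squares change-point fit of the raw
ratio within half a smoothing window, which reduces the boundary jitter
from about half a bin to essentially zero at noise levels of sigma 0.3.
The minimum size and gap parameters are exposed in the API; the defaults
are the smallest values that produce stable two-state segmentations of
the synthetic tracks. Regions (zones, chromatin segments) are assigned
to the domain covering at least half their length, ties to the larger
overlap and then leftmost.

## Okazaki fragments and initiation zones

Replication fork directionality per bin (default 1 kb) is
`RFD = (C - W)/(C + W)` from minus- and plus-mapped Okazaki fragments;
uncovered bins are NaN, interpolated before smoothing. Initiation zones
are ascents of the smoothed RFD: alternating valley/peak extrema are
found with a prominence floor of half the minimum rise, and each
valley-to-next-peak ascent with total rise >= 0.5 and extent <= 150 kb
becomes a zone. The reported extent is trimmed to the 5–95% levels of
the rise so both endpoints sit on the steep stretch where noise
displaces them least; the center is the interpolated crossing of the
mid-level (the steepest, most stable point of the ascent); the score —
the "adjusted slope" used for quartile stratification — is the trimmed
rise per kb of trimmed extent. Quartile 1 holds the lowest scores, ties
fall to the lower quartile. Zones shared between samples are those
overlapping (>= 1 bp) a zone of every other sample.

## Repair rates

For windows on a shared grid, the repair rate is `RR = XR/Damage` on
RPKM values, and the simulation-normalized repair rate is

    nRR = log2( (XR_real/XR_sim) / (Damage_real/Damage_sim) ).

Cells with any zero input are NaN and stay NaN — aggregations use
defined cells only and report how many. nRR is exactly invariant to
sequencing each library deeper. The early/late fold change is the
per-region (or per-domain) log2 ratio of mean RR, or difference of mean
nRR. Accumulated repair between damage maps at 0 h and 2 h is
`(D0 - D2)/D0`; it is meaningful only when the two libraries share a
depth reference, so the caller supplies the library sizes (the synthetic
round-trip uses the number of drawn lesions). Strand asymmetry around
zone centers uses only windows at least 2 kb from the center, pairs the
plus and minus values of each window, reports per-side medians and a
paired Wilcoxon signed-rank test (suppressed under 5 pairs), and maps
strands to leading/lagging by the polarity convention. TSS/TES profiles
orient all genes left-to-right and read template/non-template roles off
the gene strand. Chromatin-state summaries compute per-segment nRR
(strands pooled, library-normalised counts), group by state and domain,
and compare phases with Mann-Whitney tests; 2x2 tables per state (ERD
vs LRD against better-early vs better-late, dichotomised by the sign of
the per-segment phase difference) feed the odds-ratio machinery.

## Sequence context and skew

K-mers (k = 1..5) are counted on the forward strand, overlapping, within
windows (none spans a window boundary); the reverse-strand percentage of
a k-mer is the forward percentage of its reverse complement, so one
representative per complementary pair is kept (lexicographically
smaller; palindromes once). Net statistics are `net T = #T - #A`,
`net TT = TT - AA` (overlapping), `net TC = TC - GA`, `net C = #C - #G`,
`net CC = CC - GG`; all negate under reverse complementation, verified
exhaustively. The skew summary pairs each collapsed k-mer's
lagging/leading occurrence ratio with its net values and reports the
median ratio per net value. T-rich/A-rich regions are 50-kb slices
ranked by forward-strand T%/A%; the top quartile is T-rich, the bottom
A-rich.

## Mutations

Catalogs are minimal TSVs (chrom, 1-based position, ref, alt, sample).
UV-signature classes: C>T preceded by T (TC>TT, plus strand) or C
(CC>CT, plus); G>A followed by A or G are the same classes on the minus
strand; everything else is "other". Classification is involutive under
genome reverse complementation. The normalized mutation count per
window and strand is MC = signature mutations / strand-matched TC+CC
contexts (forward GA+GG for the minus strand), optionally after removing
mutations inside gene intervals (intergenic mode) and optionally
counting recurrent sites once. Quartile summaries accumulate the
absolute plus-minus difference **per zone side** before summing: fork
polarity mirrors at the center, so a lagging-strand excess has opposite
strand sign left and right of it and would cancel in a pooled total.
Recurrent sites are counted per occurrence by default (the alternative
is a flag) since tumor cohorts are aggregated without recurrence
collapsing unless stated.

## Statistics

Odds ratios are `ad/bc` with a Haldane–Anscombe 0.5 correction when any
cell is zero and Wald intervals on the log scale. The Breslow–Day
statistic compares each stratum's a-cell with its expectation under the
Mantel–Haenszel common OR (the margin-respecting root of the conditional
quadratic), summing squared residuals over the asymptotic variance;
Tarone's correction subtracts `(sum resid)^2 / sum var`. Strata with an
empty margin are excluded with a warning and the degrees of freedom
reduced; a single stratum yields statistic 0, df 0, undefined p. The
implementation is cross-checked against an independent reference
implementation in the tests, and its type-I error is calibrated by
simulation. Rank tests delegate to scipy. No multiple-testing
correction is applied; outputs are per-comparison.

## Synthetic data: what it emulates

The generator plants, deterministically per (spec, seed): a 2 x 2 Mb
genome; half-chromosome ERD/LRD blocks with base AT content 54% / 62%
(the AT contents reported for zones in the two domain classes); 8
initiation zones per chromosome (spacing 250 kb, extent 30 kb,
efficiencies cycling 0.5–0.95); a lagging-strand T-skew of 0.04 (ERD) /
0.10 (LRD) within 50 kb of each center, scaled by the zone's efficiency
(efficient origins segregate strands more often) and normalised so the
domain knob is the across-zone mean; CPD formation propensities
TT .40 / TC .25 / CT .25 / CC .10; excision lengths 22–30 with mode and
median 26; a 2-h repaired fraction of 0.5; a leading:lagging repair
ratio of 1.2; an early/late phase boost of 0.3 log2 units; genes and
ChromHMM-like state tilings; and a mutation catalog placed proportional
to damage propensity times (1 - repaired fraction) in TC/CC contexts.
Damage reads place the lesion two bases upstream of the 5' end (the
exact inverse of the damage-site localisation); excision reads place it
5–6 nt from the 3' end; Okazaki fragments follow a sawtooth RFD through
each zone with slope set by its efficiency; nascent-DNA reads are
4-fold enriched in the in-phase domains.

What the synthetic data are **not**: real coverage depth or insert-size
structure, mappability and GC artefacts, chromatin-dependent repair
kinetics, transcription-coupled repair, replication-timing gradients
within domains, or realistic mutation burden. Passing the recovery
battery shows the pipeline's arithmetic and orientation logic are
correct and that planted parameters are identifiable at these depths;
it does not certify effect sizes on real data.

## Validation battery and problem sizes

The recovery experiments isolate one knob at a time (all other
asymmetry knobs zeroed): the repair-ratio experiment recovers log2(1.2)
from 6 x 10^5 reads per library on 2-kb windows; the phase experiment
recovers +-0.3 per domain using shared damage/simulated libraries so
only the excision libraries differ; the negative control measures the
median paired strand difference over ~2,000 window pairs. The
end-to-end experiment runs the full default conditions over 20 seeds at
1.5 x 10^5 reads per library and checks the sign structure: damage
lagging-biased, normalized repair leading-biased, normalized mutation
rate lagging-biased in LRDs. Sizes were set by pre-computed standard
errors (a few times smaller than each tolerance) while keeping the whole
battery in the minutes range on one CPU.

## Known limitations

- The simulator matches per-position marginals, not joint k-mer
  statistics; a dinucleotide-level model would be needed for exact
  joint matching.
- The initiation-zone caller assumes well-separated ascents; closely
  spaced or nested zones merge.
- The Breslow–Day implementation uses the asymptotic chi-square
  reference; very sparse strata (after the Haldane-corrected OR step)
  warrant an exact test the package does not provide.
- Domain calling is two-state by design; graded replication-timing
  structure within domains is out of scope.
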