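# Methods

`breakscape` compares chromosome-level genomes by chaining orthology
anchors into large-scale homologous synteny blocks (HSBs), reading the
gaps between blocks as evolutionary breakpoint regions (EBRs), and
testing those regions for genomic-feature and gene-set enrichment. A
rearrangement simulator with exact breakpoint ground truth provides the
validation substrate. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Coordinates

All coordinates are 0-based, half-open. BED shares this convention;
GFF3 and AGP are converted at the I/O boundary (1-based, closed). One
internal convention removes a whole class of off-by-one drift.

## The simulator (`simkaryo`)

An ancestral karyotype is drawn with chromosome lengths from a gamma
distribution (mean `mean_length`, CV `length_dispersion`), i.i.d.
nucleotide sequence at a target GC, Poisson-placed non-overlapping genes
(`gene_rate` per Mb, lengths 2–10 kb), and non-overlapping repeat
elements per family until each family reaches its target coverage
fraction (`repeat_mix`; family-specific element-length ranges, e.g.
LINE-L1 1–6 kb, SINE 100–400 bp). Repeat intervals are overwritten with
a tiling of a family consensus generated at the same GC, so genome-wide
GC stays within ±0.02 of the target. There is no substitution or indel
process: the sequence model exists to make GC and repeat-coverage
statistics meaningful, not to support alignment realism.

Rearrangements — fission, fusion, inversion, translocation — are applied
as an explicit, ordered plan against evolving chromosomes. Total genome
length is conserved exactly by every event; genes survive intact with
updated coordinates (inversion flips strand); repeats spanning a cut are
split. Each derived chromosome carries a map of ancestor segments, so
every cut is recorded in ancestor coordinates as a 2-bp interval centred
on the cut site; fusion/inversion/translocation junctions are recorded
in derived coordinates as well. Fission cuts surface only at derived
chromosome termini, so the frame in which a fission is detectable is the
ancestor's — which is exactly how the detection side consumes the truth.

Random plans (`sample_plan`) pick chromosomes length-proportionally and
cut positions uniformly, avoiding gene bodies (configurable). Three
controls shape realism and detectability:

- `edge_margin` (default 0.1 of the chromosome) keeps cuts away from
  chromosome ends: observed karyotype changes involve full-sized
  products, not micro-fragments.
- `min_fragment` (default 0) enforces an absolute lower bound on every
  product and excludes cut zones within that distance of existing
  segment boundaries, guaranteeing that every maximal collinear segment
  stays chainable when set above the block-size filter.
- `breakpoint_bias` multiplies the sampling weight of positions inside
  repeat intervals (optionally one family), planting the repeat-
  associated breakpoint signal.

A fragile-site mode is the stronger form of that signal: the ancestor
can carry hotspot regions (`n_hotspots` per chromosome, width 200 kb by
default) in which gene and chosen repeat-family placement intensities
are multiplied (`hotspot_gene_boost`, `hotspot_repeat_boost`), and
hotspot-mode plans draw each cut from an unused hotspot. Hotspots are
kept ≥ 2 Mb apart and ≥ 1.5 Mb from chromosome ends so each sits inside
its own Mb-scale run of conserved flanking sequence. This mirrors the
empirical association of evolutionary breakpoints with repeat-dense,
gene-rich chromatin.

Ortholog pairs become anchors (`emit_anchors`) with configurable
dropout (Bernoulli per pair), positional jitter (Gaussian shift of each
interval, clamped to the chromosome) and micro-inversion (orientation
flip only).

## Anchors

Raw local matches are maximal exact matches of ≥ 20 bp (k-mer seeding
with k = the minimum length, bidirectional extension; `N` participates
in no match; reverse-strand matches reported in forward coordinates
with orientation −). Matches are clustered against ortholog gene pairs:
a match supports a pair when both of its intervals fall within `window`
(default 10 kb) of the pair's gene intervals, and each pair's
supporting matches merge into one anchor spanning their joint extent.
At desk scale the usual route is ortholog pairs directly: one anchor
per pair, orientation = strand product, weight = smaller gene span.

## Synteny blocks

Anchors are stratified by (chromosome A, chromosome B, orientation) and
chained by weighted dynamic programming: chains are monotone on both
genomes under the stratum orientation, with inter-anchor gaps ≤
`max_gap` (default 2 Mb) on both sides, maximizing summed anchor
weight. The DP is O(n²) per stratum — with gap constraints on both
genomes the classical O(n log n) longest-increasing-subsequence trick
does not apply, and n here is thousands at most. Chains are extracted
greedily by score; "large-scale" blocks must have ≥ `min_anchors`
(default 3) and span ≥ `min_span` (default 1 Mb) on both genomes.
Those defaults are this package's operational definition of
"large-scale" (the Mb scale of published HSB tables); published HSB
counts for real genomes are not reproduction targets since the original
block-building parameters are not public.

Micro-rearrangements are tolerated by absorption: after block
acceptance, unchained anchors lying inside a block's footprint on both
genomes are added to the block, up to `micro_tolerance` (default
200 kb) of total span — a short internal inversion or transposition
does not split a block. Blocks are finally made non-overlapping on the
target genome: contained blocks are dropped (higher score wins),
partial overlaps trimmed at the overlap midpoint.

The chainer is validated against exhaustive path enumeration on random
instances of ≤ 12 anchors (500 instances in the acceptance suite).

## Breakpoint regions

Per target chromosome, blocks are sorted and every gap between adjacent
blocks becomes one EBR demarcated exactly by the flanking block ends.
Terminal gaps have a block on only one side and are not EBRs. A gap
whose flanks map to different partner chromosomes is interchromosomal —
a fission when viewed from the target genome; same-partner gaps are
intrachromosomal. Abutting blocks with a partner change emit a 1-bp
junction EBR so fission evidence is never silently dropped. Fission
events are counted as partner transitions between adjacent blocks,
which equals the number of interchromosomal EBRs whenever gaps are
nonzero.

Merging EBR sets from two comparisons onto one genome unions intervals
sharing ≥ 1 bp (transitively), pooling source labels. The reported
cross-set overlap count is the number of merged groups containing
non-identical members of both sets; a region with identical coordinates
in both sets is the same region seen twice, not an overlap. No fuzzy
distance-based merging is done: the published unions are described as
overlapped regions, with no tolerance stated.

## Feature statistics

Chromosomes are tiled into fixed windows (default 100 kb; the terminal
window may be short). Per window: gene density (genes/Mb counted by
midpoint — midpoint counting avoids double-counting across window
edges), GC fraction (N excluded from the denominator), repeat coverage
fraction (clipped overlap). The EBR-overlapping windows (x) are
compared against all windows (y) of the chromosome or genome with the
Mann-Whitney U test — the literal "EBRs versus the whole chromosome"
contrast; `y_mode="complement"` is available. Gene *lists* for regions
use the ≥ 1 bp overlap rule instead of midpoints, the natural rule for
"genes located in EBRs".

The U statistic counts pairs with x > y (ties half). The exact method
(scipy) enumerates the permutation null and is used when samples are
tie-free with n₁·n₂ ≤ 10⁴; otherwise the tie-corrected normal
approximation with continuity correction applies. Two-sided by default;
the direction of shift is reported separately.

Because x ⊂ y under `y_mode="all"`, the test is mildly conservative:
U(x, y) = |x|²/2 + U(x, y\x), so the assumed variance overstates the
true one by the factor (m+k)/k where m = |x|, k = |y\x|. With EBRs
covering ≲ 10 % of windows the size at α = 0.05 is ≈ 0.04, which the
calibration test confirms for gene density and GC. Repeat coverage runs
slightly more conservative still (≈ 0.02–0.03): repeat elements that
straddle window boundaries correlate adjacent windows, and EBR windows
come in adjacent runs. Worth knowing when reading borderline p values
for that feature.

Repeat-family enrichment reports per-family fold change (coverage
fraction in EBRs over genome-wide) with a permutation p from ≥ 1000
(default) random placements of a length-matched region set on the same
karyotype; families absent genome-wide get an undefined fold, flagged
as NaN. Gene-set overrepresentation is the upper-tail hypergeometric
probability per term (terms intersected with an explicitly supplied
universe — no default universe is assumed), with Benjamini–Hochberg
FDR across terms of one annotation source.

## Scaffolding

Flow-sorted library depths are normalized per library by the library
median (sorted libraries differ in depth by ~4×, so raw depths are
incomparable); a scaffold is assigned to its best library only when the
best/second-best ratio ≥ `min_ratio` (default 3). This normalization
presumes each library holds a minority of scaffolds — true whenever
there are more than a handful of chromosomes. Mixed libraries (two
chromosomes co-sorted) and ambiguous scaffolds are resolved by
reference synteny through an explicit reference→target chromosome
correspondence map: a scaffold goes to the target chromosome whose
reference chromosomes carry ≥ 60 % of its aligned HSB span. Within a
chromosome, scaffolds are ordered by the span-weighted median reference
coordinate of their HSBs; orientation is the majority HSB orientation
when ≥ 70 % of aligned span agrees, else "unknown" (written as '+' in
AGP, which lacks an unknown token for placed components). The layout is
emitted as AGP v2.1 plus concatenated FASTA with 100-N gaps;
AGP → layout → AGP round-trips exactly. Scaffolds without synteny
evidence stay unplaced, like real unanchored scaffolds. Conflicts
between coverage and synteny evidence are surfaced, not silently
resolved.

## Pipeline

`run_pipeline` simulates one ancestor and three derived genomes,
runs all six ordered pairwise comparisons (each genome as target
against the other two), merges the two EBR sets per genome, profiles
EBR windows, ranks repeat families, and tests EBR genes against a
(synthetic or supplied GMT) annotation. All randomness derives from one
seed through named SHA-256 substreams, so a config + seed is fully
reproducible; every tabular output carries the tool version and config
hash, and an unchanged config reuses the previous run's report.

## Problem sizes in the test suite

The bundled tests run the analysis on scaled-down genomes: ancestors of
4–10 chromosomes at 2–10 Mb, gene densities of 8–30 per Mb, and 100-kb
windows. Scaling down a genome while keeping Mb-scale blocks means gene
density is kept higher than mammalian (≈ 9/Mb) so blocks retain
realistic anchor counts. The enrichment-recovery study uses 10 × 8 Mb
chromosomes, 18 hotspot-guided fissions and the planted 2× gene / 3×
LINE-L1 hotspot intensities, sizes fixed from a pilot power analysis on
separate seeds. The breakpoint-recovery study uses a regular 200-kb
anchor grid, which is what makes its "every EBR ≤ 400 kb" width bound a
theorem rather than a probability.

## What passing tests do and do not show

The simulator plants clean, identifiable structure: exact anchors,
independent noise, homogeneous background feature densities and sharply
bounded hotspots. Passing recovery tests therefore demonstrates the
correctness of the chaining/detection/statistics machinery, not
performance on real assemblies, where anchor noise is correlated
(alignment artifacts, segmental duplication), repeat landscapes are
autocorrelated over Mb scales, and block-size definitions trade off
against assembly fragmentation. The published genome-scale block and
EBR counts depend on those factors plus unpublished aligner settings,
and are out of reach — and out of scope — at desk scale.

## Known limitations

- No nucleotide substitution/indel evolution, segmental duplication or
  recombination in the simulator.
- Exact-match finding is k-mer seeded and quadratic in the worst case;
  it targets desk-scale sequences, not whole mammalian chromosomes.
- The EBR-window Mann-Whitney inherits the window-overlap conservatism
  described above; complement mode avoids it at the cost of departing
  from the "whole chromosome" contrast.
- Orientation of single-anchor scaffolds is undeterminable and reported
  "unknown" rather than guessed.
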