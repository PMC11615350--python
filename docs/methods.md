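# Methods

## Coordinate and signal model

All intervals are 0-based half-open, as in BED/narrowPeak/bedGraph; any
conversion happens at file boundaries only. A gene's TSS is
`interval.start` on the + strand and `interval.end − 1` on the − strand,
so the TSS is always a covered base of the gene. A gene "contains a CGI"
iff a CpG-island interval overlaps the promoter window TSS ± 2 kb
(clipped at position 0); the source data name CGI-containing genes without
defining containment, and promoter-proximal overlap is the standard
operationalization.

Coverage is a per-chromosome step function with value 0 wherever no
bedGraph record covers a position. Each chromosome stores breakpoints and
a cumulative integral, so interval means are two O(log n) lookups; a
multiplicative `scale_factor` (reads-per-million) is applied at query
time, keeping raw values auditable. A consequence used throughout:
multiplying IP and input by one constant leaves every fold change, ratio
and label unchanged (tested).

## Consensus and partition

Replicate peaks of one genotype are clustered by a single coordinate
sweep; each cluster's union interval is retained iff ≥ `min_reps` (default
2 of 3) distinct replicates contribute, with support counted per replicate
(two fragments from one replicate are one replicate's evidence). With
`min_reps = 1` this degenerates to the plain interval union, which the
tests use as an oracle.

Cross-genotype matching is one-to-one and greedy by descending overlap
length, ties broken by leftmost KO then leftmost WT interval. The source
analysis reports a single common-peak count without describing
many-to-many handling; one-to-one keeps `|WT| = |common| + |WT-only|`
(and symmetrically) an exact invariant, which the pipeline asserts on
every run. The fc for a common pair is measured over the union of the two
matched intervals so both genotypes are quantified on the same span.

## Fold change and classification

`fc` defaults to the mean of per-replicate ratios (mean IP coverage /
input coverage); "average fold change" is not further specified upstream,
so the alternative ratio-of-means is selectable in config (`fc_mode`).
The input denominator is floored at ε = 0.25 — a quarter of one
reads-per-million-scaled read — to keep peaks over input gaps finite;
engagements are visible in the calls table as exact multiples of 1/ε.

Thresholds (`fc > 3`, `log2 ratio > 0.23`) are strict inequalities, and
for common peaks the fc threshold is applied to the candidate-enriched
genotype only — the minimal reading consistent with the rule for
exclusive peaks, where only that genotype's fc exists. The ratio rule is
applied symmetrically for KO-enriched calls. Boundary behaviour (fc
exactly 3, ratio exactly 0.23 → unclassified) is pinned by tests.

Genomic categories are deliberately three (promoter/TSS = within ± 2 kb
of any TSS, then gene body, then intergenic, in that priority, anchored
at the peak summit or midpoint), not a full annotation ontology; nearest
TSS is resolved by binary search with ties broken by lexicographic
gene_id for reproducibility.

## TSS windows and metagenes

The downstream window is strand-aware: `[tss, tss + 2500)` on +,
`(tss − 2500, tss]` on −, clipped at chromosome ends with the mean taken
over the clipped span. Genes with zero WT mean have an undefined KO/WT
ratio and are excluded from both directional counts (reported separately),
rather than mapped to infinity. Per-genotype replicate means are averaged
before the ratio.

Metagene matrices tile `[anchor − flank, anchor + flank)` (defaults
10 kb / 50 bp, the deepTools convention) and reverse minus-strand rows;
bases beyond a chromosome end contribute 0 to their bin. Because the
minus-strand anchor is the last covered base, plus- and minus-strand bin
grids are offset by one base; the strand-symmetry tests account for this
by mirroring interval boundaries, and the column-mean profile is checked
against a naive per-base double loop.

## Statistics

KS uses the asymptotic two-sided null (scipy), matching common practice
at genomic sample sizes; the statistic is verified against an exhaustive
ECDF sup-difference oracle and the null type-I error is calibrated by
simulation (2,000 null pairs, n = 50, α = 0.05, accepted band
0.03–0.07). The per-category "FDR" comparison is implemented as a Fisher
exact test per category (category vs rest × condition A vs B) with
Benjamini–Hochberg across categories — the conventional reading, since
the upstream figure legend names only "p.FDR". Pearson CIs use the
Fisher z transform with SE `1/√(n−3)`; collinear inputs return the
degenerate point interval.

## Cytometry scores

SCENITH glucose dependence and FAO/AAO capacity follow the printed
formulas and satisfy GD + FAO/AAO = 100 identically; values outside
[0, 100] (possible with noisy gMFI) are reported raw with a warning, not
clamped, to preserve auditability. Relative MFI subtracts the
no-primary-antibody background, optionally normalized to a reference
population. The top-percentile selection uses the nearest-rank rule
(`ceil(n·pct/100)` cells) independently per batch, with deterministic
tie-breaking by intensity then cell id.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure of the study design:
two genotypes × three IP replicates × one shared input per genotype,
planted site classes (default 600 sites: 150 WT-enriched, 150
KO-enriched, 300 unchanged; 25% of each enriched class
genotype-exclusive), multiplicative lognormal replicate noise on fc
(σ = 0.2), 10% per-replicate peak dropout, and ± 25 bp peak-edge jitter.
Enriched sites sit 1.5× beyond both classification thresholds and
unchanged sites at 0.75× the fc threshold, so classes are separable at
the default noise; the margins are validated at construction. Genes are
laid out in slots with ≥ 6 kb between neighbours so planted CGI flags
are recovered exactly by the ± 2 kb rule. A companion generator plants
per-gene KO/WT downstream-signal ratios (default 72.4% of genes below 1)
that the TSS pipeline recovers exactly at zero noise.

Not modelled: read-level sampling (shot noise within a peak), fragment
size, GC bias, peak-shape variation, copy-number or mappability
artifacts, and a realistic peak caller (peak calls are emitted directly).
Passing tests therefore demonstrate correctness of the downstream
arithmetic and classification logic under the stated noise model, not
robustness to upstream alignment/peak-calling variation.

## Problem sizes and determinism

Default analysis and acceptance runs use a 2 × 3 Mb genome, 200 genes and
600 sites — large enough that every code path (both genotypes, exclusive
sites, dropout, CGI strata) is exercised with stable proportions, small
enough to run in seconds. All randomness flows from a single
`numpy.random.default_rng` seed per generator call; pipelines contain no
unseeded randomness, and rerunning a pipeline on identical inputs
produces byte-identical tables (tested).

## Known limitations

- One-to-one common-peak matching undercounts sharing when one broad peak
  in one genotype spans several in the other (the leftovers land in the
  exclusive sets); the pairing table makes this auditable.
- The epsilon floor makes fc over zero-input regions depend on ε; such
  calls should be treated as lower bounds.
- `scale_regions` body bins use fractional-base integration at bin edges
  rounded to whole bases, adequate for bodies ≫ bin count.
- The asymptotic KS p-value is conservative for very small samples
  (n < ~20); the statistic itself is exact.
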