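# Methods

## The ED scan

At each retained SNP site the two bulks' base counts are converted to
maximum-likelihood frequency vectors (count / total; no pseudocounts —
the per-bulk depth filter, default ≥ 3 reads in *each* bulk, is the only
guard against unstable frequencies). The Euclidean distance between the
two four-base vectors is the per-site statistic; all four bases enter
even at biallelic sites (zero-frequency bases contribute nothing, and
the four-term form makes the statistic invariant to base relabelling).
ED ∈ [0, √2], attaining the upper bound only for fixation on disjoint
bases. The power transform ED^k (default k = 5) preserves site ranking
for any k ≥ 1 while shrinking small background values; k = 1 gives raw
ED for diagnostics.

Expected values under the backcross design: a marker fully linked to
the causal locus shows donor-allele frequencies 0.5 (heterozygous
carriers, bulk F) vs 0 (bulk S), hence ED = 1/√2 and ED⁵ = 2^(−5/2) ≈
0.17678. Linkage decays the contrast as (1 − 2r(d)) with the Haldane
recombination fraction r(d), so the ED⁵ profile is a hill of width a
few cM around the locus.

## Smoothing

The fitted value at each SNP is the median of ED^k over the window of
`half_window` (default 50) SNPs on each side plus the focal SNP,
counted in SNP-index space within its chromosome. Windows shrink at
chromosome edges rather than padding or reflecting — padding invents
data — and never cross chromosome boundaries. The focal SNP is
included; for a robust median window the inclusion choice is
practically immaterial, and inclusion keeps edge windows well defined.
A base-pair window mode (`sliding_median_bp`) and a genuine locally
weighted regression (`lowess_fit`, tricube weights, span parameter) are
provided as clearly non-default alternatives; the default fit is a
median because that is what the scan thresholds.

## Threshold and region calling

The cutoff is the empirical q-quantile (default q = 0.99) of the
genome-wide smoothed ED^k values, computed by linear interpolation
between order statistics at rank 1 + q(n − 1) — stated exactly so that
results reproduce across implementations. Sites with ED = 0 are kept in
the quantile set (configurable). Sites whose track value is ≥ the
cutoff (boundary inclusive, deterministic and conservative toward
detection) are significant; maximal per-chromosome runs of significant
sites become regions, optionally bridging up to `max_gap_snps`
non-significant sites (default 0) and dropping runs below
`min_region_snps` members (default 1, so single-SNP regions are
reported and left to the analyst). Region boundaries are the first and
last member-SNP positions themselves — interval sizes are therefore
end − start, which is the convention that reproduces published interval
sizes quoted at SNP resolution. Both the threshold and the flags can be
switched to the raw ED^k track (`threshold_source="raw"`); tiny
single-SNP regions are characteristic raw-mode artifacts.

### Flag budget vs hill width

The q-quantile flags at most a fraction (1 − q) of sites. Region
calling therefore behaves well only when the linkage hill around a
causal locus occupies less than (1 − q) of the genome's SNPs. On a
ten-chromosome genome (the scale of the maize design this package
emulates) a single locus's hill is a small genome fraction and the top
region contains the causal position essentially always (measured 20/20
across seeds in the acceptance suite). On a two-chromosome toy genome
the same hill exceeds the 1% budget, the cutoff lands inside the hill,
and the flagged set fragments into slivers whose endpoints are
noise-driven — the peak *position* remains well localized (within a few
Mb), but region *containment* of the causal point becomes unreliable.
The test suite checks localization at the two-chromosome scale and full
containment at the ten-chromosome scale. Practical guidance: on small
genomes or dense single-locus signals, lower q or use `max_gap_snps` of
the order of the smoothing half-window (adjacent fitted values are
correlated over the window length, so sub-window gaps are dips of one
peak, not separate peaks).

## Candidate nomination and enrichment

Differential expression is filtered at FDR < 0.01 and fold change ≥ 2
on the bulk-F/bulk-S ratio scale; down-regulation is fold ≤ 1/2.
Reports that print magnitude-plus-direction pairs are converted to the
ratio scale on input. A gene is assigned to a region on ≥ 1 bp overlap;
a gene overlapping several regions goes to the larger overlap, ties to
the lower region id. Candidates are the intersection of the DE set with
region membership. Final shortlisting by functional annotation is a
manual step; `keyword_filter` automates only the obvious substring
screen.

Pathway enrichment uses the upper-tail hypergeometric test per term
against a background that defaults to the genes in the supplied DE
table (an "expressed genes" universe); an explicit background list or
size may be given instead, and the choice matters for the fold values,
which scale with the background size. Q-values are Benjamini–Hochberg
across terms (the method is recorded in the output header). Enrichment
fold is the DE-set annotation proportion divided by the background
annotation proportion.

## The synthetic generator

The generator emulates an advanced-backcross near-isogenic bulked
design: a parent heterozygous for a donor haplotype (by default across
the whole causal chromosome — the worst-case background; a
segment-restricted mode narrows the segregating window to mimic
marker-assisted near-isogenic material) is crossed to the recurrent
parent, so each progeny carries one recombinant gamete on segregating
chromosomes and recurrent homozygosity elsewhere. Meiosis follows the
Haldane model — Poisson crossover counts at `cm_per_mb` (default
1 cM/Mb, a typical plant genome-wide density), uniform positions, no
interference — the simplest model consistent with a backcross mapping
design. Carriers of the donor allele at every causal locus express the
phenotype with probability `penetrance` (default 1, the clean case
where fertile plants are heterozygous and sterile plants homozygous
recurrent without exception); bulks of `bulk_size` (default 30, the
study's pools) are filled adaptively from phenotype-positive and
-negative individuals, with optional `misclassification` slot swaps.
With no causal locus every chromosome segregates and the bulks are a
random partition — the null model.

Pooled sequencing draws a per-marker read count from Poisson(`depth`)
(default mean 50× per marker per bulk; a fixed-depth mode exists for
exact calibration tests) and assigns each read the donor or recurrent
base from the bulk's pooled frequency, with a uniform miscall
probability `base_error` (default 0.001, a typical post-filter
short-read error rate). Markers (default 5,000 per chromosome, placed
uniformly at random or on a grid) each carry distinct recurrent/donor
bases. Everything is driven by one integer seed; identical
configurations produce byte-identical outputs.

What the generator does *not* model: haplotype-aware reads (sampling is
per-marker independent — adequate because the statistic uses per-site
frequencies only), allele-specific or gene-level expression variation
beyond Poisson depth scatter, crossover interference, epistasis between
causal loci, and environment-dependent penetrance. Passing recovery
tests therefore demonstrate correctness of the mapping arithmetic under
the idealized design, not robustness to expression-level artifacts of
real RNA-seq bulks.

The companion fixture generator (`simulate_de_table`) places background
genes with null statistics (fold near 1, FDR ≥ 0.05), plants strongly
DE genes inside declared truth intervals, and can add strongly DE
decoys guaranteed outside them, so nomination can be tested for exact
recovery and exact rejection.

## Numerical and interface choices

Double precision throughout; comparisons use exact double semantics.
Coordinates are 1-based inclusive everywhere internally (VCF/GFF3
convention); only BED export converts to 0-based half-open.
Chromosomes sort naturally (chr1 < chr2 < chr10) unless an explicit
order list is supplied. Duplicate (chrom, pos) records: last wins, with
a warning. Multi-allelic VCF sites with up to four single-base alleles
have their depths distributed onto the A/C/G/T slots; indel and
symbolic records are skipped. No variant-quality filter is applied by
default. The depth filter is applied to each bulk separately, since one
under-covered bulk alone makes the distance meaningless.

Problem sizes in the test and acceptance suites — 5,000 markers per
chromosome, 150 Mb chromosomes, 10–20 seeds per calibration — are the
package's chosen desk-scale study conditions: large enough that the
quantile, smoothing and recovery behaviour match the asymptotic
analysis above, small enough to run routinely.
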