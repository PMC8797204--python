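# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions.

## Coordinates and containers

All intervals are 0-based, half-open (BED convention); 1-based conversion
happens only in the GFF3 reader. A minus-strand TSS is `end - 1`, the standard
convention. Adjacent intervals ([0,10) vs [10,20)) do not overlap; blacklist
subtraction removes a peak entirely on any ≥ 1 bp overlap rather than trimming
it. Signal tracks are contiguous fixed-width bins holding mean density;
region scores integrate density × covered width, so partial bins contribute
proportionally. Contact matrices are stored as upper-triangle sparse
coordinates on a single chromosome.

## Super-enhancer calling

Peaks with q ≤ 1e-5 (and no blacklist overlap) are stitched whenever the gap
to the previous peak is ≤ 12,500 bp (transitive closure), without TSS
exclusion. A stitched region's score is the integral of H3K27ac density over
its span; input subtraction (`max(signal − input, 0)`) is available but off by
default, since region-level scoring on the ChIP track alone is the common
default and both paths are tested. Ranking is by descending score with
genomic position breaking ties.

The cutoff mirrors the hockey-stick construction: scores are sorted
ascending, ranks and scores are min–max scaled to the unit square, and the
centred-secant slope (one-rank window) is scanned from the low end; the first
point where the slope reaches 1 is the tangency of a slope-1 line slid onto a
convex increasing curve, and its unscaled score is the cutoff. Regions
strictly above the cutoff are SEs (strict inequality is the conservative
tie-break). Degenerate curves — all scores equal, or slope ≥ 1 from the first
evaluable point, as on a straight line — yield zero SEs and a logged warning.
The construction is affine-invariant by design. On a dense grid of `y = x²`
the cutoff lands at scaled (0.5, 0.25), the calculus answer.

An SE is a lncRNA-SE iff at least one lncRNA TSS lies inside the SE interval
(half-open containment, per-gene canonical TSS). TSS containment rather than
a ± window is used because the class is defined by transcription *from* the
SE. Remaining SEs are regular SEs (R-SEs).

## Enrichment and profile statistics

Observed/expected enrichment uses the midpoint rule (a straddling peak counts
once): observed is the number of query midpoints inside the reference union,
expected is `n_query × (reference bp / genome length)`, and p is the
upper-tail binomial at the observed count. The GO test is the region-based
binomial over regulatory domains, simplified to basal (TSS ± 5 kb) plus up to
50 kb extension truncated at the neighbouring genes' basal domains; term
domains are unions over member genes, p-values are BH-adjusted across terms,
and zero-coverage terms are skipped with a log entry. Meta-profiles average
the track over ± 5 kb around each centre (edge centres skipped and counted)
and are smoothed by local linear regression with tricube weights (span 0.3) —
a fully specified equivalent of loess.

The Wilcoxon rank-sum test uses midranks. For small designs (any split with
C(n, n1) ≤ 20,000, which covers 8 per group) the two-sided p is computed by
exact enumeration (twice the smaller tail, capped at 1); larger designs use
the normal approximation with tie-corrected variance and a 0.5 continuity
correction. The approximation agrees with enumeration to ~0.02 on untied
8 + 8 data but drifts further on heavily tied tiny samples, hence the exact
path.

## Contact maps, virtual 4C and loop calling

Raw pairs are accumulated per unordered bin pair (5 kb default bins).
VC-sqrt normalization divides each entry by the square root of the product of
its bins' marginals; zero-coverage bins stay masked. Virtual 4C is the
symmetrized row of the bin containing the anchor, conventionally taken from
the VC-sqrt matrix; a masked anchor is an explicit error.

Loop significance is a deliberately simple surrogate for spline-based HiChIP
callers, with a contract of FDR control and power verified empirically rather
than numerical equivalence to any external tool. Candidates are bin pairs at
20 kb–2 Mb separation. The expected count is `μ(d) · b_i · b_j`, where μ(d)
is the empirical mean count of the pair's distance stratum — 100 equal-width
strata in log distance, so each stratum spans < 5% in distance and the
shortest-range strata hold single offsets; strata with < 10 pairs merge into
a neighbour — and `b_i` is the bin's coverage bias: its observed marginal
divided by the marginal expected at its position under the genome-wide
per-offset means, normalized to mean 1. The positional denominator matters:
raw marginals are low at chromosome edges only because edge bins have fewer
partners, and dividing by a global mean coverage instead would deflate edge
expectations and produce spurious edge loops (this failure mode was observed
and is why the bias is positional). p is the Poisson upper tail
`P(X ≥ count | expected)`; BH runs over *all* in-range unmasked bin pairs
(zero-count pairs carry p = 1 and count toward m), and loops are reported at
q ≤ 0.01. Calibration on null synthetic maps: zero discoveries across 20
maps; power: 8/8 planted 8-fold loops recovered per default map.

Loop-to-promoter mapping links SE *s* to coding gene *g* when one anchor bin
overlaps *s* itself (not a window around it, matching the virtual-4C anchor
usage) and the other overlaps *g*'s promoter (TSS ± 1 kb); anchor distance is
the separation of the two bin centres.

## Expression and differential lncRNAs

TMM normalization follows the published trimmed-mean-of-M-values recipe: the
reference sample is the one whose upper-quartile count fraction is closest to
the mean; M (log2 ratio of library-scaled proportions vs the reference) and A
(average log2 abundance) are computed over genes positive in both; both are
doubly trimmed (30% tails of M, 5% tails of A); the factor is the
precision-weighted mean of the surviving M values with delta-method inverse
variances, and factors are rescaled to geometric mean 1. An independent
direct-formula implementation agrees to < 5%.

Genes with CPM > 1 in at least min-group-size samples are kept. log2 CPM uses
effective library sizes (`libsize × factor`) and a prior count of 0.5. The
test is a per-gene two-sided Welch *t* on log CPM with BH adjustment — a
plain, calibration-verified engine rather than a moderated-t replica, since
the package's contribution is the funnel, not the DE machinery. On null
simulations the type-I error at 0.05 sits in [0.03, 0.07] and planted
two-fold-log2 effects at 10 + 10 samples are recovered with ≥ 80% power.

## The prioritization funnel and PPI subnetwork

Funnel stages: SEs → lncRNA-SEs → those with a DE lncRNA (q < 0.05) → those
with ≥ 1 significant loop to a coding promoter → those whose looped target is
in the designated GO set. Stage counts are non-increasing by construction;
candidates sort by DE q then anchor distance; the mean anchor distance is
reported over stage-4 SE–promoter pairs. GO membership is tested on the
looped target, reproducing the intersect-the-two-gene-sets logic of the
original analysis.

The PPI subnetwork keeps edges whose endpoints are both expressed — TPM
strictly greater than the 10th percentile (linear interpolation) of all TPM
values — and at least one endpoint is a seed; nodes are endpoints of kept
edges. Extraction is idempotent and order-independent.

## Assay quantifications and clinical tables

The two-sided Fisher exact test uses the minimum-likelihood definition: sum
the hypergeometric probabilities (log-space, with a 1e-7 relative tie
tolerance) of all margin-consistent tables no more probable than the observed
one. Categorical clinical rows are reconstructed from printed percentages as
`round(pct × n / 100)`; a row where no integer count reproduces the printed
percentage within half a unit of its last decimal is flagged, not coerced.
Continuous rows use Welch *t* from mean ± SEM with Welch–Satterthwaite
degrees of freedom; normality-based routing to nonparametric tests is
impossible from summaries, and such rows carry a note. Relative qPCR
quantification is `2^−ΔΔCt` with per-sample ΔCt against the reference gene;
3C interaction frequencies scale ligation quantities by the undigested
genomic control and then by the anchor's nearest downstream restriction
fragment (which therefore maps to 1.0); ChIP enrichment is signal/IgG,
optionally per-input normalized. All three are exactly scale-covariant.

## The synthetic-data generator

One synthetic chromosome (`chrS`, 20 Mb default; a 5 Mb `compact` preset for
repeated-seed calibration). Defaults describe the study conditions the
pipeline is meant to resolve: 30 planted SEs (clusters of 5 peaks, widths
0.8–2 kb, gaps 3–8 kb, so spans are ~25–35 kb and stitch into single regions
at 12.5 kb), 10 of them containing a lncRNA TSS; 300 coding genes and 100
lncRNAs placed at distinct 5 kb bins; ATAC accessibility boosted 5-fold
inside SEs; a contact map with mean count `200 · k^-1` at k-bin separation
and planted loops at 8-fold over expectation, with SE–promoter separations in
60–400 kb; and a 10 + 10 negative-binomial design (dispersion 0.2) with a
planted |log2 FC| of 2 on 20% of lncRNAs, library sizes log-uniform over a
4-fold range so TMM is non-trivial. Peak signal is a single mean-density
number per peak (region-level scoring consumes exactly that; read-level
simulation adds nothing the pipeline tests). Planted truth guarantees exactly
one candidate satisfying all funnel conditions, and the designated GO set
excludes the other looped targets so the answer is unique.

Placement uses guaranteed separation (one guarded slot per SE, slack spread
uniformly), erroring explicitly when the genome is too small. Background
peaks are scattered uniformly *outside* SE neighbourhoods (span ± 12.5 kb)
and away from lncRNA promoters: without those exclusion zones a background
cluster could extend a planted SE or spuriously contain a lncRNA TSS, making
the planted truth ill-defined as a test oracle. A handful of strong peaks are
planted inside blacklist regions to exercise removal. Baselines of planted DE
lncRNAs are floored at 32 counts so the planted effect is detectable at the
design size rather than vacuously untestable.

What the generator does *not* emulate: reads (no FASTQ or alignment),
restriction fragments, multiple chromosomes, diploid genomes, coverage bias
in the contact map (bias handling is exercised only through the positional
correction), batch effects or outlier samples in the counts, and secondary
structure in the PPI network. Passing tests therefore demonstrate the
pipeline's logic, calibration and power under the planted model, not
robustness to every artifact of real sequencing data.

## Numerical conventions

Every random draw flows from `numpy.random.default_rng([seed, stream])` with
a fixed stream id per generator stage, so outputs are byte-identical under a
fixed seed. BH adjustment accepts an explicit number of tests m ≥ len(p) for
implicit p = 1 hypotheses. Poisson/binomial tails and hypergeometric masses
come from scipy in log space where underflow matters. Degenerate inputs are
contracts, not crashes: all-equal scores → zero SEs; empty DE input → empty
funnel stages; zero-variance genes → p = 1 (equal means) or maximal
significance (unequal means); masked virtual-4C anchors, zero normalizers and
missing reference genes raise explicit errors.

## Known limitations

The loop caller is not a reimplementation of any published HiChIP caller; its
numbers are not comparable tool-to-tool, only its error control is specified.
The DE engine has no variance moderation and will lose power at very small n
relative to empirical-Bayes methods. GO regulatory domains use a single
basal-plus-extension rule rather than curated association rules, so absolute
GO p-values are not reproduction targets. Clinical-table statistics computed
from printed summaries cannot reproduce analyses that used raw per-patient
measurements (nonparametric routing, covariate adjustment); rows that fail
count reconstruction are flagged and excluded from assertions.
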