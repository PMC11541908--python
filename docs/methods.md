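# Methods

This note documents the models, estimators, parameter choices and known
limitations behind each stage of the pipeline, and what the synthetic
benchmark does and does not establish about real data.

## Coordinates and the contact-map model

All intervals are 0-based half-open (BED convention); pairs files carry
1-based positions and are converted on read. A read pair increments exactly
one unordered bin-pair cell, using the bin containing each mate's 5′
position; fragment-level assignment and duplicate handling are upstream
concerns. Counts are stored as dense symmetric float matrices — appropriate
below ~5,000 bins, the regime of the bundled genomes — with a sparse-input
path for larger COO data.

Bins whose marginal falls below `min_frac` (default 0.02) of the median
nonzero marginal are masked and excluded from every downstream statistic.
Balancing is iterative correction (ICE): per-bin divisors `w` such that the
balanced marginals over unmasked bins agree within `tol` (default 1e-5,
max 200 iterations), rescaled so the mean balanced marginal is 1. The unit
target makes O/E scale-free: doubling all counts changes weights by √2 and
leaves O/E untouched. Where the source study delegated normalization to an
external pipeline without stating the variant, this package standardizes on
iterative correction and records that in output metadata.

Known bias: ICE assumes equal visibility, so genuine coverage differences
are partially absorbed into the weights. Chromosome-end bins, which have
fewer close neighbors and hence smaller raw marginals, receive small
weights; their balanced trans values are inflated by roughly 10–30% on the
synthetic genomes. This is visible as telomere–telomere scores slightly
above their planted boosts and as a mildly elevated trans O/E for bins in
insulated domains. The effect is reported, not corrected.

## Contact decay (IDE)

P(s) is the mean balanced contact over unmasked pairs in log-spaced distance
bands, 8 per decade; a band's distance is the mean pair separation within
it, not the edge midpoint, which keeps an exact power law exactly straight
in log-log space. The IDE is the ordinary-least-squares slope of log10 P vs
log10 s over 10–500 kb at 10 kb bins (both configurable); zero bands are
dropped, never imputed, and fits with fewer than three usable bands raise.
OLS in log space was chosen as the estimator; alternatives (e.g. Poisson
regression on counts) were not needed at the depths the package targets.

## A/B compartments

Cis mode computes, per chromosome, the Pearson correlation map of O/E rows
(over columns valid in both rows), mean-centers it and eigendecomposes;
trans mode centers the genome-wide trans O/E (cis blocks zeroed) and
eigendecomposes once. The compartment signature is not always the *top*
eigenvector — a strong insulated domain, or the centromere sub-structure,
can carry the largest eigenvalue — so the top three eigenvectors are
computed and the one best correlated in magnitude with the GC track is
selected and sign-oriented (corr(E1, GC) ≥ 0). This mirrors standard
practice of phasing eigenvectors with a GC or gene-density track. When the
best |correlation| is inside a ±0.05 dead band the gene-density track is
tried, else the leading eigenvector's sign is kept with a warning — a
documented, deterministic stand-in for manual curation. Bins with |E1|
below 1e-12 are treated as masked. A degenerate leading-eigenvalue tie
(within 1e-9) raises rather than guessing.

Switching between two tracks is measured in bp of unmasked bins at matched
binning, with per-bin joint labels merged into maximal runs; the reported
fraction is (A→B + B→A) bp over all jointly unmasked bp.

## Aggregate chromosomal analysis

Each chromosome arm is linearly rescaled onto half of a 100-pseudo-bin axis
by area-weighted averaging of O/E cells (row-stochastic operators), so the
centromere sits exactly at pseudo-index 50 and flat maps stay exactly flat.
Arm-wise (rather than whole-chromosome) rescaling was chosen so centrality
holds under arm asymmetry. Scores divide window means by the background
(the aggregate minus centromere and telomere windows): the centromere score
uses the central 5×5 window, the telomere score the four 5×5 corners, and
the arm-alignment score the main-diagonal band with those windows excluded.
Configuration thresholds τ_c = τ_r = 1.5 (≥50% enrichment over background)
call clustered-non-Rabl, Rabl-like, or dispersed; the Rabl band passes
through the centromere window by construction, so a Rabl map lifts the
centromere score with the band — classification gives arm alignment
precedence.

The region-to-telomere test scores a region as its mean trans O/E against
telomere bins of other chromosomes, compared with matched-length controls
(supplied — e.g. other heterochromatic domains — or random placements), with
the add-one empirical p so p is never zero.

## Insulation and the TAD verdict

The insulation score of a bin is log2 of its w×w diamond mean (upstream
rows × downstream columns, w = 100 kb default) over the chromosome's mean
diamond value; it is defined only where the diamond fits. Boundaries are
local minima with prominence ≥ 0.5 log2, where prominence is the smaller
flanking maximum within one window minus the minimum; a plateau of equal
minima yields one boundary at its first bin.

A strongly compartmentalized genome dips at every A|B transition without
having TADs, so the genome-level verdict counts only *strong* boundaries
(prominence ≥ 1.0 log2, i.e. contact halving) that do not coincide (±1 bin)
with a compartment border, and calls "no conspicuous TADs" below 1 strong
boundary per Mb. This quantitative rule is an explicit stand-in for visual
map inspection and is surfaced as such in reports. Region insulation
contrast divides within-region O/E by region×flank O/E (equal-width flanks,
falling back to the available flank at chromosome edges, with a warning);
O/E rather than raw counts removes the decay confound. Because the expected
profile itself absorbs part of a large domain's attenuation, a planted
cross-boundary factor δ is recovered as a contrast somewhat below 1/δ
(≈3–3.5 for δ = 0.25 on the bundled genomes).

## Centromeres and telomeres

Hi-C centromere localization iterates c_i ← argmax_b Σ_{j≠i} trans
O/E(b, c_j) from each chromosome's maximal total-trans bin to a fixed point
(≤50 rounds, ties to the lowest index). Two estimator details matter at
realistic depth: (i) telomeres also cluster and form a competing attractor,
so candidates exclude 200 kb at each chromosome end — centromeres are
interior by definition; (ii) single trans cells hold few counts, so the O/E
map is box-smoothed (7 bins, about half the expected width of the
centromeric cluster region) before the argmax, and the final call is the
enrichment-weighted centroid of the peak neighborhood, all centroids taken
against the unrefined fixed point. With smoothing disabled the operation is
the exact cellwise update and matches brute-force search on small
instances. Calls whose score is below 1.2× the background trans level are
flagged "no enrichment".

Repeat families are called centromeric when ≥90% of genome-wide copies (by
midpoint) fall inside the candidate windows (default ±200 kb around the
Hi-C calls, closing the loop between the two methods) and every windowed
chromosome carries ≥1 windowed copy; families rank by specificity × copy
count. Centromere spans run from the first to the last copy of the selected
families; composition resolves overlaps with precedence selected families >
tandem > other interspersed (merged coverage, so the three fractions sum to
≤1), and reports span GC against the genome-wide complement plus
overlapping gene counts.

Telomeric tracts are ≥5 exact tandem copies of the motif (TTAGGG; its
reverse complement CCCTAA at 5′ ends) beginning within 2 kb of a chromosome
end. Both thresholds are explicit configuration — reported alongside the
summary — because "fully resolved" has no universal definition; a
chromosome is telomere-to-telomere when both ends carry tracts.

## Integration statistics

Features map to the compartment of the bin containing their midpoint
(majority-overlap is available as an alternative). Group comparisons use
the two-sample Wilcoxon rank-sum test: exact enumeration when n₁+n₂ ≤ 12
without ties, otherwise the normal approximation with tie and continuity
corrections; fully tied samples return p = 1. Sex-biased genes require
padj ≤ 0.01 and |log2FC| ≥ 1 (log2FC oriented male-high); differential
expression statistics are consumed from a table, never fitted here. The
SBG × switching association is a plain Pearson chi-square (no Yates
correction, df = 1; Yates available by flag) on the gene-level 2×2 table,
raising when any expected cell is below 1.

## The synthetic generator

The generator is the package's study-condition definition, not a fixture:
4 chromosomes × 2 Mb at 10 kb bins; cis intensity |i−j|^−α with α = 0.9;
alternating 200 kb compartment blocks with f_AA = f_BB = 1.6, f_AB = 0.7;
5% trans contacts; centromere boost β_c = 5 and telomere boost β_t = 3; one
400 kb insulated domain (δ = 0.3) on chr4 with an optional telomere-contact
boost β_q; an optional Rabl band β_r; Poisson counts scaled to the target
depth, fully reproducible from the seed. Compartment and insulation factors
are applied as O/E-space deviations — each cis diagonal is renormalized to
the pure decay law — because compartments are by definition structure in
O/E; without this the checkerboard would bias the fitted decay exponent.

Geometry choices: boosted centromere regions are 140 kb and telomere
regions 120 kb wide, sized so a planted cluster fully covers the default
5-pseudo-bin ACA scoring window on every chromosome despite arm asymmetry
(centromeres sit at 0.45–0.55 of chromosome length); the insulated domain
is placed off the 200 kb compartment grid so its boundaries are its own and
not compartment transitions. Matched tracks plant GC at 0.55/0.50 (σ 0.01)
for A/B bins, expression with an A−B shift of 1.5 in log2(TPM+1),
activation-mark peaks A-shifted and a repressive-mark analog B-shifted, a
10% SBG fraction with padj and log2FC drawn clear of the thresholds, a
centromere-confined retrotransposon family (plus a degraded second family
and scattered background families), and chromosome sequences with (TTAGGG)₃₀
tracts at a fixed plan of ends (2 chromosomes telomere-to-telomere, one
5′-only, one bare).

What passing the benchmark shows: the estimators recover their planted
parameters at desk-scale depth (10⁶ contacts) — IDE within ±0.05,
compartment labels ≥95%, centromere calls within ±1 bin, insulated
boundaries within ±1 bin, clustering scores within ±20% — and the empirical
tests are calibrated under the null. What it does not show: robustness to
unequal chromosome lengths and copy-number variation, restriction-fragment
artifacts, mapping biases beyond Poisson noise (no overdispersion by
default), assembly errors, or repeat-family misannotation. Trans contacts
carry no compartment preference under the default law, so trans-mode
compartment calling is validated on constructed checkerboards and via an
optional trans compartment factor, while the recovery benchmark uses cis
mode.

## Problem sizes and runtime

Default analyses run on 800-bin genomes: a full pipeline pass (simulate →
balance → decay → compartments → ACA → insulation → annotation →
integration) takes a few seconds on one CPU, the full test suite about
three minutes, and the acceptance script about half a minute. Five seeds at
depth 10⁶ are the standard replicate set; null calibrations use 10–200
replicates depending on the cost per replicate.
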