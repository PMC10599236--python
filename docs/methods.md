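# Methods

## Scope and data model

All analyses are intra-chromosomal. Contact matrices are dense,
symmetric, non-negative raw counts at a fixed bin size, one matrix per
chromosome, read from upper-triangle COO text. Genomic features use
0-based half-open coordinates internally (GFF3 is converted on read;
SNP tables carry 1-based positions, so a SNP at position *p* lies in
element [s, e) iff s ≤ p−1 < e). Overlap everywhere means ≥ 1 bp.

## Balancing and expected models

Matrix balancing is iterative correction: bins whose marginal falls
below the 0.02 quantile (lower order statistic) of the nonzero
marginals are masked, then per-bin weights are updated by
w ← w / sqrt(marginal/mean) until the coefficient of variation of the
balanced marginals drops below 1e-5 (max 200 sweeps; the square-root
damping reaches the same fixed point as the plain update but without
oscillation). Weights are rescaled so the balanced matrix keeps the raw
total, which makes balancing idempotent in the testable sense
(re-balancing returns unit weights).

The distance-decay expectation is the mean balanced value per
bin-separation over valid pixel pairs; O/E divides by it with a 1e-10
floor (floored pixels come out implausibly large and are excluded from
loop statistics by the candidate filters).

## Compartments

PC1 is the leading eigenvector of the column-centered Pearson
correlation matrix of the O/E map, computed per chromosome, unit norm.
Correlation-of-O/E (rather than PCA of O/E directly) is used because
the correlation step sharpens the plaid into a two-community structure
and makes the eigenvector insensitive to residual distance effects.
The eigenvector sign is arbitrary, so it is oriented against per-bin
gene density: if the Pearson correlation is negative the vector is
negated; gene density is the discriminator because A compartments are
operationally the gene-rich, active fraction. Bins with pc1 = 0 inherit
the previous bin's label. Segments are maximal same-label runs over
valid bins (masked bins break runs); genes are assigned to the
compartment of their midpoint bin, with a midpoint on a bin edge
belonging to the right bin under the half-open convention.

## TADs

The insulation score at bin *i* with window *w* = 5 bins is
log2(diamond mean / chromosome-wide mean diamond), where the diamond is
rows [i−w, i) × columns (i, i+w] of the balanced matrix; scores are
undefined within *w* bins of the ends and wherever the diamond is fully
masked. Boundaries are local minima with topographic prominence
≥ 0.1 (plateaus resolve to their left edge). TADs tile consecutive
boundaries, chromosome ends included, discarding intervals shorter than
3 bins. Multi-resolution calling sum-pools the raw counts, re-balances
and re-calls; finer resolutions resolve at least as many domains.

TAD epigenetic clustering z-scores per-TAD track means (gene density,
ATAC, H3K27ac, expression, CG/CHG/CHH methylation) and applies Ward
agglomerative clustering with k = 3. Roles are assigned from cluster
mean z-scores — highest mean of the active markers → active; of the
remaining clusters, highest mean methylation → repressive; the rest
intermediate — so the labels are invariant to cluster id numbering and
to marker column order.

## Loops

Candidate pixels span 2 bins to 2 Mb. The local expectation multiplies
the decay expected value by the ratio of observed to expected signal in
a Chebyshev annulus (inner radius 2, outer 5). Significance is the
upper-tail Poisson probability of the raw count with the local
expectation mapped back through the balancing weights, BH-corrected per
chromosome over all candidates. Calls require q ≤ 0.05 and fold
enrichment ≥ 1.75 over the donut and ≥ 1.5 over the lower-left
neighborhood; the same 1.5 threshold also applies to horizontal and
vertical stripe backgrounds through the pixel, which guard against
block-edge artifacts (compartment-plaid corners and TAD corners) where
the annulus mixes enriched and depleted territory. Significant pixels
are merged 8-connected; the representative pixel is the significant
pixel nearest the component centroid (a focal peak lights a block
around the true pixel, and the centroid locates it more accurately than
the maximum), and anchors are that pixel's bins as bp intervals.
One-pixel components are kept only at q ≤ q_threshold/10: with many
true discoveries the step-up threshold admits isolated count-noise
pixels at a rate far above the loop-level error one wants, while true
focal contacts essentially always light a multi-pixel neighborhood.

An anchor is genic iff it overlaps any gene body (strand ignored).
Loops-per-gene counts distinct loops with ≥ 1 anchor on the gene; a
loop with both anchors on the same gene counts once. The expression
trend uses loop-count classes 1, 2–5, 6–10, > 10 with per-class medians
plus a Spearman rank correlation; "multi-loop" selection is strictly
greater than the cutoff (default 10).

## Regulatory elements

Promoter windows are strand-aware 3-kb upstream intervals clipped at
chromosome bounds; the window doubles as the proximal zone, so "distal
intergenic" means no gene-body and no promoter-window overlap. ACR
classification is a strict partition with promoter precedence
(promoter_ACR ≻ other_ACR ≻ distal_ACR). Enhancers are distal-intergenic
H3K27ac peaks; active enhancers additionally overlap an ATAC peak by
≥ 1 bp. Enhancer–gene links are loop-mediated only: an enhancer on one
anchor links to genes whose body *or* promoter window overlaps the
other anchor; enhancer and gene on the same anchor never link. Reported
counts deduplicate anchors by coordinates and genes by id.

Meta-profiles: TSS profiles average strand-oriented depth at ±2 kb of
each TSS at track resolution; peak profiles rescale bodies to 100
positions (flanks unscaled) and report body versus flank means, which
carries the methylation-dip contrast.

Differential accessibility scales per-peak read totals to CPM and flags
peaks with |log2((cpm1+0.5)/(cpm2+0.5))| ≥ 1 whose two-sided conditional
binomial test (x1 successes of x1+x2 trials at the library-share rate)
has p < 0.05. The conditional binomial was chosen because it is exact
at low counts with two unreplicated samples.

## SNP densities

Same-class elements are merged before length summation so that
splitting an element into abutting halves cannot change its class
density. Density is unique SNPs per merged kb; enrichment divides by
the genome-wide density (total SNPs / genome kb), making the
whole-genome class's self-enrichment exactly 1.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at a scale where full runs take seconds: 2 chromosomes × 5 Mb at 25-kb
bins (200 bins each). Defaults are the study conditions used by the
tests and the acceptance script.

* **Compartments**: deterministic layout — A in the outer 20% of each
  chromosome arm (telomeric), B across the middle — so positional
  properties are exactly assertable. Contacts multiply a plaid factor
  1 ± 0.3 by compartment agreement.
* **Decay**: E[i,j] ∝ (1+d)^−α with α = 0.7, a sub-unity power law
  typical of the 0.1–1 Mb regime; coverage_scale 50 sets the diagonal
  scale.
* **TADs**: boundaries every ~20 bins with seeded jitter, contrast 1.5
  within domains. Boundaries avoid bins whose insulation diamond would
  intersect a planted loop block, so every planted boundary remains
  recoverable — loop corner signal would otherwise fill the insulation
  valley.
* **Loops**: 25 pixels per chromosome — three "hub" fans of 6/4/3 loops
  anchored at hub genes plus 12 isolated pixels — each multiplying the
  3×3 neighborhood by strength 3. Planted pixels keep pairwise
  Chebyshev distance ≥ 4 (so called components stay separable at ±1
  pixel), alternate row/column fan sides with 8-bin within-side spacing
  (so no block sits inside another pixel's stripe background), and each
  fan stays inside one compartment block (a fan crossing the A/B
  transition would sit in mixed donut backgrounds by construction).
  Hub distances run 4–24 bins, placing all loops within 600 kb and
  most within 400 kb, matching the short-range bias of real loop sets.
  The largest plantable loops-per-gene class under these separability
  constraints is 6–10; the > 10 class is exercised by unit tests on
  constructed profiles.
* **Genes**: quota allocation per bin with A:B weight 5:1 (ties in the
  largest-remainder step broken by a seeded shuffle so leftovers spread
  evenly); hub bins carry a hub gene plus two satellites so each planted
  loop-count class holds several genes and its median is stable.
  Expression is log-normal: log TPM = 1 + 1.2·log1p(loops-per-gene)
  + 0.7·[has promoter ACR] + N(0, 0.3).
* **Peaks and depth**: promoter ACRs (600 bp, upstream of a seeded half
  of genes), 600-bp gene-body ACRs, distal ATAC peaks under every 4th
  enhancer (active fraction exactly 25%), H3K27ac enhancer peaks
  1.2–2.4 kb (longer than ATAC by construction) placed in intergenic
  gaps. Depth tracks at 100-bp steps are Poisson around rectangular
  peak signal plus a Gaussian TSS accessibility bump; the designated
  differential gene carries two peaks (gene body 3' half and upstream)
  at 4× height in sample 1 versus sample 2, with the body peak placed
  clear of the TSS bump the two samples share.
* **Methylation**: Beta-distributed per 200-bp unit (concentration 30)
  with context/compartment means CG 0.55/0.80, CHG 0.35/0.65,
  CHH 0.22/0.08 (A/B), times a 0.3 dip factor inside peak bodies —
  bounded in [0,1] with tunable contrast.
* **SNPs**: 2500 SNPs; each falls inside the merged promoter+enhancer
  element set with probability f·L/G (f = 20 planted enrichment,
  L element length, G genome length), uniform within the chosen
  territory. Under this rate model the measured density enrichment is
  unbiased at f regardless of the element footprint.
* **Determinism**: each output layer draws from its own RNG stream
  (seed + layer index); a fixed seed yields byte-identical files.

What the generator does **not** emulate: read-level noise and mapping
artifacts, inter-chromosomal contacts, nested/hierarchical domains,
diploid genotypes, replicate structure, or realistic peak-shape
heterogeneity. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative
assumptions, not performance on real libraries.

## Problem sizes

Tests and the acceptance script use the default 2×5 Mb genome: five
seeded datasets for recovery rates, twenty single-chromosome null
matrices (no plaid, no TADs, no loops) for false-discovery control,
and ten replicate datasets for the differential-accessibility
contrast — chosen so the whole suite runs in well under a minute while
every rate is estimated from ≥ 96 planted boundaries, 250 planted
loops, and ~2000 valid bins.

## Known limitations

* The donut caller is single-resolution and omits reference-tool
  refinements such as λ-chunked FDR and Knight–Ruiz balancing.
* Compartment calling is two-state; no sub-compartments.
* The insulation caller reports boundary bins, not boundary intervals,
  and multi-resolution results are independent calls, not a merged
  hierarchy.
* Enhancer definition inherits the promoter-window convention; there is
  no separate distance cutoff for "distal".
* With two unreplicated samples the differential-accessibility test
  controls only count noise, not biological variability.
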