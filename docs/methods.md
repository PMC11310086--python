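# Methods

This note documents the models, statistics and numerical choices behind
`regenomics`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several constructions
were defensible.

## Time-course clustering

**TMM normalisation.** Between-sample factors follow the de-facto
standard trimmed-mean-of-M-values construction: the reference sample is
the one whose 75th-percentile count proportion is closest to the mean
across samples; for each sample, M = log2 ratio and A = mean log2
abundance of gene *proportions* are computed over genes positive in
both libraries, the 30% most extreme M and 5% most extreme A are
trimmed by rank, and the factor is 2^(weighted mean M) with weights the
inverse delta-method variance of M; factors are geometric-mean centred.
Normalised values are value/(library·factor)·10⁶. Two caveats are
deliberate properties of this definition: (i) scaling a library by a
constant leaves M untouched but perturbs the count-based weights, so
factors are only *approximately* scale-invariant (drift ≲0.03 on
100-gene tables); (ii) TMM presumes a majority of non-regulated genes —
on simulated data where *every* gene is stage-regulated the factors
absorb real composition shifts, which is why the analysis drivers
cluster the abundance-scale matrices directly and use the count layer
only to exercise normalisation.

**Transform and fuzzy c-means.** Profiles are log2(x+1)-transformed and
per-gene standardised (zero-variance genes dropped and reported).
Soft clustering minimises Σᵢⱼ uᵢⱼᵐ‖xᵢ−cⱼ‖² by alternating membership
and centroid updates until the largest centroid shift is below 1e-6
(cap 1000 iterations; non-convergence returns the best state flagged).
The fuzzifier defaults to m = 1.25, a conventional choice for
standardised expression profiles. Initial centroids come from
k-means++ seeding: uniform random initial picks were observed to strand
the optimiser in poor local optima even on well-separated data, while
k-means++ makes recovery reliable and stays deterministic given the
seed. Membership ties and argmax ties resolve to the lowest cluster
index. Two limit behaviours worth knowing: as m grows, memberships
flatten toward 1/C but never reach it exactly (FCM fixed points keep
centroids attached to the data; deviation ≈0.08 at m = 10 on typical
standardised profiles), and at extreme m degenerate fixed points pin
single profiles to centroids.

**Cluster number.** D_min(C), the minimum pairwise centroid distance,
is computed over a contiguous range; past the true cluster count
centroids begin to split real clusters and D_min collapses. The
selected C is the knee: the C immediately preceding the largest drop
D_min(C) − D_min(C+1), ties toward larger C (the raw second difference
peaks one position *past* the knee on a flat-drop-flat curve, so the
drop form is used). The full curve is always returned for inspection
and manual override — with heavily overlapping adjacent templates the
knee underestimates, as the analysis drivers illustrate.

**Major clusters.** Clusters are ordered by onset (first sample whose
centroid exceeds 0 in standardised units; ties by peak sample, then
index). A cluster is *major* iff it has more than one enriched term at
FDR < 0.05 and its centroid exceeds the threshold in more than one
regenerating sample. The onset threshold (0) and α are configurable.

## Homology

Reciprocal best hits keep a pair iff each gene is the other's unique
best-scoring target; ties for best are discarded entirely, preserving
strict one-to-one semantics. Family retention for a species pair keeps
families with between 1 and 4 members in *each* species (both bounds
configurable; the lower bound is set to "present" rather than ">1"
because cross-species overlap counting needs single-copy families, and
typical family-size distributions make a 2-gene minimum implausibly
restrictive). Phylostrata: a focal gene's age is the most ancient of
the MRCAs between the focal species and each other species in its
family — equivalently, the MRCA of the family's species set on the
focal root path; focal-only families are lineage-specific. Internal
node labels on the focal path name the strata.

## Conservation statistic

For species pair (1, 2) with filtered families, the observed statistic
for cluster pair (i, j) counts species-1 genes in cluster i having at
least one family member assigned to cluster j in species 2; each
species-1 gene contributes at most once per cell. Soft memberships are
ignored (counting is over hard assignments), and the focal species is
species 1 by convention — both directions are computable by swapping
arguments.

The null permutes the species-2 cluster-label vector over the clustered
species-2 genes: cluster sizes are preserved exactly and the family
incidence structure is untouched, so the null answers "how many shared
genes would these two cluster sets show if species-2 membership were
random given the same family topology". With N replicates the empirical
p-value is the mid-p estimate

    p = (#{null > obs} + 0.5·#{null = obs} + 1) / (N + 1).

The count statistic is discrete with substantial ties; the conventional
#{null ≥ obs} rule is then systematically conservative (measured null
rejection ~0.024 at nominal 0.05), while the strict #{null > obs} rule
is anti-conservative in the KS sense. The mid-p estimator splits the
tie mass and restores uniformity on the attainable grid (KS p ≈ 0.5–0.97,
rejection 0.034–0.056 across independent 20-seed calibration blocks);
the smallest attainable p remains 1/(N+1), and the +1 retains the
standard bias guard. BH correction runs across all C₁×C₂ cells of one
comparison (not pooled across species pairs). Defaults: N = 10,000,
α = 0.05.

Three-way consistency declares a focal cluster consistent iff it sits
in ≥1 significant pair in both pairwise comparisons, and intersects the
conserved gene lists. The homology breakdown partitions conserved genes
into no-homologue / divergent-expression / also-conserved by family
presence and significance in the third species. The heterochrony screen
reports Kendall's tau over the temporal ranks of significant pairs and
flags the pairs whose removal most increases tau; it is a report, not a
test.

## Enrichment

One-sided hypergeometric tails (upper for enrichment, lower for
depletion; two-sided tests are deliberately not offered), BH within
each foreground's test family — matching the per-panel FDR < 0.05
convention. Terms with fewer than 3 annotated background entities are
skipped and reported (configurable). Annotation propagation to families
is the union of member-gene terms, optionally restricted to a species
subset, and is idempotent. Gene-age and curated-list wrappers test each
cluster against all clustered genes, or against an explicit
conservation-aware background.

## Karyotype evolution

Painting tests every (chromosome, ALG) cell among labeled genes with
the one-sided Fisher exact test (computed as the hypergeometric upper
tail of the 2×2 margin), BH across all cells, assignment at
p_adj < 10⁻⁵. Joins — pairs of reference ALGs co-assigned to one
chromosome — are binary characters placed by Dollo parsimony (single
gain at the MRCA of the taxa showing the join, losses free; fusions are
essentially never exactly reversed, and the outgroup-based argument for
ancestral states is exactly this logic). Joins gained at or above the
ingroup ancestor merge their ALGs into ancestral units; younger joins
become fusion events on their gain branch. Event counting builds the
bipartite ALG–chromosome graph from significant assignments; a
connected component with a ALGs and c chromosomes costs (a−1)+(c−1)
events — the minimum fusion+fission explanation. An optional
translocation mode counts a fully connected 2×2 component as one
reciprocal translocation; by default such a component costs 2, so
counted events can exceed the logged history when translocations are
simulated. Rates are events divided by branch time in Myr, reported to
3 significant figures (the 500 Myr class-divergence default is
configurable). Synteny ribbons follow circos-bundlelinks semantics:
links sorted along genome 1, merged while consecutive links are within
50 ordinals on both genomes, bundles with <3 links dropped.

## Repeats

Ages assume the family consensus approximates the ancestral sequence
and copies decay at the neutral rate r, so t = d/r (d a fraction,
r = 1.885×10⁻⁹/bp/year default): 2% → 10.6 Myr, 20% → ≈106 Myr. The
halved alternative t = d/(2r) is rejected because the consensus, not a
diverging sister copy, is the comparison point. Landscapes stack genome
coverage per 1% divergence bin by repeat class (overlaps double-counted
by default; a merge option exists). Region expansion uses the exact
binomial tail P(X ≥ k), X ~ Bin(n, region/genome), per family with BH.
Breakpoint association counts copies intersecting any breakpoint ±10 kb
(window configurable) and compares with N uniform re-placements of the
family's copies (lengths preserved) via the (r+1)/(N+1) estimator and
BH; these two constructions are explicit stand-ins at the stated
significance thresholds, since only the thresholds are fixed by
convention. Copies shorter than 50 bp are ignored by the expansion
test. The differential-activity filter retains |log2FC| > 1 (strict)
and p_adj < 0.001.

## Explant contrasts

DEG retention is p_adj < 0.05 and |log2FC| strictly > 1 per contrast
(raw p can be BH-adjusted on request). Categorisation at one timepoint:
distal-specific, proximal-specific, shared (same direction) or opposite
(up in one segment, down in the other); the four categories partition
the DEG union. Shared/opposite status is evaluated per timepoint, not
across timepoints. DEG–cluster enrichment reuses the hypergeometric
machinery with all clustered genes as background and BH within each DEG
set.

## Synthetic data

One integer seed drives everything; per-stage substreams are derived
from it (offsets 0–3 for time course, karyotype, annotations,
repeats/DEGs) so stages rerun independently and identical config + seed
reproduce identical tables.

*Time courses.* Cluster templates are Gaussian bumps over the ordered
stage index (evenly spaced peaks, width 1.5 stages) — matching the
unimodal shapes of regeneration co-expression centroids without extra
structure. A gene's profile is its template plus N(0, σ) noise, clipped
at zero, scaled by a lognormal abundance (median 50, log-sd 1); the
count layer is Poisson around the abundance scaled by a per-sample
depth in [0.5, 2]. Families (default 500) draw per-species sizes
uniformly from 1–4 (satisfying the retention filter by construction); a
fraction ρ of families is conserved — all members in all species take
the family's template cluster — and the rest assign clusters per gene
independently. The default sampling design is one non-regenerating
control plus seven regenerating stages. What is *not* emulated: a
stable (non-regulated) background transcriptome, count overdispersion
beyond Poisson, batch structure, and dropout — so passing recovery
tests certify the statistics, not robustness to those real-data
features; in particular TMM behaves atypically here (see above).

*Karyotypes.* The ancestor has 20 chromosomes × 100 genes (one ALG
each). Along each branch, Poisson(rate × length) events are drawn:
fusions concatenate two chromosomes, fissions split one, reciprocal
translocations exchange terminal segments; a fusion drawn on a
one-chromosome genome is resampled and logged. Cut positions are
uniform over positions leaving at least 25 genes of every ALG on each
side (block boundaries always allowed): fully uniform cuts routinely
strand 5–20-gene minority blocks that no Fisher test can assign at
p_adj < 10⁻⁵, which would make exact recovery of the planted history
impossible by construction rather than by statistical failure. With
this constraint, event-count recovery was exact in 90/90
fusion/fission histories.

*Annotations and ages.* Term membership is Bernoulli with background
prevalence 10%; a planted (term, cluster) pair multiplies the odds by
θ (default 10). Ages plant a stratum per gene (uniform over six strata
unless tilted by θ in a planted cluster) and emit a family table
containing exactly the witness species certifying that stratum on a
fixed six-leaf tree, so the tree-walk recovers planted ages exactly.

*Repeats and DEGs.* A 1 Mb region carries 3 breakpoints and 10 repeat
families × 200 copies (lengths 100–1000 bp); the associated family
places a fraction π = 0.9 of copies within ±10 kb of a breakpoint,
everything else is uniform. DEG truth assigns categories
shared/opposite/distal-only/proximal-only/null (10/5/20/5/60%),
realised as log2FC draws at ±3 with normal error 0.5 and Wald-type
p-values; opposite genes get opposing distal/proximal signs by
construction.

## Problem sizes and determinism

The shipped analyses and test suites run at deliberately modest sizes —
two species, ~1300 genes each, 500 families, N = 1,000–10,000
permutations, 10–20 seeds per calibration — chosen so each suite
completes in seconds to a couple of minutes while leaving the planted
effects comfortably detectable. All stochastic components consume
numpy Generator streams derived from explicit seeds; reruns are
byte-identical.

## Known limitations

* The conservation test conditions on hard cluster assignments;
  uncertainty in the clustering itself is not propagated.
* Dollo parsimony cannot separate two independent identical joins on
  sister lineages from one ancestral join (the usual homoplasy
  caveat); with more taxa the risk shrinks.
* Event counting reports the minimum fusion+fission explanation, a
  lower bound on the true event number when histories are wasteful,
  and over-counts reciprocal translocations unless translocation mode
  is enabled.
* The repeat region tests treat copies as independently placed;
  clustered insertion processes other than the planted breakpoint
  attraction are not modelled.
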