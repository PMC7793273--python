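# Methods

## The co-association statistic

Two ChIP-seq peak sets are compared on their summits. The ordered overlap
count k is the number of summits of set *a* with at least one summit of set
*b* within 150 bp (each *a* summit counted once; the window is inclusive,
|distance| ≤ 150). Both directions are always reported as shares k/nₐ and
k_b/n_b.

The null model treats the genome as N equally likely accessible slots —
150 bp DNase-hypersensitive regions, N = 250,000 by default — so the
expected overlap of two independent sets is λ = nₐ·n_b/N. Significance is
the Poisson tail: P(X ≥ k) when k ≥ λ, P(X ≤ k) otherwise, with the final
score negated in the depleted case to distinguish avoidance from
co-binding. P-values are Bonferroni corrected over the number of ordered
pairs evaluated in the run (recorded in output metadata) and reported as
−log₁₀ p. Before the logarithm the corrected p is clamped below at the
smallest positive subnormal double (≈ 4.94e−324), which caps the score at
323.31; tables report the integer 323. The significance call is strict:
score > 100 and anchor share > 10%.

The anchored mode restricts both sets to summits within the window of an
anchor set (NF-YB) and uses the anchor's peak count as N. An empty
restriction yields a degenerate result (k = 0, score 0, flagged) rather
than an error.

Score matrices are clustered hierarchically with distance 1 − Pearson
correlation between rows and **centroid** linkage. Centroid linkage on a
correlation distance is not geometrically well-founded; it is implemented
as stated because it is the procedure the scores are defined for, and
average linkage is available via the `method` argument. Constant rows carry
no correlation signal and are dropped with a warning; rows are pre-sorted
by factor name so leaf order is reproducible.

## Motif enrichment

Windows are 150 bp, summit-centered, matching the overlap window. Each
window is scanned on both strands with log-odds scores against the
background base composition (uniform by default); a pseudocount of 1% of
the column total avoids −∞ on zero counts. Scores are min-max normalized
per matrix so the consensus scores exactly 1.0 and the anti-consensus 0.0.
Ties between equally scoring positions (identical k-mers recur inside a
150 bp window often enough to matter) are broken by a deterministic dither
keyed on the window content: reproducible across runs and call orders, but
without the 5′ positional bias a first-position argmax would introduce.

The *global* test asks whether the mean best score in peak windows exceeds
the mean over accessible-region background windows: a one-sided z-test on
the mean using the background variance, with an exact permutation
alternative when a full background sample is available. The *local* test is
a one-sided paired t-test of the central window's best score against the
mean of the two immediately flanking windows. Both use the 1e−10
significance threshold. These tests are reconstructions of the published
global/local semantics, not re-implementations of any specific tool's
internal statistic.

CCAAT classification: *global primary* if the CCAAT matrix is globally
significant and top-ranked among all matrices tested for that factor,
*global secondary* if significant but outranked, *local only* if only the
flank test is significant, *none* otherwise. The CCAAT matrix is identified
by its id (default `MA0060.1`); the middle A used as the positional
reference point is located by finding the CCAAT pentanucleotide in the
matrix consensus and taking its third base, so other CCAAT matrices can be
swapped in.

## Positional bias

In co-bound regions the best CCAAT hit is located; regions whose best
CCAAT match falls below normalized score 0.8 are excluded and counted. The
signed distance is (TF motif center) − (middle A), measured on the
CCAAT-defining strand (negative = TF motif 5′ of CCAAT). Motif centers use
the integer convention start + L//2; the synthetic planting code uses the
same convention, so planted offsets are recovered exactly at plant
fraction 1.0.

The non-uniformity test is a chi-square of the observed offset histogram
against a null that places the TF hit uniformly over each region's
*attainable* offset interval given its observed middle-A position
(aggregated over regions, binned so expected counts stay ≥ ~5). Testing
against a uniform over the theoretical window-wide range would be wrong —
most of that range is unattainable once the CCAAT position is fixed — and
over-rejects badly.

## Partner groups

Evaluated in order, with "any cell line" quantifiers except where noted:
Group 1 — global CCAAT enrichment (primary or secondary) and factor share
strictly above 20%; Group 2 — CCAAT enrichment of any class and share in
[5%, 20%] (both boundaries land here, consistent with published boundary
cases at exactly 20% and 17%); Group 3 — CCAAT enrichment with the maximum
share over all cell lines strictly below 5%; Group 4 — no CCAAT enrichment
but anchor share > 10% with score > 100. A factor that fits no rule is
reported unassigned rather than forced. Treated-condition datasets are
classified per dataset, so one factor can legitimately appear in more than
one group across conditions.

## Curation rules

Within each (factor, cell line) group: treated experiments are split to a
side channel; tagged-antibody entries are dropped when an untagged one
exists; replicates with fewer than 10,000 peaks or fewer than half the
peaks of the next-larger replicate are dropped as minima; the surviving
group is kept only if some pair exceeds 66% concordance, and then only the
largest member. Concordance is the share of the *smaller* replicate's
summits within 150 bp of the larger's — the most conservative symmetric
choice, and the same metric as the co-association count. Singleton
experiments enter the pipeline directly. Every drop carries a
machine-readable reason, and curation is idempotent.

## Downstream annotation

Summits are assigned to the half-open 200 bp segment containing them; a
summit exactly on a boundary belongs to the right-hand segment.
Promoter windows are inclusive on both ends, strand-mirrored for minus
genes: (−1000, +100) for pathway target assignment, (−450, +50) for
proximal TFBS work. Pathway over-representation is a one-sided
hypergeometric upper tail per pathway over the annotated-gene universe
(configurable). Pathway rows are kept when some factor's p < 1e−5 and the
pathway background is ≤ 200 genes; rows whose contributing gene sets are
identical merge into the most general one, defined as the largest
background (ties broken lexicographically) with merged ids retained for
audit. The filter/merge step is order-independent.

DEGs are partitioned at FDR < 0.01 and |log₂FC| > 1, strict inequalities.
Pairwise co-regulation uses a two-sided Fisher exact test (point-
probability method) on the 2×2 of target-set membership within the state's
DEG universe; the state-restricted universe is the reading most consistent
with "genes regulated by the single factor", and a whole-annotation
universe is available via the `universe` argument. The −log₁₀ p matrices
reuse the same clamp and clustering as co-association.

## The synthetic-data generator

The generator emulates exactly the structure the statistics assume — and
no more. A genome is a set of chromosomes with disjoint 150 bp accessible
regions placed uniformly at random. Peak summits occupy accessible-region
centers with uniform ±50 bp jitter (jitter differences stay ≤ 100 bp, so
planted pairs always satisfy the 150 bp rule while avoiding exact
coincidence); planted pairwise fractions are realized by co-locating the
stated fraction of one factor's peaks in regions occupied by the other,
with the remainder placed uniformly — so measured shares equal the planted
fraction plus the binomial chance term (1−f)·nₐ/N. Sequences are i.i.d.
uniform A/C/G/T (GC configurable); motif plants write the CCAAT consensus
with its middle A at the region center and the partner consensus at the
stated signed offset and orientation. DEG tables plant exact UP/DOWN
counts with generated FDR/log₂FC values safely inside or outside the
thresholds, plus per-factor target sets with planted pairwise overlaps.
One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`; everything is reproducible bit for bit.

What the generator does **not** emulate: read-level noise, fragment-size
effects, peak-width and signal heterogeneity, sequence composition bias,
nucleosome or accessibility biophysics, correlated motif grammar beyond
the single planted pair, or realistic pathway structure. Passing tests
therefore demonstrate that the statistics recover what they are defined to
measure under their own null, not that the pipeline is robust to every
artifact of real ChIP-seq data.

One geometric limitation: a partner consensus cannot be planted with its
center closer than about 10 bp to the CCAAT middle A, because writing both
consensus sequences would overwrite one another (the CCAAT matrix is 16 bp
wide). Overlapping motif geometries exist in nature through compatible
sequences; consensus-writing cannot produce them, so planted-offset
validation covers |offset| ≥ 10 — which includes the −10/−11/−12
archetypes that matter.

## The demo's study conditions

The demo uses three synthetic cell lines, each with 40,000 accessible
regions on two 4 Mb chromosomes, an NF-YB-like anchor and twelve partner
factors of 600 peaks each: anchor-overlap fractions 0.5 (Group 1
archetypes), 0.12 (Group 2), 0.0 (Group 3, chance overlap only ≈ 1.5%),
0.4 (Group 4); CCAAT planted in 90% of the peak regions of Groups 1–3
(excluding any region a Group 4 factor occupies, so Group 4 stays
CCAAT-free); one Group 1 factor carries its own motif at −11 bp. Motif
enrichment for each factor scans the CCAAT matrix plus the factor's own
matrix against a 2,000-region background. These sizes make every planted
effect decisively recoverable while the whole run completes in well under
a minute.

## Numerical choices, in one place

- p-value clamp: smallest positive subnormal double, applied to corrected
  Poisson and Fisher p before −log₁₀; integer score ceiling 323.
- Window inclusivity: |summit distance| ≤ 150.
- Missing narrowPeak summit offset (−1): interval midpoint, floored.
- PWM pseudocount: 0.01 × column total, per cell.
- Minimum CCAAT match for positional bias: 0.8 normalized (configurable).
- Tie-breaks: PWM scan ties by content-keyed dither; clustering leaf order
  by factor-name pre-sort; pathway-merge ties lexicographic.
- Calibration-check sizes (chosen for near-continuous null p support):
  Fisher on 500-gene sets in a 2,000-gene universe; enrichment on 120 peak
  vs 1,000 background windows.
- Chromosome names are matched exactly; no "chr" aliasing unless enabled.
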