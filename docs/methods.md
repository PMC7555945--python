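# Methods

This note records the models, conventions and design choices behind `bstk`,
in the order the analysis stages run.

## Ontology handling

The GO DAG is read from OBO 1.2/1.4 (via `obonet`) into a child→parent
directed acyclic graph; obsolete terms are dropped and `alt_id`s resolve to
their primary ids. Annotation counting follows the true-path rule: a gene
annotated to a term is annotated to every ancestor, so `propagate_annotations`
closes each gene's term set under ancestry before counts are taken.
Propagation follows `is_a` edges only by default — `part_of` crosses
namespace and granularity boundaries in ways that change counts
qualitatively — but the relation set is a parameter.

Term *level* is the minimum number of parent edges to the namespace root
(root = 0); minimum depth is the conventional meaning of "GO level" and is
well defined on a DAG, unlike maximum depth, which is unstable under
redundant edges. Descendant counts are sizes of the transitive in-closure.
Both are reported per term and back a generic-term filter (drop levels < 4);
neither enters the enrichment p-value itself.

## The pooled enrichment test (MSGEA)

Counting basis: gene–term pairs after propagation, so `n_s = Σ_go n_go,s`
and `N_s = Σ_go N_go,s` hold identically (a raw-annotation mode exists for
sensitivity checks). Terms are tested if they occur in any species' study
set; a species whose genome lacks a term contributes zero to the score and
is excluded from the null for that term — an absent term carries no
information, and erroring would discard the remaining species' signal.

The score standardises each species' count by a Poisson approximation to
the SD, exactly as defined; the null, however, uses true hypergeometric
PMFs. The exact p-value enumerates the joint support (product of
per-species supports) and sums product-PMF weights over outcomes whose
summed score reaches the observed one. Outcomes tied with the observed
score within 1e−12 are counted in the tail; this tie rule is what makes the
single-species case collapse exactly onto the one-tailed Fisher exact test
(the score is strictly increasing in the count, so the tail is
`{m ≥ m_obs}`). Enumeration is refused above a configurable joint-support
ceiling (default 1e7); Monte Carlo sampling with an explicit seed is the
fallback, using the add-one estimator `(hits + 1)/(draws + 1)` so p is
never 0. Only over-representation (upper tail) is tested.

Benjamini–Hochberg adjustment is applied to the pooled p-values as one
family; each species' single-species Fisher column is adjusted separately.
The multi-only/single-only/both cross-tabulation is computed at raw
p < alpha by default (an adjusted-value option exists).

## Cluster-set classification

The species tree is rooted, with three clade labels (Deuterostomia,
Ecdysozoa, Lophotrochozoa) and an exempt set (default *A. californica*,
whose sparse annotation would otherwise dominate loss counts). Loss
counting is Dollo: a single gain at the root, and the minimum number of
losses equals the number of maximal subtrees whose non-exempt leaves are
all absent. Exempt leaves are pruned before counting, so their absence is
never charged as a loss; this is required for set A ("all species except
possibly the exempt one") and is consistent with the exempt species'
near-absence from the stricter sets. Set L requires clade coverage (as in
C) plus at most one loss; set A requires zero losses among non-exempt
species. Exempt species do count toward clade coverage in set C — they are
genuine clade members; only the loss accounting ignores them.

The homology pre-filter discards a query iff it has at least one hit to a
non-bilaterian subject with E-value strictly below 1e−5 ("significant hit
below the threshold"); direction and cutoff are configurable. Top-hit
selection keeps k = 10 hits per (query, taxon), ranked by E-value, then
bit-score, then lexicographic subject id — a fully deterministic order.

Representation summaries report, per species and set, the protein count
(#P), the number of clusters containing the species (#C), the percentage
ratio 100·#C/set size (one decimal), and #P/#C (two decimals); the mean
representation is the mean of the non-exempt species' unrounded ratios,
rounded to one decimal.

## Most Conserved Ortholog selection

Genes are ranked within cluster and species by the fraction of sites whose
conservation score strictly exceeds 0.99 (fraction of strongly constrained
sites tracks conservation of *function*; the average score tracks overall
sequence conservation — the two are highly correlated, and
`conservation_correlation` reports the Pearson r as a QC statistic). Ties
break by higher mean score, then lexicographic gene id, making selection
invariant to member order. Scores are consumed as per-gene site arrays
(TSV/JSON); extracting them from genome-wide tracks and exon coordinates is
out of scope.

## Expression profiles

Normalization is `log10(x + pc) − log10(mean_genes(x + pc))` per stage, so
the genome-wide mean of back-transformed values is 1 at every stage. The
default pseudocount is the smallest positive value in the matrix, applied
only when zeros are present. Stage metadata (order, phase, landmarks, an
exclusion flag for e.g. unused adult stages) is supplied as a config table,
never hard-coded.

Profile enrichment runs two one-sided families per target gene on Pearson
correlations between normalized profiles: a Mann–Whitney test of the
gene's correlations with other target genes against its correlations with
the background, and Fisher exact tests of the 2×2
high-correlation × target-membership table at r thresholds 0.5, 0.7, 0.9.
The target set is excluded from the background comparator (the cleaner
null; including it only dilutes the contrast). BH runs per family and a
profile is *characteristic* if any family is significant at alpha — the
most inclusive of the defensible combination rules; measured under a pure
background, the family-wise false-flag rate stays at the nominal level
because the families are strongly dependent (they summarise the same
correlation vector).

Significant profiles are clustered by complete linkage on 1 − r and cut at
height 0.75, which guarantees max within-cluster distance ≤ 0.75 (asserted
on every output). Cluster mean shapes are computed after centring each
member profile by its own across-stage mean — on the log scale, dividing by
average expression is subtracting the mean — then averaging stage-wise.

## Background sampling

Random backgrounds draw replicate sets of the target's size uniformly
without replacement, 100 replicates by default, recording per-stage mean
normalized expression. Matched-function backgrounds follow a three-step
scheme: per target term occurrence, draw that many random carriers of the
term (without replacement within a term's carrier list); pool the draws
(a gene may recur via different terms); draw the final set of distinct
genes of target size from the pool. If the pool runs out of distinct genes
the set is topped up uniformly from the genome with a warning — this keeps
replicate sets duplicate-free and size-exact.

Age stratification splits genes into "older" (phylostrata 1–6, predating
the focal clade) and "younger" (strata ≥ 8), excluding the clade-specific
candidate genes from both groups; stratum 7 (the clade's own stratum)
belongs to neither. The younger boundary is configurable (`young_min`)
because the stratum-7 assignment is convention-dependent.

## Synthetic data generators

All generators are bit-reproducible under a fixed seed.

*Cluster fixture.* The published set-L presence marginals force the absence
structure completely: 31 clusters lack only *C. elegans*, 3 lack only
*D. melanogaster*, 6 lose the (*A. gambiae*, *D. melanogaster*) cherry as a
single loss event (the only single-loss pattern consistent with the L vs
L′ counts for *A. gambiae*), the remaining single-species absences are leaf
losses, and 32 clusters are complete; the exempt species joins two complete
clusters. The seed only shuffles which cluster ids carry which pattern.
Classification necessarily yields 125 set-L and 85 L′ clusters.

*Enrichment fixture.* Each genome gene carries exactly one term with terms
equally frequent (default: 3 species, genome 1000 genes, 40 terms, study
size 50 — margins small enough for exact enumeration, dense enough that
the discrete null has a rich support). Study sets are drawn uniformly
(fold 1: the per-term count is then exactly hypergeometric, so the test's
null holds by construction) or with sampling odds multiplied by a fold for
planted-term genes (a noncentral-hypergeometric alternative used for power
experiments).

*Expression fixture.* Background genes get i.i.d. standard-normal log10
profiles; planted genes follow unit-amplitude rising/falling/peaked
templates (the peaked template emulates a mid-development, phylotypic-style
expression peak) with additive Gaussian log10 noise, SD 0.25 by default.
The generator emulates the statistical structure the tests assume
(exchangeable background, coherent planted shapes); it does not emulate
real stage counts, autocorrelated developmental dynamics, or
mean–variance coupling of real expression data, so passing tests show the
procedures behave correctly under their own assumptions, not that real
data satisfy those assumptions.

## Numerical conventions and limitations

* Score-tail comparisons use an absolute tolerance of 1e−12; enumeration
  p-values are clipped to [0, 1] against round-off.
* All tabular outputs are TSV with deterministic column and row order;
  identifiers are opaque case-sensitive strings; species tags are declared,
  never inferred.
* The discrete exact test is conservative: its attainable level at a given
  alpha is the largest null tail probability not exceeding alpha, which can
  sit well below alpha for small margins. Calibration checks should compare
  simulated rejection rates against that attainable level, not against
  alpha itself.
* The pooled test assumes a starlike phylogeny (independent per-species
  nulls); applying it to strongly nested clades overstates independence.
* Exact enumeration cost is the product of per-species support sizes;
  beyond the ceiling, Monte Carlo error (binomial SE) applies.
* Problem sizes used in the shipped tests and the acceptance script —
  genome 1000 × 3 species for enrichment simulations, 100–220-gene
  expression matrices, 100–500 replicates — were chosen so the full
  statistical checks run in seconds while leaving the binomial CIs tight
  enough to be informative.
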