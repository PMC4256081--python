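# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the simulator does and does not emulate, and
the numerical details a user needs to interpret or reproduce the outputs.

## Sequence identity

All percent identities are matches / alignment-columns × 100, gaps
included in the denominator, with ambiguous `N` never counted as a match.
Two dialects are used, both deterministic:

* **Global (Needleman–Wunsch)**, via Biopython's `PairwiseAligner`:
  nucleotide scores match +1 / mismatch −1 / gap open −5 / gap extend −1;
  amino acids BLOSUM62 with gap open −11 / extend −1. This is the
  reference definition used for domain and protein comparisons. The value
  is taken from the first optimal alignment in Biopython's traceback
  order; co-optimal alignments can in principle differ slightly in
  identity, which the test suite bounds against an exhaustive-enumeration
  oracle on short sequences.
* **Semi-global placement ("infix")**, via edlib under unit edit costs:
  used where a 1-kb block must be located inside a full cluster sequence.
  This is the blast-like dialect: it is robust to the coordinate shifts
  that any indel whose size is not a multiple of the block size induces
  downstream. A fixed-grid global block-vs-block comparison would lose
  every match downstream of such an indel; placement matching does not.

The thresholds used downstream (70% for block matches, 50% for domain
networks, 45/50/70% for sub-cluster sharing) are only meaningful relative
to this denominator convention, which is why it is fixed package-wide.

## Block-based event calling

Clusters are decomposed into floor(L/1000) consecutive 1-kb blocks
(trailing remainder discarded; blocks are anchored at fixed offsets).
Each block is placed in the partner sequence and in its own cluster (own
span excluded), on both strands; matches are kept above 70% identity and
assigned to the partner block containing the placement midpoint. Pairs
with fewer than three matched blocks are not comparable.

Calls, in precedence order (a block consumed by a duplication call is
excluded from the later analyses, as are its immediate neighbors, which
sit on the copy breakpoint):

1. **Duplication** — maximal contiguous runs of blocks whose cross match
   targets a partner block already claimed by an earlier block and whose
   within-cluster self-match identity exceeds the cross identity (higher
   copy number on one side, copies more similar to each other than to the
   partner's single copy). Detected symmetrically on both sides.
2. **Indel** — maximal runs of unmatched blocks in exactly one cluster,
   flanked on both sides by at least two matched blocks (≥ 2 kb) whose
   targets are in non-decreasing order. Size in kb = run length. A
   breakpoint-straddling block may share its target with a flank block;
   conserved order is therefore non-strict. Runs touching either cluster
   end have no flank and are never reported.
3. **Rearrangement** — one call per maximal contiguous run of matched
   blocks participating in an order descent of the target-index sequence.
   This "one call per disordered segment" reading counts an inverted or
   shuffled segment once rather than per breakpoint. An inversion
   surfaces as a rearrangement (its blocks match on the reverse strand in
   reversed order); strand is recorded on each match but does not define
   a separate call type.

Known limitation: fixed block anchoring means events smaller than ~1 kb,
or divergence concentrated at block edges, can escape detection; the
placement dialect removes the grid-shift artifact but not the 1-kb
resolution floor.

## Phylogenetic profiling

The domain × organism matrix holds, for each of a cluster's domains, the
best global amino-acid identity to any same-Pfam domain in each
organism's other clusters (0 when absent). Pearson correlations between
domain profiles are reordered by average-linkage hierarchical clustering
on Euclidean distances between correlation rows (the linkage and metric
are this package's choice); zero-variance profiles are assigned
correlation 0 rather than propagating NaN. Candidate motifs are maximal
runs of consecutive first-offset-diagonal correlations above the cutoff
(0.5 by default; 0.65 and 0.8 supported). Because leaf order inside a
block of near-identical profiles is arbitrary, a run's members are mapped
back to genomic order before expansion into all contiguous sub-runs of
length ≥ 2, and motif occurrence in a cluster is defined as the motif's
Pfam multiset appearing as a consecutive run of the cluster's domain
order (order-insensitive). Occurrences are counted per cluster.

Significance: for each unique motif, a = clusters where it occurs and
passed the correlation cutoff, b = clusters where it occurs but did not;
χ² = (a−b)²/(a+b) with 1 df against the null that the two counts are
equal; Bonferroni factor = number of unique motifs with a+b > 0 at the
given cutoff. A motif is reported as co-evolving when a > b and the
corrected p clears the significance level (0.001 by default).

Detectability note: with per-cluster counting, a motif carried by k
clusters can reach at most χ² = k, so a motif must occur in ≥ 18 clusters
(corrected p below ~10⁻³ for family sizes around 10) to be detectable at
the default level. The profiling study condition therefore plants its
cassette in 90% of 20 organisms — a widely shared sub-cluster, which is
also the regime the motif analysis is scientifically aimed at.

## Similarity indices

**Percentile Jaccard.** Candidate pairs are same-Pfam domain pairs across
the two clusters, greedily matched one-to-one by descending identity so a
single conserved domain cannot be counted twice. A matched pair enters
the intersection when its identity reaches the 90th percentile of that
Pfam family's corpus-wide cross-cluster identity distribution (the pooled
distribution is substituted for families with < 20 pairs; the boundary is
inclusive, so identical clusters score 1 even in degenerate backgrounds).
The index is |intersection| / (n_a + n_b − |intersection|) over domain
instances; the union convention is this package's choice and reduces to 1
for identical and 0 for Pfam-disjoint clusters.

**Tanimoto.** |a∧b| / |a∨b| on fingerprint bit vectors; fingerprints are
inputs (hex-encoded loader provided); generation from structures is out
of scope. Undefined (error) when both vectors are all-zero.

**Best-hit organism distances.** For each domain, the best cross-organism
same-Pfam homolog (global identity, ties broken by lexicographically
first organism) is mapped to the marker distance between the two
organisms; the distribution is compared against all organism-pair
distances. Under frequent sub-cluster transfer the mass shifts toward
larger distances than under vertical descent — a tendency, not an
invariant: individual tree realizations can flip the comparison, which is
why the analysis driver aggregates replicates.

**Operon calling.** Pathway Pfam sets for histidine (PF00475, PF00815,
PF01174, PF01502, PF01634, PF04864, PF08029, PF08645) and tryptophan
(PF00218, PF00290, PF00465, PF00697, PF01220, PF01264, PF01487, PF04715,
PF08501) biosynthesis. A call requires a contiguous run of pathway-domain
genes (gaps of at most one intervening gene — the contiguity rule is this
package's choice) with ≥ 2 pathway domains, at least one at probability
> 0.5.

**Dereplication.** Mean marker identity per organism pair → similarity
graph → Markov clustering with expansion 2, inflation 2, pruning at
10⁻⁵, iterated to idempotence; one representative (lexicographically
first) per cluster. MCL is implemented in-package on numpy; disconnected
components are never merged. Dense graphs of uniformly high similarity
will merge — the procedure targets collapsing near-identical organisms,
so cross-group marker identities should sit well below within-group ones.

## NRPS/PKS evolutionary modes

Domain "type" is the assembly-line role (KS/AT/C/A/T) when annotated,
else the Pfam id. All empirical p-values use the (r+1)/(N+1) upper-tail
estimator and "inverse p-value" is realized as 1 − p (bounded and
order-preserving; the alternative 1/p is unbounded).

* **Internal homology**: for each domain with a same-type partner in its
  cluster, the empirical p of its best within-cluster identity against
  the corpus-wide distribution of such values for that type. Domains
  without a partner are undefined and excluded.
* **ISI** = mean over defined domains of 1 − p; range [0, 1); high for
  repetitive/homogenized (concerted) clusters.
* **VEI** = mean over each domain's top-10 cross-cluster hits of
  p_identity − p_similarity, where p_identity ranks the hit identity in
  the type's cross-cluster distribution and p_similarity ranks the
  similarity of the two host clusters among all cluster pairs. Positive:
  hits sit in exceptionally similar clusters while their identities are
  corpus-typical (vertical coherence). Negative: exceptional-identity
  hits in unremarkable clusters (promiscuous recruitment). The
  cluster-similarity function is pluggable; the default is the percentile
  Jaccard. In small corpora that index is tie-heavy (many exact zeros),
  which degrades similarity ranks, so the sign-analysis corpora use a
  continuous robust alternative: mean same-Pfam cross identity with the
  single best pair dropped (fewer than two shared families ⇒ similarity
  0), encoding the principle that one recruited domain must not make two
  clusters similar. Any monotone cluster similarity preserves the sign
  logic.
* **Network topology**: nodes = domains, weighted edges = pairwise global
  identity; the graph is thresholded at > 50% identity for component
  counts, clustering coefficient, transitivity, average neighbor degree,
  and counts of complete subgraphs of exactly 2, 3 and 4 nodes.
* The feature table has 17 named features (the topology set, domain and
  Pfam counts, mean/SE of best-pair identities and internal indices, ISI,
  VEI); the feature count is recorded in the table itself rather than
  padded to any nominal number.
* **PCA**: z-scored columns (constant columns dropped with a warning),
  full eigendecomposition; sign convention: each component's
  largest-magnitude loading is positive. Explained-variance ratios sum
  to 1.

## Trees and concerted evolution

Neighbor joining is the canonical Saitou–Nei algorithm with the Q
criterion, ties broken by the smallest index pair in node-creation order,
negative branch lengths clamped to zero with a warning. It is exact on
additive matrices (property-tested on random trees up to 12 leaves, and
cross-checked against an independent implementation). Maximum-likelihood
tree building is out of scope; newick import lets externally built trees
feed the statistics.

BGC specificity: for each leaf (a domain), the nearest other leaf by
patristic distance; the leaf counts as cluster-specific only if *all*
tied nearest neighbors belong to the same cluster. Monophyly of a
cluster's leaves is evaluated on the unrooted tree (the leaf set or its
complement forms one side of an edge bipartition). Both statistics are
reported because "forms its own clade" and "nearest neighbors are
internal" capture different strengths of the concerted signal.

Column entropy: Shannon entropy in bits over amino-acid frequencies per
alignment column, gaps excluded from the frequencies by default; columns
with gap fraction > 0.5 are flagged indel-rich. Bootstrap split support
by column resampling is available but off by default.

## Simulator

The simulator is the oracle for every detector, built to produce the
phenomena the detectors target with exactly known ground truth.

* **Organism tree**: pure-birth (Yule) with exponential branch lengths,
  via dendropy; the marker-distance table is the tip-to-tip path-length
  matrix normalized to [0, 1]. Branch lengths affect only this table.
* **Rates**: event rates are Poisson means per branch; the substitution
  rate is a per-site per-branch flip probability (uniform across sites,
  Jukes–Cantor-like). This per-branch convention keeps expected event
  counts λ·(number of branches) independent of tree height.
* **Operators** act at gene resolution (segment indels, tandem
  duplications, inversions, cross-lineage transfers snap to gene
  boundaries; a free-breakpoint mode is deliberately not offered because
  every downstream contract is gene-scale). Gene conversion overwrites
  one same-type domain's nucleotide span with a paralog's, leaving length
  unchanged. Insertions and transfers carry their payload in the event
  log so that replaying the log from the ancestral clusters reproduces
  every tip exactly — the invariant that makes the log a usable oracle.
  Transfers draw their donor from lineages already visited in the
  traversal, an approximation to "donor alive at transfer time".
* **Assembly lines**: one gene per module, C-A-T (NRPS) or KS-AT-T (PKS)
  domain triplets at fixed windows in a 180-aa module protein, 50-aa
  domains. Module 0's domains can seed all modules (a duplication origin,
  the concerted starting point) or each module can be drawn independently
  (a vertical, position-diverged ancestor); gene conversion can be
  restricted to a subset of domain types (e.g. AT-only homogenization).
* **Proteins** are re-derived from the nucleotide sequence by standard
  codon translation after every event; internal stops simply appear as
  `*` (no selection against them — the simulator models neutral sequence
  divergence only).

**Study conditions** fixed in `bgcevo.scenarios` (sizes chosen to give
each experiment a clearly detectable signal at desk scale):

* single-event pairs: 12–15 genes of 1.0–1.5 kb, per-branch substitution
  probability 0.04 (pair identity ≈ 92%), the planted event applied after
  the substitutions, interior placement with ≥ 2 flanking genes;
* profiling corpus: 20 organisms × 2 clusters, a 4-domain cassette
  shared (with a common per-organism divergence) by 90% of organisms,
  background domains with independent divergences (see the
  detectability note above);
* mode corpora: concerted = homogeneous origin + conversion rate 2 per
  branch; vertical = independent module origins, no conversion;
  N-terminal extension = three rounds of first-module duplication with
  substitutions between rounds; mixed = AT/A/T homogenized and
  converting, KS/C vertical;
* VEI sign corpora are constructed directly in protein space (an
  anchored vertical family; a domain-thief cluster over tight families;
  an exchangeable null) as described in their docstrings.

**What the simulator does not emulate**: realistic amino-acid
substitution processes (no rate heterogeneity, no selection), genome
context around clusters, annotation noise (domain calls are exact),
cluster birth/death, and population-genetic dynamics. Passing recovery
tests therefore demonstrates correctness of the detectors under the
stated generative model, not their error rates on real annotated genomes,
where alignment ambiguity and annotation error add noise these corpora
do not contain.

## Problem sizes and determinism

The test and acceptance runs use: 200 single-event pairs (acceptance
suite) / 120 (acceptance script) for the event caller; 20 / 10 profiling
seeds; 50 + 50 clusters for ISI separation; 100 random additive matrices
for NJ; 30 concerted-vs-vertical replicates; 15 clusters per mode for
PCA/k-means. These sizes give the binomial assertions comfortable margins
at desk scale. Every random draw descends from a single seed (numpy
`SeedSequence`; dendropy trees from a seeded `random.Random`), and every
writer emits sorted, fixed-format output, so identical seeds and inputs
give byte-identical files.
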