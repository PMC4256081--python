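# bgcevo

Comparative-genomic analysis of biosynthetic gene cluster (BGC) evolution.

Bacterial secondary metabolites — polyketides, nonribosomal peptides and
their relatives — are encoded by physically clustered groups of genes.
These clusters evolve fast: they gain and lose multi-kb segments, duplicate
and rearrange internal blocks, swap discrete sub-clusters between otherwise
unrelated loci, and (in multimodular NRPS/PKS assembly lines) homogenize
their repeated domains by recurrent gene conversion (concerted evolution).
`bgcevo` implements the computational machinery to detect and quantify
these processes from cluster sequences and Pfam-style domain annotations,
together with a simulator that generates cluster corpora with ground-truth
event logs so that every detector can be validated against a known answer.

The package is organised as an analysis project: the computation lives in
the library under `src/bgcevo/`, and the numbered scripts under `analysis/`
are thin drivers that run each study and write tables under `results/`.

## What it computes

* **Block-based event calling** (`bgcevo.blocks`). Cluster sequences are
  cut into consecutive 1-kb blocks; each block is placed at its most
  homologous position in the partner cluster (semi-global alignment, both
  strands) and in its own cluster. For pairs with ≥ 3 blocks matching at
  > 70% identity, events are read off the matched-index sequence:
  *rearrangements* are maximal disordered segments of the block order,
  *indels* are unmatched runs in exactly one cluster flanked by ≥ 2 kb of
  order-conserved homology, and *duplications* are blocks whose best hit
  lies within their own cluster at higher copy number than in the partner.
* **Phylogenetic profiling of sub-cluster motifs** (`bgcevo.profiling`).
  For each cluster, a domain × organism matrix of best same-Pfam
  identities; Pearson correlation of domain profiles, reordered by
  hierarchical clustering; runs of adjacent correlations > 0.5 (also 0.65,
  0.8) become candidate co-evolving motifs, tested with a 1-df χ²
  goodness-of-fit — χ² = (a−b)²/(a+b) for *a* co-evolving vs *b*
  non-co-evolving occurrences — with Bonferroni correction.
* **Similarity indices** (`bgcevo.similarity`). The cluster-pair sequence
  similarity index is a Jaccard index over Pfam domain pairs whose
  identity reaches the top decile of their own family's corpus-wide
  identity distribution; product similarity is the Tanimoto coefficient
  |a∧b|/|a∨b| on fingerprint bit vectors. Also: best-hit organism-distance
  distributions (a horizontal-transfer proxy), His/Trp operon calling
  (≥ 2 pathway domains, ≥ 1 with probability > 0.5), and organism
  dereplication by Markov clustering (expansion 2, inflation 2) of
  marker-gene distances.
* **NRPS/PKS evolutionary modes** (`bgcevo.modes`). Per-domain empirical
  p-values for the best within-cluster same-type match, the internal
  similarity index ISI = mean(1 − p), the vertical evolution index
  VEI = mean(p_identity − p_similarity) over each domain's top-10
  cross-cluster hits, domain-similarity network topology (clustering
  coefficient, transitivity, k-clique counts, components above 50%
  identity), and a PCA over the 17-feature table.
* **Concerted-evolution detection** (`bgcevo.trees`). Neighbor-joining
  trees (canonical Saitou–Nei, exact on additive matrices) of same-type
  domains across clusters; the BGC-specificity statistic (fraction of
  domains whose nearest tree neighbor is a same-cluster domain, plus
  per-cluster monophyly); alignment-column Shannon entropy.
* **Simulator** (`bgcevo.simulate`, `bgcevo.scenarios`). Clusters evolve
  along a pure-birth organism tree under substitutions, gene-scale indels,
  tandem duplications, inversions, cross-lineage sub-cluster transfers,
  module duplications and gene conversion. Every event is logged with
  enough payload that replaying the log reproduces the tip clusters
  exactly.

## Worked example

Run the analyses (each is standalone):

```bash
python analysis/02_block_events.py
python analysis/06_nrps_modes.py
```

The first plants one known event (a ≥ 3-kb deletion, a tandem two-gene
duplication, or a two-to-three-gene inversion) into each of 60 simulated
cluster pairs at ~92% pairwise identity and calls events blind:

```
planted-event recovery over 60 pairs:
  indel          recall 1.00  precision 1.00
  duplication    recall 1.00  precision 1.00
  rearrangement  recall 1.00  precision 1.00
```

(An inversion surfaces as a rearrangement call, since the block order
reverses in place.) The second simulates 15 assembly-line clusters in each
of four evolutionary modes — concerted, N-terminal extension, vertical,
mixed — computes the feature table and reports how well the modes separate:

```
first two principal components explain 87.6% of the variance
k-means on PC1/PC2 vs true modes: adjusted Rand index 0.955
N-terminal-extension gradient: Spearman rho > 0 in 15/15 clusters (median rho 0.87)
```

The positive rank correlation between module index and internal-homology
p-value is the signature of clusters that grow by repeatedly duplicating
their most N-terminal module: the newest (N-terminal) modules are the most
mutually similar.

A `bgcevo` command-line tool wraps the same library for ad-hoc use
(`bgcevo simulate`, `bgcevo call-events`, `bgcevo profile-motifs`,
`bgcevo indices`, `bgcevo find-operons`, `bgcevo subcluster-net`,
`bgcevo nrps-modes`, `bgcevo concerted`); all commands are byte-identical
across runs for a fixed seed and input.

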