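# Methods

`rosmine` re-implements, as a tested and reusable pipeline, a
database-construction workflow for mining reactive-oxygen-species-scavenging
enzymes (ROSes) from microbial proteomes: similarity screening against a
labeled reference set, a hierarchical voting-ensemble classifier over 26
enzyme categories with confidence tiers, sequence-similarity network
analysis with K-shell decomposition and attack-robustness simulation,
NG86 Ka/Ks estimation, and in-silico mutational significance mapping.
Everything is exercised end to end on synthetic data whose ground truth is
known by construction.

## Mining model

**Screening gate.** A candidate protein enters the pipeline only if its
best local alignment against the reference set has percent identity >= 10
and E-value <= 1e-3 (both inclusive; the common tool convention for bare
thresholds). The built-in engine is exact Smith–Waterman with affine gaps
(BLOSUM62, gap open 11, extend 1). Bit scores use the published *ungapped*
BLOSUM62 Karlin–Altschul constants (lambda = 0.3176, K = 0.134) applied to
the gapped raw score, with E = m·n·2^(−bits) and search space m·n = query
length × summed reference length. Applying ungapped constants to gapped
scores overstates significance by a small factor (measured ~4× at E ≈ 0.1
on shuffled decoys), which for a permissive screening gate errs on the
side of keeping candidates; the classifier downstream is the precise
filter. An NCBI `blastp` engine is available behind the same contract for
large runs, and precomputed BLAST/DIAMOND tabular hits ("outfmt 6") can be
ingested directly.

**Hierarchical ensemble.** Level 0 decides ROSes vs non-ROSes by hard
voting over three component models, each with its own view of the
sequence:

- *tree model*: XGBoost gradient-boosted trees (150 trees, depth 4) on
  3-mer counts over the full 20³ = 8000-dimensional k-mer space;
- *conv model*: one convolution layer over the L×20 one-hot encoding whose
  512 width-8 filters are one-hot patches sampled (seeded) from the
  training sequences — a patch-dictionary convolution whose max-pooled
  activation is the best local match of each patch anywhere in the input —
  with global max and mean pooling and a trained one-hidden-layer dense
  head. No deep-learning framework is used; the conv layer is fitted by
  patch sampling rather than backpropagation, which keeps training on one
  CPU to seconds while preserving the architecture (one conv layer, global
  pooling, dense head);
- *dense model*: a two-hidden-layer feed-forward network (64, 32 units) on
  the 20-vector of residue frequencies plus length, standardized.

A component votes positive when its probability >= 0.5 (an unstated
threshold fixed at the symmetric default). A sequence is labeled ROSes
when >= 2 of 3 components vote positive; three positive votes give *high*
confidence, exactly two give *medium*. Level 1 assigns one of 26 category
names by soft voting: the unweighted mean of the three models'
class-probability vectors, argmax with lexicographic tie-break on the
category name (deterministic and row-order independent). Categories absent
from training data receive zero-probability columns. No sequence receives
a category without a positive level-0 label. The 26-name label space
places the twelve family names commonly reported for gut-microbial
antioxidant systems first and fills the remainder with plausible
antioxidant-enzyme names; the list is configurable wherever a
`categories` argument is accepted.

**Database.** The flat-file database holds the screen survivors voted
ROSes, with category, confidence tier, best reference hit and vote
provenance. Per-(phylum, category) summaries report two layers
distinctly: screen-level homolog counts (with a best-homolog flag at
E < 1e-10) and vote-filtered entries, because homolog counts and curated
entries answer different questions. Per-genome averages count every genome
in the metadata, including genomes with zero entries.

## Network analysis

Nodes are genes; an undirected edge joins two genes when the
better-direction alignment hit has E <= 1e-5 (a configurable default —
no canonical threshold exists for similarity networks), weighted by the
maximum bit score. On this simple graph the package computes degree
distributions, PageRank (power iteration, damping 0.85, tolerance 1e-10,
isolated nodes treated as dangling), and K-shell decomposition by
minimum-degree peeling on the unweighted graph (the classical definition;
edge weights are ignored). Robustness simulations remove nodes under
three strategies — uniform random, highest degree first, highest PageRank
first — recording at each removal fraction:

- RS = N_t / n₀, the relative size of the largest connected component
  (denominator fixed at the initial node count so RS ∈ [0, 1] and
  RS(0) = 1);
- RE = E(G_t) / E(G₀), relative global efficiency, where E(G) is the mean
  over ordered pairs of 1 / shortest-path-length (0 for disconnected
  pairs) — the standard network-science reading of "relative efficiency",
  the standard network-science definition.

Targeted strategies re-rank after every removal by default (adaptive);
a static rank-once mode is available behind a flag. Graphs are exported
as GraphML with node attributes (category, phylum, shell, pagerank)
rather than rendered.

## Ka/Ks estimation

Coding-sequence pairs are aligned protein-first: the two translations are
globally aligned (BLOSUM62, affine gaps) and back-translated so gaps fall
on whole-codon boundaries. Ka and Ks follow Nei–Gojobori (1986) counting
with equal-weight pathway averaging and Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p), chosen as the canonical, fully specifiable
counting baseline. Numerical conventions:

- single-base changes producing stop codons count as nonsynonymous sites,
  so synonymous + nonsynonymous sites total exactly 3 per codon;
- mutational pathways passing through a stop codon are excluded from the
  pathway average, falling back to all pathways when every one is blocked;
- the ratio is reported as NA (not 0, not infinity) when Ks = 0 or a
  correction is undefined (p >= 3/4); batch summaries exclude NAs and
  report their count;
- a trailing stop codon is tolerated and dropped; internal stops are
  errors naming the codon index. Standard genetic code only.

Spearman correlations among Ka, Ks and the ratio use midranks for ties
and return NA for constant input.

## Mutational significance maps

For a sequence of length L, all L×20 single-residue substitutions are
scored by the level-0 ensemble's *soft* score (the mean of the three
component probabilities — a hard vote would give a two-valued map and
destroy the map's continuous structure). Entry (i, a) is the probability
that the mutant with residue a at position i is a ROSes; wild-type cells
are computed once and broadcast, so they are exactly identical across
positions. The conservation score of a position is the wild-type
probability minus the mean over its 19 true substitutions — "mutation
hurts here" — and positions strictly above a configurable quantile
(default 0.95) of all positional scores are flagged, so a perfectly flat
map flags nothing while ties above the threshold are kept. Positions are
reported 1-based.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions:

- **Reference families** (default 26 categories × 20 members): each family
  is a cluster of diverged homologs — a consensus sequence drawn on a
  family-specific residue composition (symmetric Dirichlet, concentration
  5) with a distinct random motif (length 10) planted once, members being
  copies of the consensus with uniform point substitutions at rate 0.25
  (~75 % within-family identity, typical of a curated family), motif
  protected. Lengths are uniform on 80–150 residues, the range of small
  redox enzymes such as thioredoxins and peroxiredoxins.
- **Genomes** (default 50): each genome draws its planted ROSes count from
  Poisson(9) (gut bacteria typically carry on the order of nine such
  enzymes per genome), planting point-mutated copies of reference members (rate 0.10,
  motif protected so truth labels remain recoverable by motif scan) among
  10 uniform-random background proteins, with a phylum label from a fixed
  gut-associated list.
- **Codon pairs**: one random stop-free CDS and a copy that accumulates
  exactly round(t·n_codons) accepted single-base substitutions;
  synonymous proposals are accepted with probability min(1, 1/ω) and
  nonsynonymous with min(1, ω), and proposals creating stops are rejected,
  so the realized nonsynonymous:synonymous odds — and the NG86-estimable
  ratio — scale with ω. The generator's own bookkeeping of accepted
  synonymous/nonsynonymous changes serves as an independent oracle for the
  estimator. At ω = 0 each codon receives at most one substitution:
  stacked synonymous hits can otherwise compose into codon pairs whose
  mutational pathways pass through nonsynonymous intermediates, which any
  pathway-averaging estimator counts as fractional nonsynonymous signal,
  and the ω = 0 contract ("no nonsynonymous divergence") is meant exactly.
- **Benchmark graphs**: path/star/complete/barbell fixtures plus
  Barabási–Albert (scale-free) and Erdős–Rényi generators, seeded.

Not emulated: indels and site-rate heterogeneity (no phylogenetic
realism), KEGG pathway structure, genome-scale gene content, real
amino-acid background frequencies (background proteins are uniform
random). Consequently, passing the synthetic benchmark demonstrates that
the pipeline machinery recovers planted structure under controlled
conditions — not that the classifier would reach the same accuracy on
real proteomes, where family boundaries are fuzzier and negatives are
biological sequences rather than random strings.

## Problem sizes and numerical choices

The end-to-end benchmark uses 26 families × 20 members (70/30 stratified
split), 50 genomes, Poisson(9) planted genes and 10 background proteins
per genome, run over 10 seeds with medians reported; these sizes keep a
full multi-seed run on one CPU in a few minutes while leaving every
pipeline stage non-trivially loaded. Ka/Ks recovery uses 2000-codon pairs
(20 replicates per ω); robustness simulations use scale-free graphs with
300 nodes and removal steps of 0.05. Screening for the large demo runs
uses the `blastp` engine; unit tests exercise the exact built-in engine.
All randomness flows from explicit integer seeds; training is
single-threaded and reproducible given the seed (XGBoost `n_jobs=1`,
scikit-learn `random_state`).

## Known limitations

- E-values from the built-in aligner are approximate (ungapped constants
  on gapped scores); rank order of hits is unaffected.
- The conv component's filters are sampled, not learned; its standalone
  accuracy trails the tree model, which the 2-of-3 vote absorbs.
- K-shell core fractions on dense within-family cliques are close to 1 by
  construction; core–periphery structure appears once more-diverged
  members (e.g., planted genome copies) enter the network.
- The NG86 ratio is undefined (NA) for pairs without synonymous
  divergence; summaries must be read together with the reported NA count.
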