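# Methods

## Problem and approach

Protein complexes appear in a protein–protein interaction (PPI)
network as node sets whose induced subgraphs look statistically
different from random subgraphs — but not necessarily as dense
cliques, which is where purely density-driven clustering struggles.
`epcomplex` treats complex detection as a supervised contrast-mining
problem:

1. **Representation.** Every subgraph C of the network G = (V, E) is
   summarised by a 22-dimensional feature vector: node size, graph
   density, and mean/max/variance statistics of per-node degree,
   degree correlation, local clustering coefficient, and topological
   coefficient, the leading eigenvalues of the induced adjacency and
   combinatorial Laplacian matrices, and mean/max/variance of protein
   sequence length and molecular weight from an optional attribute
   table (zero when absent).
2. **Contrast mining.** Known complexes mapped onto the network form
   the positive class Dp; random node sets form the negative class Dn
   (20 per positive by default, sizes resampled from the positive size
   list).  Features are discretized into 10 equal-width bins fitted on
   Dp ∪ Dn; a (feature, bin) pair is an item.  A noise-tolerant
   emerging pattern (NEP) of a class is an itemset with support ≤ δ1
   in the contrasted class and ≥ δ2 in its own class, minimal with
   respect to the rarity condition.  Both directions are mined:
   EP(Dp) and EP(Dn).
3. **Scoring.** The aggregate score of a subgraph for a class sums the
   own-class supports of the class's NEPs contained in its discretized
   vector Ins(G).  Each aggregate is divided by a per-class base score
   (the median aggregate of the class's own training instances) to
   correct for unequal pattern counts, and the clustering score
   combines the two normalized scores np and nn as f = np/(np + nn)
   (f = 0 when both vanish).  f > 1/2 iff np > nn, and f = 1 iff the
   subgraph matches no negative pattern at all — the two identities
   that pin down this ratio form.
4. **Search.** Seeds are taken in descending network degree among
   proteins not yet covered by an accepted complex.  From seed v0 the
   cluster C grows by repeatedly testing the single external neighbor
   with the most edges into C (ties by lexicographic ID); the
   candidate is accepted iff f does not decrease **and** the average
   degree avedeg(C) = 2|Ec|/|Vc| strictly increases.  Growth stops at
   the first rejection; C is emitted if f(C) > 1/2 and |C| ≥ 3.
   Predictions with overlap score ω(A, B) = |A∩B|²/(|A||B|) ≥ 0.8 are
   merged into their union, highest ω first, recomputing ω after every
   merge.
5. **Evaluation.** Predictions P against a reference S: matched-set
   precision/recall/F1 at ω ≥ 0.25, clustering-wise Sen/PPV and their
   geometric mean Acc from the intersection matrix T, the maximum
   matching ratio MMR (maximum-weight one-to-one ω-matching divided by
   |S|), and the composite score Frac + Acc + MMR.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `bins` | 10 | equal-width bins per feature; fitted on Dp ∪ Dn |
| `delta1` | 0.1 | background-rarity support bound; admits patterns occurring in ≤10% of the contrasted class |
| `delta2` | 0.7 | target-frequency support bound; requires ≥70% own-class support, well separated from δ1 |
| `neg_ratio` | 20 | random subgraphs per training complex |
| `min_size` | 3 | emitted complexes need ≥3 proteins, mirroring the removal of 1–2-protein training complexes |
| `merge_threshold` | 0.8 | ω at which two predictions merge; the convention of overlap-merging complex detectors |
| `best_of_k` | 1 | neighbors tested per growth step; 1 is the strict best-candidate rule, larger values are experimental |
| `connected_negatives` | off | random-walk-connected negatives instead of uniform node sets |
| `random_state` | 0 | seeds negative sampling; fixes all outputs byte-for-byte |

Uniform (not forced-connected) negative node sets are the default:
uniform sets in a sparse network are nearly edgeless, which is exactly
the contrast that makes topological patterns discriminative.

## Design choices

* **Degree normalization.** Per-node degrees inside the subgraph are
  divided by |Vc|−1, so all degree statistics live in [0, 1] and are
  comparable across sizes.  Degree correlation is the ratio of a
  node's mean neighbor degree to its own degree (0 for isolated
  nodes), a per-node quantity whose variance is unbounded above 1,
  unlike graph-level assortativity.  The topological coefficient
  follows the Cytoscape convention, counting shared neighbors (plus
  one for a direct link) over the node's degree.
* **Miner.** Depth-first search over items ordered by (feature, bin),
  with tidset intersection for supports.  Two prunes are exact: a
  branch dies when target support falls below δ2 (anti-monotonicity),
  and a branch stops extending once the rarity condition holds
  (any extension would be non-minimal).  Because support is
  anti-monotone, minimality only needs checking on the immediate
  (|X|−1)-subsets, which the post-filter does.  Correctness is defined
  by equality with a literal enumeration oracle, which the test suite
  checks on hundreds of random instances.
* **Base-score guard.** If a class's median training aggregate is 0,
  the base falls back to the smallest strictly positive per-instance
  score, then to 1 — normalization stays defined even for tiny
  pattern sets; the fallback is logged.
* **Termination.** The natural stopping rule "every protein occurs in
  some found complex" can never be met by proteins that never join a
  complex, so every tried seed is marked visited; each round consumes
  a seed, guaranteeing termination.
* **Merging vs the f-contract.** A merged union is re-scored; in the
  rare case it no longer satisfies f > 1/2 it is dropped, keeping the
  necessary condition of every emitted complex intact.
* **MMR.** Solved exactly as a rectangular maximum-weight assignment
  (`scipy.optimize.linear_sum_assignment`); with nonnegative weights
  the optimal assignment weight equals the optimal matching weight.
  Edges are included for every ω > 0, not only ω ≥ 0.25.
* **F1** is the harmonic mean 2PR/(P+R).  Note that Sen/PPV do not
  simply swap when S and P are exchanged: Sen is normalized by
  reference sizes while PPV is normalized by the total intersection
  mass Σ_ij T_ij, the standard convention for geometric accuracy.

## Synthetic benchmark

`FixtureSpec` defaults describe the standard benchmark used by the
tests and the reproduction script: a 300-protein Erdős–Rényi
background at edge probability 0.02 (mean degree ≈ 6, comparable to
curated yeast interactomes), 20 planted complexes with sizes 4–10
drawn from a power law with exponent 2, internal edge density 0.8
(sparse variant: 0.4) with a random spanning chain forcing
connectivity, 2 attachment edges per complex tying it into the
background, log-normal sequence lengths (median ≈ 450 residues) and
molecular weight ≈ 0.11 kDa per residue ± 5%.

The generator emulates the statistical contrast the method relies on
— planted cohesive subgraphs against a sparse background with
size-matched random negatives — but not other properties of real
interactomes (scale-free background degrees, correlated experimental
noise, shared subunits between complexes, GO-informed edge
confidence).  Passing the recovery tests therefore demonstrates the
machinery works end-to-end under the model's own assumptions, not
field performance on curated PPI data.

Problem sizes throughout the suite (300-node networks, 10 training
complexes, 200 negatives, 50-network search sweeps) were chosen as the
smallest at which the planted-recovery behaviour is stable; a full
train–predict–evaluate cycle takes a few seconds.

## Degenerate inputs and numerics

Singleton subgraphs score 0 on every topological feature; density and
average degree are 0 by convention, so growth from a one-node seed is
well defined.  Constant features over the training matrix map every
value to bin 0 and can never discriminate.  Discretization clips
values outside the fitted range into the boundary bins.  Support
comparisons use a 1e-12 slack so threshold equality (e.g. support
exactly δ2) is honoured despite floating-point division.  All
randomness flows from explicit integer seeds; model JSON is written
with sorted keys, making every artefact byte-reproducible.

## Known limitations

* Single-seed growth is brittle by design: from a singleton all
  neighbors tie at one connecting edge and the lexicographically
  smallest wins, so an individual seed can wander into the background.
  Coverage comes from the seed schedule, not from any one growth.
* Precision on the synthetic benchmark is low (~0.15): many background
  regions grow into small false positives.  The upstream evaluation
  regime emphasises recall/MMR-style measures; no post-filtering of
  low-f predictions beyond f > 1/2 is applied.
* Sparse-complex recovery varies strongly with the random seed; the
  documented bound (recall ≥ 0.3 on the standard seed) should not be
  read as a general guarantee.
* Edge weights are parsed and stored but unused; the method is
  topology- and attribute-based.
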