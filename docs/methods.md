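# Methods

## Model and procedure

`fcgrclust` clusters DNA sequences from composition alone. The pipeline
has three stages:

1. **Representation.** Every sequence is reduced to its FCGR at
   resolution k: a 2^k × 2^k grid counting all length-k sliding windows
   composed of A/C/G/T (windows containing ambiguity codes are skipped).
   The grid cell of a k-mer is the quantized endpoint of the chaos-game
   midpoint iteration with corners A bottom-left, C top-left, G
   top-right, T bottom-right, rendered with row 0 at the top. Because
   each midpoint move halves the remaining displacement, the last base
   of the k-mer selects the quadrant and earlier bases refine it; the
   map is a bijection from the 4^k k-mers onto the grid. The corner
   layout is a frozen convention — any fixed bijection carries the same
   information — but it must stay frozen for reproducible exports.
   Counts are L1-normalized and flattened row-major to a 4^k vector.

2. **Mutual-information training on mimic pairs.** For each sequence,
   m mimics are generated by per-position random substitutions: mimic 1
   with transitions only (probability p_ts per position, A↔G / C↔T),
   mimic 2 with transversions only (p_tv, the two cross-class partners
   equally likely), mimics 3..m with both (transition draw first, then
   an independent transversion draw on the result). A shared MLP
   (4^k → 512 → 64 → c, ReLU + dropout 0.5 after each hidden layer,
   softmax output) maps the FCGR of a sequence and of one of its mimics
   to cluster distributions; each batch estimates the joint distribution
   P = (1/B) Σ Φ(x)Φ(x̃)ᵀ, symmetrized to (P + Pᵀ)/2, and Adam minimizes
   L = −λ·H(marginal) + H(conditional) with natural logarithms and
   entries clamped at 1e-12 before logs.

3. **Ensemble voting.** Several networks train independently (seeds
   seed+0..seed+V−1). Their labelings are aligned by maximizing
   contingency agreement (Hungarian assignment) against a reference
   voter, then each sequence takes the majority label; ties resolve to
   the reference's label, or to the lowest tied index if the reference
   is not among the tied maxima.

Evaluation is strictly post hoc: true labels feed only the Hungarian
cluster→taxon mapping behind ACC, plus NMI (geometric-mean
normalization) and ARI. Training functions accept bare sequences, so
labels cannot leak in by construction. Probability vectors can be
projected for inspection onto a regular c-gon (vertex 0 at 90°,
counter-clockwise) as the convex combination of vertices — a confident
assignment sits on a vertex, an undecided one near the origin.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 6 | FCGR resolution; 4^k input features (k = 4 in the test benchmark, which is gentler on memory/time at no benchmark cost) |
| c | — | upper bound on the number of clusters; empty clusters are allowed |
| m | 3 | mimics per sequence (one per substitution mode plus combinations) |
| p_ts, p_tv | 1e-4, 0.5e-4 | per-position transition / transversion probabilities |
| λ | 2.5 | marginal-entropy weight; larger values push harder against cluster collapse |
| learning rate | 5e-5 | Adam step size (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) |
| epochs | 150 | fixed-length training, no early stopping |
| batch size | 512 | the batch is also the sample for the joint-distribution estimate, so it must be large enough to represent the cluster marginal |
| noise period / σ | 50 epochs / 0.01 | i.i.d. Gaussian noise added to all parameters to escape plateaus; never after the final epoch |
| voters | 10 | independently trained networks in the ensemble |

## Numerical choices

- **Input scaling.** L1-normalized 4^k vectors have entries of order
  4^-k, far below the unit-variance regime Kaiming initialization
  assumes. With such inputs the optimizer demonstrably converges *into*
  the uniform-output saddle: near uniform outputs the marginal-entropy
  curvature is quadratic while the mutual-information signal is only
  quartic in the deviations, so tiny initial deviations shrink instead
  of growing (one loss term dominates, and training stalls at loss
  (1−λ)·ln c). Inputs are therefore multiplied by 4^k at the network
  entry — each feature becomes the k-mer frequency relative to the
  uniform composition, with mean 1 — which restores order-one
  pre-activations and reliable escape. Stored pair vectors remain
  L1-normalized; the scaling is internal to training and assignment.
- **Ensemble reference.** Anchoring alignment on an arbitrary voter is
  fragile: if that voter merged two clusters (one cluster empty), the
  Hungarian alignment of better voters to it is tie-ambiguous, they land
  on conflicting conventions, and the degenerate reference can win the
  vote. The reference is therefore the voter with the lowest final-epoch
  training loss — an unsupervised criterion, consistent with the premise
  that the loss tracks clustering quality.
- **Logarithm base.** Natural log throughout the loss; a different base
  rescales the loss uniformly and is absorbed by the learning rate.
- **Batches.** Random permutation each epoch; the final short batch is
  kept unless it holds fewer than c samples, in which case it merges
  into the previous batch (a marginal estimated from fewer than c
  samples is meaningless and small datasets would otherwise lose a
  large fraction of pairs).
- **Ties.** Hard labels take the lowest index among tied maxima;
  `linear_sum_assignment` resolves assignment ties deterministically.
- **Determinism.** All randomness flows from integer seeds through
  NumPy `SeedSequence` streams (separate streams for initialization,
  shuffling, dropout, noise; mimic streams keyed by (seed, sequence id,
  mimic index) so adding sequences never changes existing mimics).
  Training arithmetic is float32 with float64 loss accounting; reruns
  on the same platform are bit-identical.
- **Degenerate inputs.** Sequences shorter than k, empty FASTA records,
  all-ambiguous windows, and single-block partitions (NMI undefined)
  raise explicit errors rather than producing silent zeros.

## Synthetic benchmark

The generator emulates the one property the method actually needs from
real data: taxon-specific k-mer composition. Each cluster is an order-1
(configurable to 3) Markov chain over A/C/G/T; a shared base matrix T₀
with Dirichlet(1,1,1,1) rows is blended with an independent draw per
cluster, T_c = (1−δ)·T₀ + δ·T'_c, so δ interpolates from identical
composition (δ = 0, the correct clustering outcome is chance) to fully
independent signatures (δ = 1). Expected k-mer spectra are computed
analytically from the stationary distribution to quantify benchmark
difficulty (`signature_separation`).

The default benchmark uses c = 4 balanced clusters of 150 sequences,
lengths uniform in 5–10 kbp, δ = 0.8, k = 4, 60 epochs, 5 voters —
sized so the full suite and the acceptance script run in minutes on one
CPU while still exercising every stage at realistic signal strength.

What the generator does *not* model: mutation processes relating
sequences within a cluster (sequences are i.i.d. draws from the cluster
chain), indels, variable GC along a genome, horizontal transfer,
phylogenetic structure between clusters, or sequencing noise. Passing
benchmarks therefore demonstrate that the pipeline recovers
compositional structure when present at a known strength — not that it
matches the published accuracy on any particular real taxon set.

## Limitations

- Accuracy inherits the genomic-signature premise: clusters that differ
  only by features invisible to k-mer composition (e.g. rearrangements)
  are indistinguishable.
- The batch-size constraint means very small datasets (n·m well below
  512) estimate the joint distribution from a single batch; increasing
  m is the intended remedy.
- c is an upper bound supplied by the user; the method does not select
  the number of clusters.
- Training cost scales with voters × epochs × pairs; the NumPy
  implementation is single-process and CPU-bound.
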