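# Methods

## Model and assumptions

The pipeline treats drug-like herbal ingredients and human protein targets
as the two node sets of a heterogeneous network: an ingredient similarity
network, a target similarity network, and the known binary association
matrix A connecting them. Two assumptions drive the scoring: similar
ingredients tend to bind similar targets (and vice versa), and association
probability diffuses along similarity edges. A restart term anchors the
diffusion at the known associations (bi-random walk) or at the disease
seed targets (seeded walk), so predictions stay local to the evidence.

The bi-random walk runs its left recursion (over the target network) and
right recursion (over the ingredient network) independently to their fixed
points and averages them; each recursion is a contraction with factor α,
so the fixed point exists, is unique, and equals the closed form
(1−α)·A′·(I−αS_t″)⁻¹ (and the left-multiplied analogue). The iterative
solver is the production path; the direct solve is retained as an
independent cross-check.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (restart probability) | 0.3 | fraction of each step taken along the similarity network; 1−α returns to the anchor distribution |
| tolerance | 1e-6 | elementwise max-abs residual at which iteration stops (strictest common reading of an unnamed norm; scale-free in matrix size) |
| max_iterations | 1000 | safety bound; the contraction argument implies ≈12 steps at α = 0.3, so hitting this signals degenerate input |
| c, d (logistic) | −15, log 9999 | chosen so L(0) = 10⁻⁴ and L(0.3) < 0.01: near-zero chemical similarities carry almost no weight |
| neighbor threshold | 0.4 | minimum interaction confidence (strictly greater) for two targets to count as neighbors in the common-neighbor measure |
| γ′_r, γ′_t (GIP) | 1.0 | bandwidth multipliers; the kernel bandwidth is γ′ divided by the mean squared profile norm, adapting to association density |
| fingerprint | Morgan, radius 2, 2048 bits | deterministic and widely reproducible circular fingerprint; the historical fingerprint behind the original similarity tables is not recoverable, so exact reproduction of those matrices is out of scope |
| SW scoring | BLOSUM62, gap open 10, extend 0.5 | standard protein local-alignment scheme; scores are kernel-normalized to [0,1] by SW(i,j)/√(SW(i,i)·SW(j,j)) |
| OB / DL screen | > 20%, > 0.1 | strict ADME inequalities; records missing either value are dropped with a warning |

## Numerical and design choices

- **Tanimoto denominator.** Implemented as |f_i|² + |f_j|² − f_i·f_j, the
  standard symmetric form for binary fingerprints.
- **Diagonals.** The logistic transform is applied off-diagonal only and
  every measure's diagonal is forced to 1: self-similarity must be maximal
  for the Laplacian-normalized walk operators to be well-behaved. Entropy
  is computed on the matrices after this diagonal policy, with the
  diagonal included in row normalization (the row sum has no exclusion).
- **Entropy logarithm.** Natural log. A near-uniform 731-wide row then has
  entropy ln 731 ≈ 6.59, consistent with the reference mean entropy of the
  sequence measure at that scale; base 2 or 10 would not be.
- **Seeded-walk orientation.** The normalized target matrix S_t″ is
  row-stochastic, so the iteration uses its transpose: only
  P ← α·(S_t″)ᵀ·P + (1−α)·P₀ conserves total probability (asserted to
  1e-8 at convergence).
- **Ties.** Ingredient ranking is a stable descending sort with input
  order as the final key (deterministic); ties are logged. Effect-score
  tables use dense ranks. A compound's ingredient set is the union of its
  member herbs' sets without multiplicity, since the effect score sums
  over ingredients, not herb–ingredient pairs.
- **Degenerate inputs.** All-zero similarity rows stay all-zero after
  normalization (the walker stalls there, with a warning); an all-zero
  association matrix is rejected outright; a measure with zero mean
  entropy raises instead of silently taking infinite weight.
- **Strictness.** "Greater than" is strict everywhere it appears: the 0.4
  neighbor threshold, the cap condition St3 > 1 → 0.99, and the OB/DL
  screen.
- **Edge scores.** Readers require confidence scores in [0, 1]; raw
  0–1000 combined scores must be pre-scaled (CLI `--scale-string-scores`),
  because the 0.4 neighbor threshold is only meaningful on the unit scale.
  Symmetric duplicate edges merge keeping the maximum.
- **Canonical index.** Entity order is first-appearance order in the
  association table; all other inputs are re-indexed against it. Entities
  with missing SMILES or sequence are retained and contribute 0
  off-diagonal in the affected measure only.

## Synthetic data: what it emulates and what it does not

The generator plants a block structure: ingredients and targets are
assigned round-robin to blocks (default 4 blocks over 60 ingredients ×
80 targets, seed 7), and block-b ingredients associate with block-b
targets at rate 0.5 against a 0.02 background. Every similarity channel
carries the same signal — each block draws SMILES from its own slice of a
fixed list of 20 real drug-like molecules, targets share an embedded
10-residue block motif inside otherwise random 80–200 residue sequences,
and the interaction edge list is denser and higher-scoring within blocks.
Disease seeds are the block-0 targets; positive controls are the block-0
ingredients with at least one association, negatives are drawn from other
blocks. Herbs sample mostly from a home block and compounds group a few
herbs. A matched null fixture sets the within-block rate equal to the
background, removing the association signal.

This emulates the *structure* a real herbal dataset presents to the
algorithm — sparse block-correlated associations, chemistry/sequence/
interaction similarity that partially agrees with the association
structure — but not the marginal distributions of real databases: real
fingerprint similarity is continuous rather than clustered on a 20-
molecule pool, real sequence similarity is not motif-driven, and real
control sets are noisier than block labels. Recovery on the fixture
(AUC > 0.9 planted vs ≈ 0.5 null) therefore demonstrates that the
implementation propagates planted signal correctly, not that it attains
any particular accuracy on real data.

## Problem sizes used in routine checks

Routine verification runs the full pipeline on the 60×80 default fixture
(sub-second per run), 20 null-fixture replicates for the chance-level
comparison, 200 random instances up to 50×50 for iterative-vs-direct-solve
agreement at 1e-5, and one 457×731 matrix with ~6973 associations — the
scale of the production AD network — to confirm the network stage
(GIP kernels, fusion, both walks, scoring) completes in well under a
minute on one CPU.

## Known limitations

- The historical fingerprint implementation behind the original
  ingredient-similarity tables is unrecoverable, so those matrices (and
  quantities downstream of them) can be reproduced in procedure but not
  bit-for-bit in value.
- Whether the original seeded walk used S_t″ or its transpose is
  ambiguous; the transpose is the probability-conserving choice and is
  what this package implements.
- The pipeline assumes dense square similarity matrices in memory
  (O(n_t²)); comfortable to a few thousand targets, not designed for
  proteome scale.
- Live database retrieval (TCMSP, HERB, UniProt, PubChem, String) is out
  of scope; inputs are the documented on-disk formats.
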