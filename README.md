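# rwrhe

Network-pharmacology association prediction for herbal medicine:
entropy-weighted similarity fusion and random walks with restart on an
ingredient–target heterogeneous network.

Medicinal herbs contain many active ingredients that act on many protein
targets at once. Given a sparse set of known ingredient–target
associations, `rwrhe` predicts new associations, scores each ingredient's
relevance to a disease defined by a set of seed targets, and ranks whole
herbs and multi-herb compound formulas by the ranks of their member
ingredients. It is aimed at computational pharmacologists and systems
biologists who have association tables, SMILES, protein sequences and
interaction-confidence edge lists, and want a reproducible scoring
pipeline rather than database plumbing.

## Method

Let A ∈ {0,1}^(n_r×n_t) be the known ingredient–target association matrix.

**Similarity measures.** Ingredients: S_r1, the Tanimoto similarity of
2048-bit Morgan fingerprints sharpened by the logistic map
L(s) = 1/(1 + e^(cs+d)) with c = −15, d = log 9999 (so L(0) = 10⁻⁴ and
L(0.3) < 0.01); and S_r2, the Gaussian interaction-profile (GIP) kernel
exp(−γ‖IP(i) − IP(j)‖²) on the rows of A, with bandwidth
γ = γ′ / mean‖IP‖². Targets: S_t1, Smith–Waterman local-alignment scores
normalized as SW(i,j)/√(SW(i,i)·SW(j,j)); S_t2, interaction confidence
scores placed directly in a matrix; S_t3, degree-weighted common-neighbor
similarity Σ_z 1/k(z) over shared neighbors in the graph of edges with
confidence > 0.4 (values > 1 capped at 0.99); and S_t4, the GIP kernel on
the columns of A.

**Entropy fusion.** Each measure m gets weight
ω_m = (1/E_m) / Σ_n (1/E_n), where E_m is the mean Shannon entropy
(natural log) of its row-normalized rows — structured, low-entropy
measures dominate. The fused matrices are S_r = Σ ω_m S_rm and
S_t = Σ ω_m S_tm.

**Walks.** After two-step Laplacian normalization (divide by
√(D_i D_j), then row-normalize) and global-sum normalization
A′ = A/ΣA, two independent restart recursions are iterated from
RT₀ = A′ with restart probability α = 0.3:

    leftRT_t  = α·RT_{t−1}·S_t″ + (1−α)·A′
    rightRT_t = α·S_r″·RT_{t−1} + (1−α)·A′

to elementwise max-abs residual < 10⁻⁶; the prediction is
RT = (leftRT + rightRT)/2. Disease–target scores come from a random walk
with restart P_t = α·(S_t″)ᵀ·P_{t−1} + (1−α)·P₀ started uniformly on the
seed targets. Disease–ingredient scores are P_r = RT·P, ingredients are
ranked by P_r, and a herb or compound k scores H_k = Σ_{i∈k} 1/rank(i).

Two ablation variants support evaluation: `no_gip` (drop S_r2 and S_t4,
reweight the rest) and `equal_weights` (keep all measures, uniform
weights).

## Worked example

Generate a synthetic bundle with planted block structure (60 ingredients ×
80 targets in 4 blocks; block-0 targets are the disease seeds and block-0
ingredients the positive controls), evaluate all variants, and rank the
compound formulas:

```
$ rwrhe synth --out-dir demo/bundle
wrote bundle to demo/bundle
$ rwrhe eval --in-dir demo/bundle --out-dir demo/out
      variant  auc
         full  1.0
       no_gip  1.0
equal_weights  1.0
$ rwrhe rank --in-dir demo/bundle --out-dir demo/out --level compound
$ head -3 demo/out/compound_ranking.tsv
compound_id	score	rank
CMP01	2.092476968	1
CMP00	1.337916018	2
```

AUC 1.0 means the walk ranks every positive-control ingredient above every
negative control — the planted association signal is fully recovered.
CMP01's effect score 2.09 is the sum of the reciprocal disease-ranks of
the ingredients in its member herbs; it ranks first because its herbs draw
mostly from the disease block. On matched null bundles (within-block
association rate equal to background) the AUC falls to ≈ 0.5.

Other subcommands: `rwrhe similarity` (per-measure matrices),
`rwrhe fuse` (entropy table and weights), `rwrhe walk` (the RT matrix),
`rwrhe disease-score` (the P vector). All accept `--config config.yaml`
and `--variant {full,no_gip,equal_weights}`.

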