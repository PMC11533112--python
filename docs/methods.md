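# Methods

This note records the model as implemented, the defaults and why they are
what they are, and the choices made where the design was genuinely open.

## Problem setting

Given molecules as attributed graphs (atoms/bonds with categorical
features), the package learns, without supervision, a soft partition of
every molecule's atoms into K substructure classes shared across the
whole dataset, such that (i) each substructure is tightly connected,
(ii) instances of one class look alike across molecules, and (iii) the
resulting substructure embeddings improve downstream property
prediction.  K is a global hyper-parameter, not per-molecule: atoms of a
molecule assigned the same class form that molecule's instance of the
class.

## Featurization

Heavy-atom graphs; hydrogens appear only as a total-H count feature.
Atom features: element one-hot over {C, N, O, F, P, S, Cl, Br, I} plus an
"other" bucket, degree one-hot (0–5), formal charge, hybridization
one-hot, aromaticity flag, total-H one-hot (0–4), chirality tag one-hot.
Bond features: bond-type one-hot (single/double/triple/aromatic),
conjugation, ring membership, stereo one-hot.  All lists are
configurable; the feature dimensions d₁/d₂ are derived from the config.
The synthetic generator emits vectors through the same scheme, so
generated graphs and parsed molecules are interchangeable to the encoder.

## Encoder

An edge-conditioned attention MPNN (the family that includes the
gated-attention molecular encoders common in MPP).  Per layer, a directed
edge (j→i) carries the key h_j + e_ij (projected edge embedding), scores
are LeakyReLU of a learned linear form of (transformed) destination state
and key, normalized by a per-destination softmax, and the state update is
ELU(W_self·h_i + Σ α_ij·W·key).  The encoder is permutation-equivariant
by construction (verified by test).  Defaults d = 128, L = 3 layers,
dropout 0.1 for real-data work; the scaled-down study below uses d = 32,
L = 2, dropout 0 — small motifs need a receptive field about the motif
radius, and deeper stacks let neighbouring-motif context leak into every
node, which *hurts* cross-molecule class consistency (observed
empirically as rising modularity but falling recovery).

## Partitioner and pooling

s_i = softmax(MLP(h_i)/τ₁) with a 2-layer MLP.  The temperature divides
the logits (the only reading under which τ₁ controls peakedness; the
printed form with the divisor outside both exponentials would cancel).
Default τ₁ = 1.0.

Substructure embeddings support two pooling modes:

* `soft` — Z = (SᵀH) ⊘ rep(Sᵀ1, d), every atom contributes to every
  class with its assignment probability.  This is the algebraic form of
  the pooled mean and the contract of the public `pool_substructures`
  operator (tested against a group-by weighted-mean oracle).
* `member` (model default) — average pooling of the atoms *inside* each
  substructure: only atoms whose top class is c contribute to z_c, with
  their soft weights renormalized; a class with no member atoms is absent
  (zero row, masked out of the clustering losses and prototype updates).
  Rationale: with fully soft pooling every class is nominally "present"
  in every molecule and the contrastive objective can be satisfied by
  mixture-weighting atoms to synthesize each prototype from arbitrary
  node sets — no partition structure required.  Member pooling makes
  z_c a genuine mean of the atoms in the instance, which is also the only
  reading under which classes that do not occur in a molecule are
  naturally zero vectors.  Both modes are config-switchable.

A class is "present" when its pooled mass exceeds ε = 1e-6 (guards the
division).

## Self-supervised objective

L_ss = γ·(L_p + β·L_d) + (1 − γ)·(−Q + α·L_o), defaults α = β = 1,
γ = 0.5.

**Modularity** Q = (1/2m)·Tr(Sᵀ(A − ddᵀ/2m)S) is a quantity to maximize;
the connectivity loss uses its negation so every term is minimized.
Edgeless graphs get Q = 0 with a warning.  The implementation is tested
to 1e-8 against an explicit double-sum oracle and, for hard partitions,
against networkx's community modularity.

**Orthogonality scope.**  L_o = (√K/n)·‖Σᵢ sᵢ‖ − 1 is evaluated, by
default, over *all atoms in the mini-batch* rather than per molecule
(the per-molecule average is available behind
`self_supervised_loss(..., orthogonality="graph")`).  This is the single
most consequential choice in the package.  Per-molecule balance demands
that every molecule spread its atoms over all K classes; when K is
comparable to the number of substructures per molecule this directly
rewards splitting chemically heterogeneous substructures (the C and the
two O's of a carboxyl) into element-wise classes, and in controlled
experiments on planted motifs it capped node-level recovery at ARI ≈ 0.2.
Batch-level balance keeps the anti-collapse effect — class usage must
even out across the dataset — while leaving each molecule free to use
only the classes its substructures need; recovery jumps to ARI ≈ 0.9
under otherwise identical conditions.  The balance regularizer in the
spectral-clustering literature this term descends from is likewise
computed over the full set of nodes being clustered.

**Prototypes** are non-parametric K×d vectors updated after each
optimizer step by p_c ← μ·p_c + (1−μ)·(batch mean of present class-c
instances), μ = 0.99; no gradient flows into the bank.  Initialization:
k-means centroids (seeded, scikit-learn) of the first batch's node
embeddings.  The naive alternative — first-batch class means — is
degenerate at initialization: assignments start near-uniform, so every
class mean collapses to the global embedding mean and the contrastive
objective begins with K indistinguishable anchors.  K-means gives K
genuinely distinct anchors aligned with the embedding geometry.  The
batch-means variant remains available (`prototype_init="batch_means"`).

**Contrastive and compactness terms** operate on present instances only
(cosine similarity to a zero vector is undefined): InfoNCE over cosine
similarities to the K prototypes at temperature τ₂ = 0.1, plus
(1 − s(z, p_c))².  Closed-form checks: the aligned-orthogonal
construction gives −log(e/(e+K−1)) at τ₂ = 1, all-equal similarities give
log K, K = 1 gives 0.

## Fine-tuning

Readout g = mean over node embeddings (sum available).  Cross-scale
attention: per head m, scores σ(aᵀ[W_m g ‖ W_m z_i]) over all K slots
(absent slots included in the softmax, as the sum runs over all K; a mask
is available), softmax over slots, heads concatenated after an ELU;
M = 4 heads, LeakyReLU(0.2) for scores.  Prediction MLP on [g ‖ g′]
(dimension d + M·d; d alone under the no-attention ablation).
Classification: per-task 2-way softmax; the positive-class component
feeds a focal loss with α_t = 0.25 and γ_t set per task to the fraction
of negative training labels; missing labels are masked, losses sum over
samples and average over tasks with at least one observed label.
Regression: masked MSE.  The joint objective is
λ·L_sup + (1−λ)·L_ss with λ = 0.5; prototype updates continue during
fine-tuning unless frozen.

## Training

Adam (weight decay 0), cosine-annealed learning rate from the configured
peak to a floor of 1e-5, global-norm gradient clipping at 5, batch 128
by default.  Defaults: 100 pre-training epochs, 200 fine-tuning epochs
with early stopping (patience 30) on validation ROC-AUC (max) or RMSE
(min); the best snapshot is restored.  All randomness flows from one
seed; fixed seed on one device reproduces epoch-1 losses exactly.
NaN losses abort with a diagnostic.  An optional τ₁ annealing schedule
(soft → sharp across pre-training) is available but off by default — with
batch-scope orthogonality it proved unnecessary.

Splits are 8:1:1 (rounding toward train) either uniformly at random or
by Bemis–Murcko scaffold, where scaffold groups are sorted by (size
descending, scaffold string) and assigned greedily to the subset with
most remaining capacity, so one scaffold never straddles subsets.

## Synthetic study conditions

The planted-motif generator is the package's test bed: motifs of 3–6
nodes with categorical attributes from the featurization vocabulary
(carbon path, carboxyl-like O=C–O, amine-like N(C)(C)C, carbon triangle,
thiocarbonyl-like, benzene-like ring, hydrazine-like N–N–C, dioxane-like
ring), 2–4 motifs per graph joined in a chain by single bridge edges
(sparse inter-motif connectivity), uniform motif sampling.  Templates 0
and 3 are attribute-identical but topology-distinct (C path vs C
triangle), so class recovery requires context, not atom attributes alone.
Binary labels mark the presence of a designated motif class (optional
flip noise); regression labels are a linear function of motif counts
(optional Gaussian noise).  Everything is reproducible from one seed.

The scaled-down recovery study used throughout the tests: 200 graphs,
4 motif classes, K = 4, encoder d = 32, L = 2, batch 16, learning rate
5e-3, 40 pre-training epochs, 3 seeds — sizes chosen so the whole study
runs in well under a minute on one CPU.  Under these conditions median
node-level ARI against planted labels is ≈ 0.9 (threshold 0.6; chance is
|ARI| < 0.02), and fine-tuning the presence task reaches test ROC-AUC
1.0.  What this does and does not show: the generator reproduces the
structural premise of the method (dense motifs, sparse boundaries,
shared classes) but not the full heterogeneity of real chemistry — no
valence constraints, no fuzzy substructure boundaries, no label noise
from assay error; passing it demonstrates the machinery optimizes its
objectives and recovers structure where structure is plainly there, not
benchmark performance on real MPP datasets.

## Numerical choices

float64 throughout; cosine similarities floor their norms at 1e-12;
probabilities are clamped to [1e-7, 1−1e-7] inside the focal loss
(saturated softmax values silently, genuinely out-of-range inputs with a
warning); argmax ties break toward the lowest class index; the
per-segment max is subtracted (as a constant) inside segment softmax.
Checkpoints are .npz archives of float64 parameter arrays plus a JSON
config fingerprint, giving bit-stable round trips and load-time
compatibility checks.

## Known limitations

* The autodiff engine is minimal by design (no GPU, no fused kernels);
  practical problem sizes are thousands of small graphs, not the
  40k-molecule pre-training corpora of production MPP systems.
* K is global and fixed; there is no mechanism to merge or split classes
  during training.
* Substructure instances are defined by shared class membership within a
  molecule; two disconnected same-class motifs in one molecule pool into
  a single instance embedding.
* The supplementary feature tables of the encoder lineage are not
  reproduced verbatim; the documented defaults above stand in for them.
* Scaffold splitting uses the standard Bemis–Murcko SMILES; molecules
  without rings share the empty scaffold and travel together.
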