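# Methods

## Model

`spagnet` learns two coupled graphs from one SRT slice: a gene–gene
attention network S (M × M) and a spot–spot manifold graph Z (N × N).
Input is the log-transformed expression matrix X₁ (genes × spots); all
training is self-supervised — no labels, annotations or marker lists.

### Spatially local graph B

Spot neighbourhoods are Euclidean k-nearest neighbours on the array
coordinates (k = 10 by default, appropriate for Visium-scale arrays;
k = 30 is the recommended setting for near-cellular platforms). For
multi-slice 3-D data, all slices are projected along z into a common x–y
plane and each spot's candidates are restricted to its own and the two
adjacent slices (window ±1); ties are broken by spot index. Edge weights
come from PCA embeddings U of expression (50 components by default,
capped at the data rank):

    D_ij = exp(2 − dist(U_i, U_j) / (‖U_i‖·‖U_j‖)),  B_ij = D_ij / Σ_i D_ij,

computed on the kNN support only (the column normalisation runs over the
sparse support; self-weights are excluded). **Embedding columns are
rescaled to unit length before the formula is applied.** The exponent
then equals 2 minus the chord distance and spans its full [0, 2] range;
without this the ratio collapses toward 0 for any embedding of moderate
norm and the weights lose nearly all contrast between similar and
dissimilar neighbours (we measured within-domain vs cross-domain weight
ratios of ~1.5 raw versus ~5 normalised on synthetic data, the difference
between failing and exact domain recovery). A `normalize=False` flag
restores the raw reading, and a `metric="cosine"` switch replaces the
distance with an inner product for users who prefer that reading of the
similarity bracket.

### Gene-level attention stack

Genes are tokens; a gene's feature vector is its expression across the N
spots of the training token (weights are therefore sized to a fixed
token width; smaller tokens are zero-padded). Three encoder units with
five heads each are the default. Per unit:

1. queries and keys are projected from per-gene LayerNorm-normalised
   profiles (so attention logits compare standardized expression
   patterns); values are projected from the raw input so the output keeps
   expression scale;
2. per head, `S_t = softmax(Q_t K_tᵀ/√d_t)`; during pretraining the prior
   adjacency is added (`+ μA`, μ = 0.2) and rows are renormalised to sum
   one — row renormalisation is our reading of the unspecified
   `Normalize(·)`, chosen so each map stays a stochastic (convex-mixing)
   operator; in fine-tuning μ = 0;
3. the head width is d_t = ⌈N/Γ⌉, so **concatenating the Γ head outputs
   spans the full feature width directly — there is no output projection
   and no residual bypass around the attention mix**;
4. a two-layer ELU feed-forward sublayer with a residual connection
   closes the unit.

Design rationale for (3): the augmented view X₂ produced by the stack is
pulled toward X₁'s representations by the contrastive and alignment
losses. If the architecture offers any path around the attention mix (an
output projection or an additive residual), the objective is minimised by
routing reconstruction through that path, the attention contribution is
free to vanish, and weight decay then flattens the maps toward
uninformative uniformity — we observed exactly this (edge-ranking AUROC
decaying to or below chance with training). With load-bearing attention
the only way to reconstruct a gene is to mix genes with similar profiles,
which pins the maps to the co-expression structure the method is built to
read out.

Initialisation: W_Q = W_K (scaled by a gain of 0.3 over Xavier), making
the initial logits a positive-semidefinite quadratic form of the
normalised profiles — i.e. the initial attention is a symmetric
profile-similarity map, the model's own "expression is reconstructible
from co-expressed genes" assumption; W_V starts at identity plus small
noise so each unit initially emits attention-smoothed expression.
Training refines all of these; every initialisation draws from a seeded
generator.

The aggregated network S is the arithmetic mean of all (unit, head) maps
from a deterministic forward pass at convergence (a `scale="printed"`
option divides the plain sum by Γ + Y instead; the two differ by a
positive constant, so ranked edge lists are identical). S is read with
regulators on rows. Positional encodings P = (Ũ‖Ṽ)·W_PE, with Ũ = U√Σ
and Ṽ = V√Σ from the top-r SVD of the prior adjacency (r = 8 by default)
and W_PE learned, are added to the stack input whenever a prior is
attached.

### Spot-level manifold VAE

A two-layer encoder (128 hidden units, ELU) maps each spot to a 10-d
Gaussian latent (mean and log-variance heads); a mirrored two-layer
decoder reconstructs the spot, giving L = 4 layer representations per
view. Weights are shared between the X₁ and X₂ views. The ELBO is the
standard Gaussian form — squared-error reconstruction (unit-variance
Gaussian likelihood, summed over genes, averaged over spots) plus the
analytic KL to N(0, I) — with the reconstruction computed from a
reparameterised sample and the layer representations taken along the
deterministic mean path (which also feeds all alignment losses). The
layer sums in the manifold, contrastive and alignment losses run over
layers 1..L; the raw inputs (layer 0) are excluded.

The manifold term ties every layer to the learnable graph Z:

    L_manifold = (1/L) Σ_i Σ_views ‖H⁽ⁱ⁾(I + αB) − H⁽ⁱ⁾Z‖²_F / ‖H⁽ⁱ⁾‖_F,

with α = 1 by default. Z is initialised at I + αB. Because that point is
an exact zero of the residual, no other loss term involves Z, and Z is
excluded from weight decay, **Z remains at its anchor during
fine-tuning**: the learned spot graph equals the expression-weighted
spatial graph, and the manifold term acts as a regulariser that keeps
every layer representation compatible with it (any drift of the
representations away from the anchored geometry is penalised). Users who
want Z to depart from the anchor can initialise it differently; the loss
then drives it back toward the anchor's action on the layer span.

### Distribution alignment

MMD uses the fixed Gaussian kernel K(x, y) = exp(−‖x−y‖²/2) (no median
heuristic — the kernel is part of the model definition) and the biased
V-statistic estimator; the implementation supports unequal sample sizes
(1/n², 2/nm, 1/m² weighting) although both views always share the same
spots here. Global alignment averages the MMD between the views' spot
distributions over layers; local alignment averages it over every spot's
kNN neighbourhood and layer; the contrastive term is
‖H₁⁽ⁱ⁾ − H₂⁽ⁱ⁾‖²_F / ‖H₁⁽ⁱ⁾ + H₂⁽ⁱ⁾‖ averaged over layers (a zero
denominator skips the layer with a warning). Total objective:

    L = L¹_ELBO + L²_ELBO + λ₁·L_manifold + λ₂·(L_CL + L_GD + L_SLD),

λ₁ = 1.0, λ₂ = 0.1 by default; both exposed.

### Optimisation

Adam with decoupled weight decay (10⁻²; applied to weight matrices only,
never biases or Z) at learning rate 10⁻³ with a linear warmup (20 steps
by default — warmup is scaled to desk-size runs in proportion to their
step counts). Fine-tuning runs full-batch epochs until the relative
total-loss change stays below 10⁻⁴ for 20 consecutive epochs, or a
maximum of 300 epochs. Pretraining splits each slice into spot tokens
(3000 by default), trains tokens sequentially with parameters carried
forward, reshuffles token order between passes, and stops when the
relative Frobenius change of S between passes falls below 10⁻³. Weight
initialisation, VAE sampling and token shuffling consume independent
seeded streams derived from the config seed; fixed-seed runs are
bit-identical, and HDF5 checkpoints restore forward passes exactly. A
non-finite loss aborts the loop at the last good state.

All numerics run in float64 on the package's reverse-mode autodiff core
(`spagnet._tensor`), whose gradients are verified against central
differences in the test suite; the Gaussian-kernel double sums are fused
ops with analytic gradients.

## Downstream

- **Regulons**: per TF, the top-k targets by the TF's row of S (k = 50,
  minimum 10 targets by default; ties broken by gene id). On small gene
  panels both parameters should be scaled down (the examples use top-3
  with minimum 1 on a 20-gene panel). A motif-pruning interface accepts
  any backend with a `verdicts(tf, targets)` method; the shipped
  pass-through stub keeps all targets and logs a notice — connecting a
  real cis-regulatory motif database is the user's responsibility.
- **Activity**: per spot, genes are ranked by descending expression (ties
  by gene id, which perturbs activities by less than 1/M per tie); the
  activity is the recovery-curve area of the regulon's genes up to rank
  ⌈threshold·M⌉, normalised to [0, 1]. The default threshold is the
  conventional top-5%; on panels of tens of genes a coarser cutoff (e.g.
  25%) is advisable since 5% of 20 genes is a single rank.
- **Clustering**: Leiden (RBConfiguration partition, seeded) on the
  symmetrised, negative-clipped Z with the diagonal removed; resolution
  1.0 by default, or found by bisection to match a known number of
  annotated structures.
- **Specificity**: one-vs-rest log₂ fold change of mean activity (with a
  10⁻⁹ pseudocount) and Mann–Whitney AUROC per (regulon, cluster); the
  default filter keeps log₂FC > 0.25 and AUROC > 0.75, with an AUROC-off
  mode for high-resolution data. Singleton clusters are flagged rather
  than scored.
- **Evaluation**: AUROC (mid-rank tie handling, equal to the trapezoidal
  ROC area) and average-precision AUPRC over a candidate-edge universe
  (TF rows when a TF list is given, all ordered pairs otherwise; edges
  are scored directed, with an undirected comparison available by
  symmetrising S upstream); consecutive-run Spearman and top-k Jaccard
  stability; Moran's I with binary symmetrised kNN weights by default
  (B-weighted mode available); pair-counting ARI.

## Synthetic benchmark generator

The generator emulates the standard simulation design for SRT-GRN
benchmarking: expression at single-cell resolution from a planted
network, then binning of similar cells into spatially arranged spots.

- **Network**: two-layer TF → target topology; every non-TF gene has at
  least one regulator; ~3 targets per TF; 20% of the optional extra edges
  are repressive. Regimes (default 3) switch distinct TF subsets on in a
  round-robin pattern.
- **Dynamics**: per cell, Euler–Maruyama integration (200 steps, dt 0.1)
  of dx_g/dt = v·Hill(regulators) − x_g + σ dW for targets (Hill
  coefficient 2, K = 1, v = 2; multiple regulators average their Hill
  terms, repressors contribute 1 − Hill) and a per-cell lognormal basal
  rate for active TFs (median 2, σ_log = 0.4 — this within-regime
  variability is what propagates TF fluctuations to targets and creates
  the correlation signal a GRN method must read). Noise σ = 0.1;
  trajectories are clipped at zero. These constants were fixed once as a
  realistic stationary regime for a log-scale expression range of ~0–3.
- **Binning**: cells are embedded on two principal components, ordered
  within each regime, and pooled (default 4 cells per spot, summed) into
  spots on a square grid. `grid_blocks` gives each regime a contiguous
  vertical band (domains are spatially contiguous by construction);
  `gradient` mixes regimes along x with 15% label noise, for testing
  spatial-continuity metrics on non-block layouts. Cells are oversampled
  by 1.5× so every regime can fill its quota.

What the generator does *not* emulate: count noise and dropout (values
are continuous concentrations, not UMI counts), platform-specific capture
efficiency, multi-cell-type spot mixtures, cell–cell communication, or
batch effects. Passing the recovery tests therefore shows the
architecture extracts planted co-expression and spatial structure
correctly, not that it meets any particular accuracy on real tissue.

## Reference study conditions and problem sizes

The acceptance suite and `scripts/acceptance.py` use 20 genes / 5 TFs /
3 regimes with 500 spots for network recovery (fine-tuned 100 epochs)
and 300 spots for domain recovery, descent and spatial-coherence checks
(60 epochs), 3–5 seeds per check. These sizes make a full run of the
pipeline a few CPU-minutes while leaving all mechanisms (attention,
manifold, alignment, clustering) active at realistic ratios of genes to
spots for a targeted panel.

## Known limitations

- Trained attention tracks co-expression; without motif pruning the
  network contains indirect edges by construction, and edge direction
  between correlated pairs is not identified from expression alone.
- Z does not move from its anchor under the default initialisation (see
  above); clustering quality is that of the expression-weighted spatial
  graph.
- Transformer weights are sized to the token width, so pretrained
  checkpoints transfer only to runs with the same token size and gene
  panel; the 31k-gene full-vocabulary setting is out of scope here.
- The ±1-slice window and index-based tie-breaks are conventions, not
  fitted choices.
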