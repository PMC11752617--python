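# spagnet

Joint inference of **spatial gene regulatory networks** and **tissue
domains** from spatially resolved transcriptomics (SRT), for computational
biologists who want context-specific TF–target networks without cell-type
annotations.

Single-cell GRN methods ignore where a cell sits in the tissue, yet the
same cell type can run different regulatory programs in different niches.
`spagnet` couples two learners through one self-supervised objective:

- **Gene dimension** — a multi-head self-attention stack over genes
  (tokens = genes, features = a gene's expression across spots). Each unit
  computes head maps

  `S_t = Normalize( softmax(Q_t K_tᵀ / √d_t) + μA )`,

  mixes value projections through them, and the concatenated heads
  reconstruct the augmented expression X₂ from the original X₁ ∈ R^{M×N}.
  The maps averaged over every (unit, head) form the gene–gene weight
  matrix **S**, read as regulator (row) → target (column). A prior
  interaction network A biases the maps during pretraining (μ = 0.2) and
  supplies SVD positional encodings; fine-tuning sets μ = 0.
- **Spot dimension** — a variational autoencoder with weights shared
  between the X₁ and X₂ views, constrained by a self-expressive manifold
  graph **Z** ∈ R^{N×N} anchored to the spatially local graph B:

  `L_manifold = (1/L) Σᵢ ‖H⁽ⁱ⁾(I + αB) − H⁽ⁱ⁾Z‖²_F / ‖H⁽ⁱ⁾‖`

  where B weights each spot's k nearest spatial neighbours by expression
  similarity, `B_ij = D_ij / Σᵢ D_ij` with
  `D_ij = exp(2 − dist(U_i, U_j)/(‖U_i‖‖U_j‖))` on PCA embeddings U.
- **Alignment** — the two dimensions are tied by maximum mean discrepancy
  (Gaussian kernel `exp(−‖x−y‖²/2)`) between the views' layer
  distributions, globally and within each spot's spatial neighbourhood,
  plus a contrastive per-spot term. The overall objective is

  `L = L₁_ELBO + L₂_ELBO + λ₁ L_manifold + λ₂ (L_CL + L_align_GD + L_align_SLD)`.

Downstream, S is decomposed into **regulons** (a TF plus its top-weighted
targets, optionally pruned through a motif-backend interface), per-spot
regulon activity is scored by a rank-based recovery-curve area
(AUCell-style), spots are clustered by **Leiden** on the symmetrised Z,
and domain-specific regulons are filtered at log₂FC > 0.25 and
AUROC > 0.75. Evaluation utilities cover edge-ranking AUROC/AUPRC,
Spearman/Jaccard run stability, Moran's I spatial autocorrelation and ARI.

A built-in generator produces desk-scale SRT benchmarks with planted
ground truth: stochastic Hill-kinetics dynamics on a random TF→target
network, cells binned into contiguous spatial domains (one regulatory
regime per domain).

## Worked example

```bash
python examples/infer_grn.py
```

```
trained 60 epochs; total loss 84.59 -> 13.89
edge-ranking AUROC 0.937, AUPRC 0.732 (shuffled-truth control 0.641)
top 5 predicted edges: [('G02', 'G12', 0.1941), ('G02', 'G07', 0.1912), ...]
```

On a 20-gene / 5-TF / 300-spot benchmark the fine-tuned attention matrix
ranks planted TF→target edges far above random pairs (AUROC 0.94; a
degree-preserving shuffle of the truth scores near chance), and the top
predicted edges are genuine planted interactions.

```bash
python examples/spatial_domains.py
```

```
found 3 clusters at resolution 0.250
adjusted Rand index vs planted domains: 1.000
```

Leiden on the learned spot graph recovers the three planted tissue
domains exactly. `examples/regulon_activity.py` continues the pipeline:
the planted regulon's AUCell activity has Moran's I 0.88 versus 0.57 for
a random gene set, and every TF regulon passes the specificity filter in
exactly the domain where its regime is active.

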