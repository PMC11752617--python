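"""Cross-dimensional model: gene transformer + manifold VAE + alignment.

Bundles the two dimension-specific networks with the learnable spot graph
Z and evaluates the overall training objective on an input bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from . import alignment
from .alignment import LossReport, LossWeights
from .data_io import ExpressionMatrix, PriorNetwork
from .gene_transformer import (AttentionNetwork, GeneTransformer,
                               TransformerConfig, aggregate_attention)
from .manifold_vae import (ManifoldGraph, ManifoldVAE, VAEConfig, elbo_loss,
                           initial_manifold, manifold_loss)
from .spatial_graph import SpatialGraph


@dataclass
class DataBundle:
    """Everything one training run needs for a single slice."""

    expression: ExpressionMatrix          # log-scale, genes x spots
    graph: SpatialGraph                   # spatially local graph B
    prior: PriorNetwork | None = None     # gene network A (pretraining)

    def __post_init__(self) -> None:
        if self.graph.n_spots != self.expression.n_spots:
            raise ValueError("spatial graph does not match expression spots")
        if (self.prior is not None
                and self.prior.adjacency.shape[0] != self.expression.n_genes):
            raise ValueError("prior network does not match gene count")


def prepare_bundle(expr: ExpressionMatrix, coords, k: int = 10,
                   n_pcs: int = 50, prior: PriorNetwork | None = None,
                   n_hvg: int | None = None, seed: int = 0) -> DataBundle:
    """Standard preprocessing pipeline: (optional HVG) log1p, PCA, spatial
    kNN and the weighted graph B, assembled into a training bundle."""
    from .data_io import preprocess
    from .spatial_graph import build_spatial_graph, knn_neighbors, pca_embedding

    if not expr.is_log:
        expr = preprocess(expr, n_hvg=n_hvg)
    embed = pca_embedding(expr, n_pcs=n_pcs, seed=seed)
    neighbors = knn_neighbors(coords, k=k)
    graph = build_spatial_graph(embed, neighbors, k=k)
    return DataBundle(expression=expr, graph=graph, prior=prior)


class CrossDimModel:
    """Joint model over a fixed gene count and feature (spot-token) width."""

    def __init__(self, n_genes: int, n_features: int,
                 transformer_config: TransformerConfig | None = None,
                 vae_config: VAEConfig | None = None,
                 weights: LossWeights | None = None,
                 seed: int = 0):
        self.n_genes = n_genes
        self.n_features = n_features
        self.weights = weights or LossWeights()
        self.transformer = GeneTransformer(
            n_genes, n_features, config=transformer_config, seed=seed)
        self.vae = ManifoldVAE(n_genes, config=vae_config, seed=seed + 1)
        self.z: Tensor | None = None  # created per bundle (N x N)
        self._z_alpha = self.weights.alpha

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        params = {f"transformer.{k}": v
                  for k, v in self.transformer.params.items()}
        params.update({f"vae.{k}": v for k, v in self.vae.params.items()})
        if self.z is not None:
            params["Z"] = self.z
        return params

    def init_manifold(self, graph: SpatialGraph) -> None:
        """(Re)create Z = I + alpha * B for a bundle's spot set."""
        self.z = Tensor(initial_manifold(graph.B, self.weights.alpha),
                        requires_grad=True)

    def attach_prior(self, prior: PriorNetwork, seed: int = 0) -> None:
        self.transformer.attach_prior_encoding(prior, seed=seed)

    # -- objective ------------------------------------------------------------

    def _padded(self, x: np.ndarray) -> np.ndarray:
        """Zero-pad the spot axis up to the model's feature width."""
        m, n = x.shape
        if n == self.n_features:
            return x
        if n > self.n_features:
            raise ValueError(f"bundle has {n} spots but model width is "
                             f"{self.n_features}")
        out = np.zeros((m, self.n_features))
        out[:, :n] = x
        return out

    def loss(self, bundle: DataBundle, mu: float,
             rng: np.random.Generator) -> tuple[Tensor, LossReport]:
        """Evaluate the overall objective on one bundle (one step)."""
        if self.z is None or self.z.shape[0] != bundle.graph.n_spots:
            self.init_manifold(bundle.graph)
        x1 = bundle.expression.values
        n = x1.shape[1]
        prior_a = bundle.prior.adjacency if bundle.prior is not None else None
        x2_full, all_heads = self.transformer.forward(
            self._padded(x1), prior_a=prior_a, mu=mu)
        if n != x2_full.shape[1]:  # drop padding columns for the spot-level path
            from . import _tensor as tz
            x2 = tz.take(x2_full, np.arange(n), axis=1)
        else:
            x2 = x2_full

        c = self.vae.config
        eps1 = rng.standard_normal((c.latent_dim, n))
        eps2 = rng.standard_normal((c.latent_dim, n))
        f1 = self.vae.forward(x1, eps=eps1)
        f2 = self.vae.forward(x2, eps=eps2)

        elbo1 = elbo_loss(Tensor(x1), f1.reconstruction, f1.mean, f1.logvar)
        elbo2 = elbo_loss(x2.detach(), f2.reconstruction, f2.mean, f2.logvar)
        mani = manifold_loss(f1.layers, f2.layers, self.z, bundle.graph.B,
                             self.weights.alpha)
        gd = alignment.align_global(f1.layers, f2.layers)
        sld = alignment.align_local(f1.layers, f2.layers,
                                    bundle.graph.neighbor_sets)
        contrast = alignment.contrastive(f1.layers, f2.layers)
        total = alignment.total_loss(elbo1, elbo2, mani, contrast, gd, sld,
                                     self.weights)
        if not np.isfinite(total.data).all():
            raise FloatingPointError("non-finite total loss")
        report = alignment.report_from_components(
            elbo1, elbo2, mani, contrast, gd, sld, total)
        self._last_heads = all_heads
        return total, report

    # -- outputs --------------------------------------------------------------

    def attention_network(self, bundle: DataBundle, mu: float = 0.0,
                          scale: str = "mean") -> AttentionNetwork:
        """Aggregated gene-gene network S from a fresh deterministic pass."""
        prior_a = bundle.prior.adjacency if bundle.prior is not None else None
        _, all_heads = self.transformer.forward(
            self._padded(bundle.expression.values), prior_a=prior_a, mu=mu)
        return aggregate_attention(all_heads, bundle.expression.gene_ids,
                                   scale=scale)

    def manifold_graph(self) -> ManifoldGraph:
        if self.z is None:
            raise ValueError("manifold graph not initialised")
        return ManifoldGraph(Z=self.z.data.copy(), alpha=self.weights.alpha)
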