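"""Deep spatial distribution alignment losses.

Three terms couple the gene-level transformer to the spot-level VAE by
comparing layer representations of the original (H1) and augmented (H2)
views, with spots as the samples:

* global alignment — mean over layers of the maximum mean discrepancy
  (MMD) between the two views' spot distributions;
* spatially local alignment — the same MMD restricted to every spot's
  spatial neighbourhood, averaged over layers and spots;
* contrastive term — a normalised Frobenius gap that pins each spot's
  representation across views (distribution alignment alone would allow
  per-spot drift).

The MMD uses the fixed Gaussian kernel K(x, y) = exp(-||x - y||^2 / 2) and
the biased V-statistic estimator; with samples X = {x_i}, Y = {y_j},

    MMD = (1/n^2) sum K(x_i, x_j) - (2/(n m)) sum K(x_i, y_j)
          + (1/m^2) sum K(y_i, y_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as tz
from ._tensor import Tensor


@dataclass
class LossWeights:
    """Tunable coefficients of the overall objective."""

    lambda1: float = 1.0   # manifold term
    lambda2: float = 0.1   # cross-dimension (alignment + contrastive) block
    alpha: float = 1.0     # spatial anchor inside the manifold term
    mu: float = 0.0        # prior-constraint weight (pretraining only)

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "alpha", "mu"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class LossReport:
    """Per-step loss components (floats, already evaluated)."""

    elbo1: float
    elbo2: float
    manifold: float
    align_gd: float
    align_sld: float
    contrastive: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "elbo1": self.elbo1, "elbo2": self.elbo2,
            "manifold": self.manifold, "align_GD": self.align_gd,
            "align_SLD": self.align_sld, "contrastive": self.contrastive,
            "total": self.total,
        }


def mmd_t(x: Tensor, y: Tensor) -> Tensor:
    """Differentiable biased-estimator MMD between column samples."""
    n = x.shape[1]
    m = y.shape[1]
    if n == 0 or m == 0:
        raise ValueError("MMD of an empty sample set")
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature dimensions differ")
    kxx = tz.gauss_kernel_sum(x, x) * (1.0 / n ** 2)
    kyy = tz.gauss_kernel_sum(y, y) * (1.0 / m ** 2)
    kxy = tz.gauss_kernel_sum(x, y) * (2.0 / (n * m))
    return kxx + kyy - kxy


def mmd(x: np.ndarray, y: np.ndarray) -> float:
    """MMD between two sample sets (columns are samples); clamped at 0
    against the V-statistic's ~1e-12 negative excursions."""
    val = mmd_t(Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64))),
                Tensor(np.atleast_2d(np.asarray(y, dtype=np.float64)))).item()
    return max(val, 0.0)


def align_global(layers1: list[Tensor], layers2: list[Tensor]) -> Tensor:
    """Mean over layers of MMD between the views' spot distributions."""
    if len(layers1) != len(layers2):
        raise ValueError("views have different layer counts")
    total: Tensor | None = None
    for h1, h2 in zip(layers1, layers2):
        term = mmd_t(h2, h1)
        total = term if total is None else total + term
    assert total is not None
    return total * (1.0 / len(layers1))


def _neighbor_index_matrix(neighbors: list[np.ndarray]) -> np.ndarray:
    k = {len(nb) for nb in neighbors}
    if 0 in k:
        raise ValueError("a spot has an empty neighbour set")
    if len(k) != 1:
        raise ValueError("neighbour sets must have equal size for batching")
    return np.stack([np.asarray(nb, dtype=int) for nb in neighbors])


def align_local(layers1: list[Tensor], layers2: list[Tensor],
                neighbors: list[np.ndarray]) -> Tensor:
    """Average over layers and spots of the neighbourhood-restricted MMD.

    Evaluated batched: for layer H (w x N) and the N x k neighbour index
    matrix, per-spot kernel sums are computed over (N, k, k) blocks.
    """
    if len(layers1) != len(layers2):
        raise ValueError("views have different layer counts")
    nb = _neighbor_index_matrix(neighbors)
    n, k = nb.shape
    inv = 1.0 / (k * k)
    total: Tensor | None = None
    for h1, h2 in zip(layers1, layers2):
        g1 = tz.take(h1, nb, axis=1).transpose(1, 2, 0)  # (N, k, w)
        g2 = tz.take(h2, nb, axis=1).transpose(1, 2, 0)
        layer_term = (tz.gauss_kernel_sum(g2, g2)
                      + tz.gauss_kernel_sum(g1, g1)
                      - tz.gauss_kernel_sum(g2, g1) * 2.0) * (inv / n)
        total = layer_term if total is None else total + layer_term
    assert total is not None
    return total * (1.0 / len(layers1))


def contrastive(layers1: list[Tensor], layers2: list[Tensor]) -> Tensor:
    """Normalised per-spot gap between views, averaged over layers."""
    import warnings

    if len(layers1) != len(layers2):
        raise ValueError("views have different layer counts")
    total: Tensor | None = None
    for h1, h2 in zip(layers1, layers2):
        denom = float(np.linalg.norm(h1.data + h2.data))
        if denom == 0.0:
            warnings.warn("skipping contrastive term with zero denominator",
                          stacklevel=2)
            continue
        term = (h1 - h2).frobenius_sq() * (1.0 / denom)
        total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / len(layers1))


def total_loss(elbo1: Tensor, elbo2: Tensor, manifold: Tensor,
               contrast: Tensor, align_gd: Tensor, align_sld: Tensor,
               weights: LossWeights) -> Tensor:
    """Overall objective: manifold-dominated VAE block plus the
    lambda2-weighted cross-dimension block."""
    return (elbo1 + elbo2 + weights.lambda1 * manifold
            + weights.lambda2 * (contrast + align_gd + align_sld))


def report_from_components(elbo1, elbo2, manifold, contrast, align_gd,
                           align_sld, total) -> LossReport:
    def val(t) -> float:
        return float(t.item() if isinstance(t, Tensor) else t)

    return LossReport(elbo1=val(elbo1), elbo2=val(elbo2),
                      manifold=val(manifold), align_gd=val(align_gd),
                      align_sld=val(align_sld), contrastive=val(contrast),
                      total=val(total))
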