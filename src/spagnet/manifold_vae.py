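"""Variational autoencoder over spots with a self-expressive manifold
constraint.

The encoder/decoder weights are shared between the original (X1) and
augmented (X2) views.  Spots are the samples: each column of the M x N
input is encoded through `l` layers to a Gaussian latent (mean / log
variance) and decoded back through `l` layers, giving L = 2l layer
representations H^(1)..H^(L) per view.  The deterministic mean path feeds
the manifold and alignment losses; reparameterised samples feed only the
reconstruction term of the ELBO.

The manifold term ties every layer to a learnable N x N self-expressive
graph Z over spots, anchored to the spatially local graph B:

    L_manifold = (1/L) sum_i  ||H^(i)(I + aB) - H^(i) Z||_F^2 / ||H^(i)||_F
                 summed over both views.

Z is initialised at I + aB, the exact zero of this residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _tensor as tz
from ._tensor import Tensor

DEFAULT_HIDDEN = 128
DEFAULT_LATENT = 10
DEFAULT_ALPHA = 1.0


@dataclass
class VAEConfig:
    hidden_dim: int = DEFAULT_HIDDEN
    latent_dim: int = DEFAULT_LATENT

    @property
    def encoder_depth(self) -> int:
        return 2  # hidden layer + latent layer

    @property
    def total_depth(self) -> int:
        return 2 * self.encoder_depth


@dataclass
class ViewForward:
    """Per-view forward pass results."""

    layers: list[Tensor]          # H^(1)..H^(L), deterministic path
    mean: Tensor                  # latent mean (latent_dim x N)
    logvar: Tensor                # latent log-variance (latent_dim x N)
    reconstruction: Tensor        # decoder output from sampled latent (M x N)


@dataclass
class ManifoldGraph:
    """Learnable N x N spot-spot graph and its spatial anchor weight."""

    Z: np.ndarray
    alpha: float = DEFAULT_ALPHA

    def symmetrized(self) -> np.ndarray:
        """Clustering view of Z: symmetrised, negatives clipped to zero."""
        z = 0.5 * (self.Z + self.Z.T)
        return np.clip(z, 0.0, None)


class ManifoldVAE:
    """Shared-weight encoder/decoder over both expression views."""

    def __init__(self, n_genes: int, config: VAEConfig | None = None,
                 seed: int = 0):
        self.config = config or VAEConfig()
        self.n_genes = n_genes
        c = self.config
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}

        def param(name: str, shape: tuple[int, ...]) -> None:
            scale = 1.0 / np.sqrt(shape[-1])
            self.params[name] = Tensor(rng.normal(0.0, scale, size=shape),
                                       requires_grad=True)

        param("enc.W1", (c.hidden_dim, n_genes))
        self.params["enc.b1"] = Tensor(np.zeros((c.hidden_dim, 1)),
                                       requires_grad=True)
        param("enc.Wmean", (c.latent_dim, c.hidden_dim))
        self.params["enc.bmean"] = Tensor(np.zeros((c.latent_dim, 1)),
                                          requires_grad=True)
        param("enc.Wlogvar", (c.latent_dim, c.hidden_dim))
        self.params["enc.blogvar"] = Tensor(np.zeros((c.latent_dim, 1)),
                                            requires_grad=True)
        param("dec.W1", (c.hidden_dim, c.latent_dim))
        self.params["dec.b1"] = Tensor(np.zeros((c.hidden_dim, 1)),
                                       requires_grad=True)
        param("dec.W2", (n_genes, c.hidden_dim))
        self.params["dec.b2"] = Tensor(np.zeros((n_genes, 1)),
                                       requires_grad=True)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (H^(1) hidden, latent mean, latent log-variance)."""
        p = self.params
        h1 = tz.elu(p["enc.W1"] @ x + p["enc.b1"])
        mean = p["enc.Wmean"] @ h1 + p["enc.bmean"]
        logvar = p["enc.Wlogvar"] @ h1 + p["enc.blogvar"]
        if not np.isfinite(logvar.data).all():
            raise FloatingPointError("non-finite latent log-variance")
        return h1, mean, logvar

    def decode(self, z: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (H^(3) hidden, H^(4) reconstruction), linear output head."""
        p = self.params
        h3 = tz.elu(p["dec.W1"] @ z + p["dec.b1"])
        return h3, p["dec.W2"] @ h3 + p["dec.b2"]

    def forward(self, x: np.ndarray | Tensor,
                eps: np.ndarray | None = None) -> ViewForward:
        """Full pass; `eps` (latent_dim x N standard normals) enables the
        reparameterised sample for the reconstruction term."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        h1, mean, logvar = self.encode(x)
        h3, h4 = self.decode(mean)
        if eps is not None:
            z = mean + tz.exp(logvar * 0.5) * Tensor(eps)
            _, recon = self.decode(z)
        else:
            recon = h4
        return ViewForward(layers=[h1, mean, h3, h4], mean=mean,
                           logvar=logvar, reconstruction=recon)


def gaussian_kl(mean, logvar) -> Tensor:
    """Analytic KL(N(mean, exp(logvar)) || N(0, I)), summed over latent
    dimensions and averaged over spots."""
    mean = mean if isinstance(mean, Tensor) else Tensor(mean)
    logvar = logvar if isinstance(logvar, Tensor) else Tensor(logvar)
    per_entry = (mean * mean + tz.exp(logvar) - 1.0 - logvar) * 0.5
    n_spots = mean.shape[1] if mean.ndim > 1 else 1
    return per_entry.sum() * (1.0 / n_spots)


def elbo_loss(x, reconstruction, mean, logvar) -> Tensor:
    """Gaussian ELBO (negated): squared-error reconstruction summed over
    genes and averaged over spots, plus the analytic KL term."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    reconstruction = (reconstruction if isinstance(reconstruction, Tensor)
                      else Tensor(reconstruction))
    if x.shape != reconstruction.shape:
        raise ValueError("reconstruction shape does not match input")
    n_spots = x.shape[1] if x.ndim > 1 else 1
    resid = x - reconstruction
    recon = resid.frobenius_sq() * (0.5 / n_spots)
    out = recon + gaussian_kl(mean, logvar)
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite ELBO")
    return out


def initial_manifold(b: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Canonical Z initialisation I + alpha * B (the manifold residual's
    exact zero)."""
    n = b.shape[0]
    return np.eye(n) + alpha * b


def manifold_loss(layers1: list[Tensor], layers2: list[Tensor],
                  z: Tensor, b: np.ndarray, alpha: float) -> Tensor:
    """Self-expressive residual of every layer of both views against Z."""
    n = b.shape[0]
    anchor = Tensor(np.eye(n) + alpha * b)
    gap = anchor - z  # H (anchor - Z) == H(I + aB) - H Z
    total: Tensor | None = None
    n_layers = len(layers1)
    if len(layers2) != n_layers:
        raise ValueError("views have different layer counts")
    for h1, h2 in zip(layers1, layers2):
        for h in (h1, h2):
            norm = float(np.linalg.norm(h.data))
            if norm == 0.0:
                warnings.warn("skipping degenerate all-zero layer in "
                              "manifold loss", stacklevel=2)
                continue
            term = (h @ gap).frobenius_sq() * (1.0 / norm)
            total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / n_layers)
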