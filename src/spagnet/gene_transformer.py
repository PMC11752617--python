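"""Gene-level multi-head self-attention stack.

Genes are the tokens; a gene's feature vector is its expression across the
spots of the batch.  Each unit computes per-head attention maps

    S_t = Normalize( softmax(Q_t K_t^T / sqrt(d_t)) + mu * A )

(`Normalize` = row renormalisation to sum 1, so S_t stays a stochastic map;
mu > 0 only during pretraining, biasing attention toward the prior network
A), mixes value projections through them, projects the concatenated heads
back to the feature width and applies a residual feed-forward sublayer.
The maps averaged over every (unit, head) form the aggregated gene-gene
weight matrix S used for network inference; positional encodings derived
from a truncated SVD of A can be added to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as tz
from ._tensor import Tensor
from .data_io import PriorNetwork

DEFAULT_N_UNITS = 3   # transformer encoder units
DEFAULT_N_HEADS = 5   # attention heads per unit
DEFAULT_MU = 0.2      # prior-constraint weight during pretraining


@dataclass
class TransformerConfig:
    n_units: int = DEFAULT_N_UNITS
    n_heads: int = DEFAULT_N_HEADS
    ffn_hidden: int = 128
    mu: float = DEFAULT_MU    # forced to 0 in fine-tuning
    pe_rank: int = 8          # truncated-SVD rank of positional encodings
    #: queries and keys start identical, scaled by this gain, so initial
    #: attention is a symmetric similarity map over gene profiles (the
    #: model's own reconstruct-from-co-expressed-genes assumption) that
    #: training then refines
    qk_init_gain: float = 0.3

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_heads < 1:
            raise ValueError("n_units and n_heads must be positive")

    def head_width(self, n_features: int) -> int:
        """d_t such that the concatenated head outputs span the feature
        width: the width is padded up to a multiple of the head count."""
        return -(-n_features // self.n_heads)


@dataclass
class PositionalEncoding:
    """Rank-r SVD factors of the prior adjacency and their projection."""

    u_tilde: np.ndarray  # M x r, U sqrt(Sigma)
    v_tilde: np.ndarray  # M x r, V sqrt(Sigma)
    r: int

    def reconstruction(self) -> np.ndarray:
        return self.u_tilde @ self.v_tilde.T


def svd_positional_encoding(prior: PriorNetwork | np.ndarray,
                            r: int) -> PositionalEncoding:
    """Best rank-r factors A ~ (U sqrt(S))(V sqrt(S))^T of the prior network."""
    if isinstance(prior, PriorNetwork):
        a = prior.adjacency
    else:
        a = np.asarray(prior, dtype=np.float64)
    if r > min(a.shape):
        raise ValueError(f"rank {r} exceeds matrix size {a.shape}")
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    root = np.sqrt(s[:r])
    return PositionalEncoding(u[:, :r] * root, vt[:r].T * root, r)


@dataclass
class AttentionNetwork:
    """Aggregated gene-gene attention weights (regulator rows)."""

    S: np.ndarray
    gene_ids: list[str]

    def ranked_edges(self, zero_diagonal: bool = True
                     ) -> list[tuple[str, str, float]]:
        """All directed pairs ranked by weight, deterministic tie order."""
        s = self.S.copy()
        if zero_diagonal:
            np.fill_diagonal(s, -np.inf)
        pairs = [(self.gene_ids[i], self.gene_ids[j], s[i, j])
                 for i in range(s.shape[0]) for j in range(s.shape[1])
                 if i != j or not zero_diagonal]
        pairs.sort(key=lambda e: (-e[2], e[0], e[1]))
        return pairs


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-6) -> Tensor:
    """Per-token (gene) normalisation over the feature axis with affine."""
    mu = x.mean(axis=1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=1, keepdims=True)
    return centred / ((var + eps) ** 0.5) * gamma + beta


class GeneTransformer:
    """Stack of attention units over the gene dimension.

    Weights are sized to a fixed feature width (the number of spots in a
    training token); seeded Xavier initialisation keeps the initial
    attention near-uniform.
    """

    def __init__(self, n_genes: int, n_features: int,
                 config: TransformerConfig | None = None, seed: int = 0):
        self.config = config or TransformerConfig()
        self.n_genes = n_genes
        self.n_features = n_features
        c = self.config
        self.d_head = c.head_width(n_features)
        #: feature width padded to a multiple of the head count, so the
        #: concatenated head outputs exactly span it (no output projection)
        self.width = self.d_head * c.n_heads
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}

        def param(name: str, shape: tuple[int, ...], scale: float) -> Tensor:
            t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
            self.params[name] = t
            return t

        wide = self.width
        for layer in range(c.n_units):
            sc_in = 1.0 / np.sqrt(wide)
            wq = rng.normal(0.0, c.qk_init_gain * sc_in, size=(wide, wide))
            self.params[f"l{layer}.Wq"] = Tensor(wq, requires_grad=True)
            self.params[f"l{layer}.Wk"] = Tensor(wq.copy(), requires_grad=True)
            # near-identity value projection: the unit starts out emitting
            # attention-smoothed expression, which the reconstruction
            # pressure then anchors to the co-expression structure
            wv = np.eye(wide) + rng.normal(0.0, 0.1 * sc_in, size=(wide, wide))
            self.params[f"l{layer}.Wv"] = Tensor(wv, requires_grad=True)
            param(f"l{layer}.ffn.W1", (wide, c.ffn_hidden), sc_in)
            self.params[f"l{layer}.ffn.b1"] = Tensor(
                np.zeros(c.ffn_hidden), requires_grad=True)
            param(f"l{layer}.ffn.W2", (c.ffn_hidden, wide),
                  1.0 / np.sqrt(c.ffn_hidden))
            self.params[f"l{layer}.ffn.b2"] = Tensor(
                np.zeros(wide), requires_grad=True)
            for ln in ("ln1", "ln2"):
                self.params[f"l{layer}.{ln}.gamma"] = Tensor(
                    np.ones(wide), requires_grad=True)
                self.params[f"l{layer}.{ln}.beta"] = Tensor(
                    np.zeros(wide), requires_grad=True)
        # learned projection of SVD positional factors (created lazily when
        # a prior is attached, since it depends on the PE rank)
        self._pe: PositionalEncoding | None = None

    def attach_prior_encoding(self, prior: PriorNetwork, seed: int = 0) -> None:
        """Compute SVD positional encodings of the prior and add W_PE."""
        r = min(self.config.pe_rank, min(prior.adjacency.shape))
        self._pe = svd_positional_encoding(prior, r)
        rng = np.random.default_rng(seed + 7)
        self.params["W_PE"] = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(2 * r), size=(2 * r, self.width)),
            requires_grad=True)

    def positional_input(self) -> Tensor | None:
        if self._pe is None:
            return None
        factors = Tensor(np.concatenate(
            [self._pe.u_tilde, self._pe.v_tilde], axis=1))
        return factors @ self.params["W_PE"]

    # -- forward -------------------------------------------------------------

    def attention_layer(self, x: Tensor, layer: int,
                        prior_a: np.ndarray | None = None,
                        mu: float = 0.0) -> tuple[Tensor, list[Tensor]]:
        """One unit: multi-head attention + output projection + residual FFN.

        Returns the unit output (M x n_features) and the per-head attention
        maps (each M x M, rows summing to 1).
        """
        c = self.config
        if mu > 0 and prior_a is None:
            raise ValueError("mu > 0 requires a prior adjacency")
        p = self.params
        m = x.shape[0]
        d = self.d_head
        # queries/keys from per-gene normalised profiles (similarity view);
        # values from the raw input so the output keeps expression scale
        xn = _layer_norm(x, p[f"l{layer}.ln1.gamma"], p[f"l{layer}.ln1.beta"])
        q = (xn @ p[f"l{layer}.Wq"]).reshape(m, c.n_heads, d).transpose(1, 0, 2)
        k = (xn @ p[f"l{layer}.Wk"]).reshape(m, c.n_heads, d).transpose(1, 0, 2)
        v = (x @ p[f"l{layer}.Wv"]).reshape(m, c.n_heads, d).transpose(1, 0, 2)
        logits = tz.matmul(q, k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
        if not np.isfinite(logits.data).all():
            bad = np.argwhere(~np.isfinite(logits.data))[0]
            raise FloatingPointError(
                f"non-finite attention logits at layer {layer}, head {bad[0]}")
        soft = tz.softmax(logits, axis=2)  # (heads, M, M), rows sum to 1
        if mu > 0:
            biased = soft + Tensor(mu * prior_a[np.newaxis])
            s_all = biased / biased.sum(axis=2, keepdims=True)
        else:
            s_all = soft
        heads_out = tz.matmul(s_all, v)  # (heads, M, d)
        # concatenating the heads restores the full feature width directly;
        # there is no bypass around the attention mix, so the maps must
        # carry the reconstruction (they cannot go lazy)
        merged = heads_out.transpose(1, 0, 2).reshape(m, self.width)
        mn = _layer_norm(merged, p[f"l{layer}.ln2.gamma"], p[f"l{layer}.ln2.beta"])
        h = tz.elu(mn @ p[f"l{layer}.ffn.W1"] + p[f"l{layer}.ffn.b1"])
        out = merged + (h @ p[f"l{layer}.ffn.W2"] + p[f"l{layer}.ffn.b2"])
        s_heads = [tz.take(s_all, np.array(t), axis=0) for t in range(c.n_heads)]
        return out, s_heads

    def forward(self, x1: np.ndarray, prior_a: np.ndarray | None = None,
                mu: float = 0.0) -> tuple[Tensor, list[list[Tensor]]]:
        """Full stack: returns augmented expression X2 (feature columns
        padded to the head-aligned width) and all head maps."""
        x1 = np.asarray(x1, dtype=np.float64)
        if x1.shape[1] < self.width:  # head-alignment padding
            pad = np.zeros((x1.shape[0], self.width - x1.shape[1]))
            x1 = np.concatenate([x1, pad], axis=1)
        x = Tensor(x1)
        pe = self.positional_input()
        if pe is not None:
            x = x + pe
        all_heads: list[list[Tensor]] = []
        for layer in range(self.config.n_units):
            x, s_heads = self.attention_layer(x, layer, prior_a=prior_a, mu=mu)
            all_heads.append(s_heads)
        return x, all_heads


def aggregate_attention(all_heads: list[list[Tensor | np.ndarray]],
                        gene_ids: list[str],
                        scale: str = "mean",
                        zero_diagonal: bool = False) -> AttentionNetwork:
    """Aggregate per-(unit, head) maps into the gene-gene network S.

    `scale='mean'` is the arithmetic mean over all maps; `scale='printed'`
    divides the plain sum by (heads + units - 1) instead.  The two differ
    by a positive constant only, so downstream edge rankings are identical.
    """
    mats = [np.asarray(s.data if isinstance(s, Tensor) else s)
            for layer in all_heads for s in layer]
    if not mats:
        raise ValueError("no attention maps to aggregate")
    total = np.sum(mats, axis=0)
    if scale == "mean":
        s = total / len(mats)
    elif scale == "printed":
        n_heads = len(all_heads[0])
        n_units = len(all_heads)
        s = total / (n_heads + n_units - 1)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if zero_diagonal:
        s = s.copy()
        np.fill_diagonal(s, 0.0)
    return AttentionNetwork(S=s, gene_ids=list(gene_ids))
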