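"""Optimisation loops: fine-tuning on one dataset and token-batched
prior-constrained pretraining.

The optimiser is Adam with decoupled weight decay and a linear warmup
schedule.  Fine-tuning minimises the overall objective with the prior
bias mu = 0; pretraining keeps mu > 0, splits each slice into spot tokens,
trains them sequentially and repeats shuffled passes until the aggregated
gene network S stops moving.  All randomness (weight init, VAE sampling,
token shuffling) flows from the config seed through separate named
streams, and fixed-seed runs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._tensor import Tensor
from .alignment import LossReport, LossWeights
from .data_io import ExpressionMatrix
from .gene_transformer import AttentionNetwork, TransformerConfig
from .manifold_vae import ManifoldGraph, VAEConfig
from .model import CrossDimModel, DataBundle


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    warmup_steps: int = 20          # scaled-down linear warmup
    max_epochs: int = 300
    token_size: int = 3000          # spots per training token
    seed: int = 0
    mode: str = "finetune"          # or "pretrain"
    weights: LossWeights = field(default_factory=LossWeights)
    weight_decay: float = 1e-2
    loss_tol: float = 1e-4          # relative total-loss change
    patience: int = 20              # epochs below tol before stopping
    s_tol: float = 1e-3             # relative ||dS||_F across pretrain passes
    max_passes: int = 10            # shuffled pretrain passes cap
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    vae: VAEConfig = field(default_factory=VAEConfig)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.token_size < 2:
            raise ValueError("token_size must be >= 2")
        if self.mode not in ("finetune", "pretrain"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class AdamW:
    """Adam with decoupled weight decay and linear warmup."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 weight_decay: float = 0.0, warmup_steps: int = 0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_steps = warmup_steps
        self.betas = betas
        self.eps = eps
        self.step_count = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def _decayed(self, name: str) -> bool:
        # decay weight matrices only: not biases, not the manifold graph Z
        leaf = name.rsplit(".", 1)[-1]
        return not (name == "Z" or leaf.startswith("b"))

    def current_lr(self) -> float:
        if self.warmup_steps > 0 and self.step_count < self.warmup_steps:
            return self.lr * (self.step_count + 1) / self.warmup_steps
        return self.lr

    def step(self) -> None:
        lr = self.current_lr()
        b1, b2 = self.betas
        self.step_count += 1
        t = self.step_count
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** t)
            vhat = self.v[k] / (1 - b2 ** t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self._decayed(k):
                p.data -= lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class FitResult:
    network: AttentionNetwork
    manifold: ManifoldGraph
    model: CrossDimModel
    history: list[LossReport]
    converged: bool


def _new_model(bundle: DataBundle, config: TrainConfig,
               n_features: int) -> CrossDimModel:
    model = CrossDimModel(
        n_genes=bundle.expression.n_genes, n_features=n_features,
        transformer_config=config.transformer, vae_config=config.vae,
        weights=config.weights, seed=config.seed)
    if bundle.prior is not None:
        model.attach_prior(bundle.prior, seed=config.seed)
    return model


def _run_epochs(model: CrossDimModel, bundle: DataBundle, config: TrainConfig,
                optimizer: AdamW, mu: float, rng: np.random.Generator,
                max_epochs: int) -> tuple[list[LossReport], bool]:
    history: list[LossReport] = []
    quiet = 0
    converged = False
    for _ in range(max_epochs):
        optimizer.zero_grad()
        try:
            total, report = model.loss(bundle, mu=mu, rng=rng)
        except FloatingPointError:
            break  # divergence: stop at the last good state
        total.backward()
        optimizer.step()
        history.append(report)
        if len(history) >= 2:
            prev, cur = history[-2].total, history[-1].total
            rel = abs(cur - prev) / max(abs(prev), 1e-12)
            quiet = quiet + 1 if rel < config.loss_tol else 0
            if quiet >= config.patience:
                converged = True
                break
    return history, converged


def finetune(bundle: DataBundle, config: TrainConfig | None = None,
             init_checkpoint: "str | Path | None" = None) -> FitResult:
    """Fine-tune on one dataset with the prior bias mu = 0.

    With `max_epochs=0` the initialisation is returned unchanged.  An
    optional checkpoint provides initial weights (shapes must match the
    dataset's gene count and spot width).
    """
    config = config or TrainConfig()
    n = bundle.expression.n_spots
    n_features = min(n, config.token_size)
    model = _new_model(bundle, config, n_features)
    model.init_manifold(bundle.graph)
    if init_checkpoint is not None:
        load_weights_into(model, init_checkpoint)
        if model.z is None or model.z.shape[0] != bundle.graph.n_spots:
            # Z is dataset-specific; pretrained Z does not transfer
            model.init_manifold(bundle.graph)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)))
    optimizer = AdamW(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay,
                      warmup_steps=config.warmup_steps)
    history, converged = _run_epochs(model, bundle, config, optimizer,
                                     mu=0.0, rng=rng,
                                     max_epochs=config.max_epochs)
    network = model.attention_network(bundle, mu=0.0)
    return FitResult(network=network, manifold=model.manifold_graph(),
                     model=model, history=history, converged=converged)


def partition_tokens(n_spots: int, token_size: int,
                     rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Split spot indices into tokens of `token_size` covering all spots
    (last token holds the remainder).  Shuffles spot order when given an rng."""
    order = np.arange(n_spots)
    if rng is not None:
        rng.shuffle(order)
    return [order[i:i + token_size] for i in range(0, n_spots, token_size)]


def _token_bundle(bundle: DataBundle, idx: np.ndarray) -> DataBundle:
    from .spatial_graph import SpatialGraph

    expr = bundle.expression
    sub = ExpressionMatrix(expr.values[:, idx],
                           list(expr.gene_ids),
                           [expr.spot_ids[i] for i in idx],
                           is_log=expr.is_log)
    # restrict B to the token and renormalise columns over surviving support
    b = bundle.graph.B[np.ix_(idx, idx)]
    col = b.sum(axis=0)
    col[col == 0] = 1.0
    b = b / col
    pos = {g: i for i, g in enumerate(idx)}
    neigh = []
    for j in idx:
        kept = np.array([pos[i] for i in bundle.graph.neighbor_sets[j]
                         if i in pos], dtype=int)
        neigh.append(kept)
    # equal-size neighbour sets are required for batched local alignment;
    # refill from the token's own B support where edges were cut
    k = bundle.graph.k
    for row, j in enumerate(idx):
        if len(neigh[row]) < min(k, len(idx) - 1):
            others = np.setdiff1d(np.arange(len(idx)), np.append(neigh[row], row))
            need = min(k, len(idx) - 1) - len(neigh[row])
            neigh[row] = np.concatenate([neigh[row], others[:need]])
    graph = SpatialGraph(B=b, neighbor_sets=neigh, k=min(k, len(idx) - 1))
    return DataBundle(expression=sub, graph=graph, prior=bundle.prior)


def _slice_network(model: CrossDimModel, bundle: DataBundle, mu: float,
                   token_size: int) -> AttentionNetwork:
    """Slice-level S in token-batched mode: attention maps averaged over a
    deterministic partition of the slice's spots."""
    n = bundle.expression.n_spots
    if n <= model.n_features:
        return model.attention_network(bundle, mu=mu)
    mats = []
    for tok in partition_tokens(n, model.n_features):
        tb = _token_bundle(bundle, tok)
        mats.append(model.attention_network(tb, mu=mu).S)
    return AttentionNetwork(S=np.mean(mats, axis=0),
                            gene_ids=list(bundle.expression.gene_ids))


def pretrain(slices: list[DataBundle], config: TrainConfig | None = None
             ) -> tuple[CrossDimModel, AttentionNetwork, list[LossReport]]:
    """Token-batched pretraining with the prior bias mu > 0.

    Trains each token to convergence carrying parameters forward; after a
    full pass the token order is shuffled and training repeats until the
    relative Frobenius change of S between passes drops below `s_tol`.
    """
    config = config or TrainConfig(mode="pretrain")
    if not slices:
        raise ValueError("empty slice list")
    if any(b.prior is None for b in slices):
        raise ValueError("pretraining requires a prior network on every slice")
    mu = config.transformer.mu
    n_features = min(config.token_size,
                     max(b.expression.n_spots for b in slices))
    model = _new_model(slices[0], config, n_features)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(2,)))
    noise_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(3,)))
    optimizer = AdamW(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay,
                      warmup_steps=config.warmup_steps)
    history: list[LossReport] = []
    prev_s: np.ndarray | None = None
    epochs_per_token = max(1, config.max_epochs // 10)
    for pass_no in range(config.max_passes):
        tokens = [(si, tok) for si, b in enumerate(slices)
                  for tok in partition_tokens(b.expression.n_spots,
                                              config.token_size,
                                              rng=shuffle_rng)]
        if pass_no > 0:
            shuffle_rng.shuffle(tokens)  # reshuffle token order across passes
        for si, tok in tokens:
            tb = _token_bundle(slices[si], tok)
            model.init_manifold(tb.graph)
            optimizer.params = model.parameters()
            optimizer.m.setdefault("Z", np.zeros_like(model.z.data))
            optimizer.v.setdefault("Z", np.zeros_like(model.z.data))
            optimizer.m["Z"] = np.zeros_like(model.z.data)
            optimizer.v["Z"] = np.zeros_like(model.z.data)
            h, _ = _run_epochs(model, tb, config, optimizer, mu=mu,
                               rng=noise_rng, max_epochs=epochs_per_token)
            history.extend(h)
        s = _slice_network(model, slices[0], mu, config.token_size).S
        if prev_s is not None:
            rel = np.linalg.norm(s - prev_s) / max(np.linalg.norm(prev_s),
                                                   1e-12)
            if rel < config.s_tol:
                break
        prev_s = s
    network = _slice_network(model, slices[0], mu, config.token_size)
    return model, network, history


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(model: CrossDimModel, path: str | Path,
                    config: TrainConfig | None = None,
                    step: int = 0) -> Path:
    """Single-file HDF5 checkpoint of every parameter plus S/Z state."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for k, v in model.parameters().items():
            grp.create_dataset(k, data=v.data)
        f.attrs["n_genes"] = model.n_genes
        f.attrs["n_features"] = model.n_features
        f.attrs["step"] = step
        if config is not None:
            f.attrs["config_hash"] = config.config_hash()
    return path


def load_weights_into(model: CrossDimModel, path: str | Path) -> None:
    """Copy checkpointed parameters into a model (shapes must match)."""
    import h5py

    with h5py.File(path, "r") as f:
        stored = {k: np.asarray(v) for k, v in f["params"].items()}
    params = model.parameters()
    for k, v in stored.items():
        if k == "Z":
            model.z = Tensor(v, requires_grad=True)
            continue
        if k.endswith("W_PE") and k not in params:
            continue  # positional projection is unused without a prior
        if k not in params:
            raise KeyError(f"checkpoint parameter {k} unknown to model")
        if params[k].data.shape != v.shape:
            raise ValueError(f"shape mismatch for {k}: "
                             f"{params[k].data.shape} vs {v.shape}")
        params[k].data = v.copy()


def load_checkpoint(path: str | Path, config: TrainConfig | None = None,
                    prior=None) -> CrossDimModel:
    """Rebuild a model from a checkpoint; forward passes reproduce the
    saved model bit-identically."""
    import h5py

    config = config or TrainConfig()
    with h5py.File(path, "r") as f:
        n_genes = int(f.attrs["n_genes"])
        n_features = int(f.attrs["n_features"])
        has_pe = "W_PE" in f["params"]
        pe_shape = f["params"]["W_PE"].shape if has_pe else None
    model = CrossDimModel(n_genes=n_genes, n_features=n_features,
                          transformer_config=config.transformer,
                          vae_config=config.vae, weights=config.weights,
                          seed=config.seed)
    if has_pe:
        if prior is not None:  # restore the SVD factors the projection expects
            model.attach_prior(prior, seed=config.seed)
        else:
            model.transformer.params["W_PE"] = Tensor(
                np.zeros(pe_shape), requires_grad=True)
    load_weights_into(model, path)
    return model
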