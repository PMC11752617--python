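"""Downstream analyses: regulon extraction, activity scoring, spatial
clustering and specificity filtering.

The aggregated attention network S is decomposed into regulons (a TF plus
its top-weighted targets, read from the TF's row of S).  Regulon activity
per spot is a rank-based recovery-curve area over the spot's gene ranking
(AUCell-style), so it is invariant to monotone transforms of expression.
Spots are clustered by Leiden community detection on the learned manifold
graph Z; domain- or cell-type-specific regulons are selected by one-vs-rest
log2 fold change of mean activity and rank-based AUROC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .gene_transformer import AttentionNetwork
from .manifold_vae import ManifoldGraph

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 50
DEFAULT_MIN_TARGETS = 10
DEFAULT_AUCELL_THRESHOLD = 0.05   # conventional top-5% ranking cutoff
DEFAULT_MIN_LOG2FC = 0.25
DEFAULT_MIN_AUROC = 0.75
_LOG2FC_EPS = 1e-9


@dataclass
class Regulon:
    """A TF with its direct targets and their attention weights."""

    tf: str
    targets: list[str]
    weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf} contains its own TF")

    @property
    def name(self) -> str:
        return f"{self.tf}(+)"

    @property
    def genes(self) -> list[str]:
        return [self.tf] + list(self.targets)


@dataclass
class ActivityMatrix:
    """Regulon x spot activity scores in [0, 1]."""

    values: np.ndarray
    regulon_ids: list[str]
    spot_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regulon_ids,
                            columns=self.spot_ids)


@dataclass
class ClusterLabels:
    labels: np.ndarray
    resolution: float

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def extract_regulons(network: AttentionNetwork, tf_list: list[str],
                     top_k: int = DEFAULT_TOP_K,
                     min_targets: int = DEFAULT_MIN_TARGETS) -> list[Regulon]:
    """Top-k targets per TF from the TF's row of S (self excluded).

    Weight ties are broken by gene id; regulons smaller than `min_targets`
    are dropped.
    """
    gene_index = {g: i for i, g in enumerate(network.gene_ids)}
    tfs = [tf for tf in tf_list if tf in gene_index]
    if not tfs:
        raise ValueError("no TF from the list occurs in the network genes")
    regulons: list[Regulon] = []
    for tf in tfs:
        row = network.S[gene_index[tf]]
        candidates = sorted(
            (g for g in network.gene_ids if g != tf),
            key=lambda g: (-row[gene_index[g]], g))
        chosen = candidates[:top_k]
        if len(chosen) < min_targets:
            continue
        regulons.append(Regulon(
            tf=tf, targets=chosen,
            weights=[float(row[gene_index[g]]) for g in chosen]))
    return regulons


class MotifBackend(Protocol):
    """Interface to a cis-regulatory motif pruning tool.

    `verdicts(tf, targets)` returns the subset of targets with motif
    support for the TF.
    """

    def verdicts(self, tf: str, targets: list[str]) -> list[str]: ...


class PassThroughMotifBackend:
    """Stub backend: keeps every target (no motif database attached)."""

    def verdicts(self, tf: str, targets: list[str]) -> list[str]:
        return list(targets)


def prune_regulons(regulons: list[Regulon],
                   motif_backend: MotifBackend | None = None,
                   min_targets: int = 1) -> list[Regulon]:
    """Drop targets without motif support per the backend's verdicts.

    With the pass-through stub (default) the input is returned unchanged
    and a notice is logged.  Regulons falling below `min_targets` after
    pruning are dropped.  A backend failure propagates and leaves the
    input untouched.
    """
    if motif_backend is None:
        motif_backend = PassThroughMotifBackend()
    if isinstance(motif_backend, PassThroughMotifBackend):
        logger.info("motif pruning skipped: pass-through backend "
                    "(no motif database attached)")
    pruned: list[Regulon] = []
    for reg in regulons:
        kept = motif_backend.verdicts(reg.tf, list(reg.targets))
        unknown = set(kept) - set(reg.targets)
        if unknown:
            raise ValueError(
                f"motif backend returned unknown targets {sorted(unknown)}")
        keep_set = set(kept)
        targets, weights = [], []
        for t, w in zip(reg.targets, reg.weights or [np.nan] * len(reg.targets)):
            if t in keep_set:
                targets.append(t)
                weights.append(w)
        if len(targets) >= min_targets:
            pruned.append(Regulon(tf=reg.tf, targets=targets, weights=weights))
    return pruned


def _spot_ranking(column: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Indices of genes ranked by descending expression, ties by gene id."""
    order = sorted(range(len(gene_ids)),
                   key=lambda i: (-column[i], gene_ids[i]))
    return np.asarray(order, dtype=int)


def aucell_activity(expr: ExpressionMatrix, regulons: list[Regulon],
                    threshold_frac: float = DEFAULT_AUCELL_THRESHOLD
                    ) -> ActivityMatrix:
    """Recovery-curve area of each regulon's genes in each spot's ranking.

    Genes are ranked by descending expression within the spot (ties by
    gene id); the recovery curve counts regulon members among the top r
    ranks and the activity is its area up to rank ceil(threshold_frac * M),
    normalised by the maximum attainable area, giving values in [0, 1].
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must lie in (0, 1]")
    m, n = expr.values.shape
    top = int(np.ceil(threshold_frac * m))
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    values = np.zeros((len(regulons), n))
    for ri, reg in enumerate(regulons):
        members = {gene_index[g] for g in reg.genes if g in gene_index}
        if not members:
            warnings.warn(f"regulon {reg.name} has no genes in the "
                          "expression matrix; activity set to 0", stacklevel=2)
            continue
        n_set = len(members)
        max_area = sum(min(r, n_set) for r in range(1, top + 1))
        for j in range(n):
            ranking = _spot_ranking(expr.values[:, j], expr.gene_ids)
            hits = np.cumsum(np.isin(ranking[:top], list(members)))
            values[ri, j] = hits.sum() / max_area
    return ActivityMatrix(values=values, regulon_ids=[r.name for r in regulons],
                          spot_ids=list(expr.spot_ids))


def cluster_spots(manifold: ManifoldGraph | np.ndarray, resolution: float = 1.0,
                  seed: int = 0, n_clusters: int | None = None
                  ) -> ClusterLabels:
    """Leiden community detection on the (symmetrised) manifold graph Z.

    Z is symmetrised and negatives are clipped before graph construction;
    the diagonal is ignored.  With `n_clusters` given, the resolution is
    found by bisection so the partition has that many communities (the
    conventional way of matching a known number of annotated structures).
    """
    import igraph as ig
    import leidenalg

    z = manifold.symmetrized() if isinstance(manifold, ManifoldGraph) \
        else np.clip(0.5 * (manifold + manifold.T), 0.0, None)
    np.fill_diagonal(z, 0.0)
    if not z.any():
        raise ValueError("manifold graph is all-zero; nothing to cluster")
    sources, targets = np.nonzero(np.triu(z, k=1))
    graph = ig.Graph(n=z.shape[0],
                     edges=list(zip(sources.tolist(), targets.tolist())))
    graph.es["weight"] = z[sources, targets]

    def partition(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=res, seed=seed,
            n_iterations=2)
        return np.asarray(part.membership)

    if n_clusters is None:
        return ClusterLabels(labels=partition(resolution),
                             resolution=resolution)
    lo, hi = 1e-4, resolution
    labels = partition(hi)
    while len(np.unique(labels)) < n_clusters and hi < 1e4:
        hi *= 2
        labels = partition(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        labels_mid = partition(mid)
        got = len(np.unique(labels_mid))
        if got == n_clusters:
            return ClusterLabels(labels=labels_mid, resolution=mid)
        if got < n_clusters:
            lo = mid
        else:
            hi = mid
    labels = partition(hi)
    return ClusterLabels(labels=labels, resolution=hi)


def specific_regulons(activity: ActivityMatrix, labels: ClusterLabels,
                      min_log2fc: float = DEFAULT_MIN_LOG2FC,
                      min_auroc: float | None = DEFAULT_MIN_AUROC
                      ) -> pd.DataFrame:
    """One-vs-rest marker table of regulons per cluster.

    For every (regulon, cluster): log2FC of mean activity inside vs outside
    (with a small pseudocount) and the rank-based AUROC of activity against
    cluster membership.  Rows pass when log2FC > `min_log2fc` and, if
    `min_auroc` is set, AUROC > `min_auroc` (high-resolution platforms
    conventionally drop the AUROC condition).  Singleton clusters have no
    defined AUROC; such rows are flagged.
    """
    from .evaluation import rank_auroc

    lab = np.asarray(labels.labels)
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for specificity")
    rows = []
    for ri, rid in enumerate(activity.regulon_ids):
        act = activity.values[ri]
        for cl in clusters:
            inside = act[lab == cl]
            outside = act[lab != cl]
            log2fc = float(np.log2((inside.mean() + _LOG2FC_EPS)
                                   / (outside.mean() + _LOG2FC_EPS)))
            flagged = len(inside) < 2
            auroc = np.nan if flagged else rank_auroc(inside, outside)
            passed = log2fc > min_log2fc and (
                min_auroc is None or (not np.isnan(auroc) and auroc > min_auroc))
            rows.append({"regulon": rid, "cluster": cl, "log2fc": log2fc,
                         "auroc": auroc, "flagged": flagged,
                         "passed": bool(passed)})
    return pd.DataFrame(rows)


def write_regulons_gmt(regulons: list[Regulon], path) -> None:
    """Export regulons in GMT format, one set per line named 'TF(+)'."""
    with open(path, "w") as fh:
        for reg in regulons:
            fh.write("\t".join([reg.name, reg.tf] + list(reg.targets)) + "\n")
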