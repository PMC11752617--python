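"""Benchmarking metrics: edge-ranking accuracy (AUROC/AUPRC), run-to-run
stability (Spearman / top-k Jaccard), spatial autocorrelation (Moran's I)
and clustering accuracy (ARI)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spatial_graph import SpatialGraph


@dataclass
class GroundTruthNetwork:
    """Directed reference edges over gene symbols."""

    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.edges = {(a, b) for a, b in self.edges}
        loops = [e for e in self.edges if e[0] == e[1]]
        if loops:
            raise ValueError(f"self-loops in ground truth: {loops[:3]}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class EdgeRanking:
    """Scored directed pairs, descending; unlisted pairs count as score 0."""

    entries: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        pairs = [(a, b) for a, b, _ in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pairs in ranking")
        self.entries = sorted(self.entries, key=lambda e: (-e[2], e[0], e[1]))

    def scores_over(self, universe: list[tuple[str, str]]) -> np.ndarray:
        lookup = {(a, b): s for a, b, s in self.entries}
        return np.asarray([lookup.get(pair, 0.0) for pair in universe])

    def top_k(self, k: int) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.entries[:k]}


def rank_auroc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """AUROC as the Mann-Whitney U statistic scaled to [0, 1] (mid-rank
    tie handling), equivalent to the trapezoidal ROC area."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def average_precision(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average-precision form),
    with tied scores handled as one threshold group."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("no positive labels")
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # group by distinct score: cumulative tp/fp at each group boundary
    distinct = np.flatnonzero(np.diff(scores)) .tolist() + [len(scores) - 1]
    tp = np.cumsum(labels)
    ap = 0.0
    prev_tp = 0
    for boundary in distinct:
        cur_tp = tp[boundary]
        if cur_tp > prev_tp:
            precision = cur_tp / (boundary + 1)
            ap += (cur_tp - prev_tp) / n_pos * precision
        prev_tp = cur_tp
    return float(ap)


def auroc_auprc(ranking: EdgeRanking, truth: GroundTruthNetwork,
                universe: list[tuple[str, str]]) -> tuple[float, float]:
    """Edge-ranking accuracy over a candidate-pair universe.

    `universe` is every TF->gene pair under evaluation; ranked pairs keep
    their scores, unranked ones score 0, and the reference edges must be a
    subset of the universe.
    """
    if truth.n_edges == 0:
        raise ValueError("empty ground-truth network")
    uni = list(universe)
    missing = truth.edges - set(uni)
    if missing:
        raise ValueError(f"truth edges outside the universe: "
                         f"{sorted(missing)[:3]}")
    scores = ranking.scores_over(uni)
    labels = np.asarray([pair in truth.edges for pair in uni])
    auroc = rank_auroc(scores[labels], scores[~labels])
    auprc = average_precision(labels, scores)
    return auroc, auprc


def tf_universe(gene_ids: list[str], tfs: list[str] | None = None
                ) -> list[tuple[str, str]]:
    """Candidate edges: TF rows x all other genes (all ordered pairs when
    no TF list is given)."""
    regulators = tfs if tfs is not None else gene_ids
    return [(tf, g) for tf in regulators for g in gene_ids if g != tf]


def network_ranking(network, tfs: list[str] | None = None) -> EdgeRanking:
    """Ranked TF->target entries from an attention network's S matrix."""
    idx = {g: i for i, g in enumerate(network.gene_ids)}
    regulators = tfs if tfs is not None else network.gene_ids
    entries = [(tf, g, float(network.S[idx[tf], idx[g]]))
               for tf in regulators for g in network.gene_ids if g != tf]
    return EdgeRanking(entries)


def stability(rankings: list[EdgeRanking], k: int
              ) -> tuple[list[float], list[float]]:
    """Consecutive-run agreement: Spearman over full score lists and
    Jaccard of the top-k edge sets."""
    if len(rankings) < 2:
        raise ValueError("need at least two runs")
    universes = [sorted((a, b) for a, b, _ in r.entries) for r in rankings]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("rankings cover different edge universes")
    universe = universes[0]
    spearman, jaccard = [], []
    for prev, cur in zip(rankings[:-1], rankings[1:]):
        s_prev = prev.scores_over(universe)
        s_cur = cur.scores_over(universe)
        spearman.append(float(stats.spearmanr(s_prev, s_cur).statistic))
        a, b = prev.top_k(k), cur.top_k(k)
        jaccard.append(len(a & b) / len(a | b) if (a | b) else 1.0)
    return spearman, jaccard


def morans_i(values: np.ndarray, weights: SpatialGraph | np.ndarray,
             binary: bool = True) -> float:
    """Moran's I spatial autocorrelation.

        I = (N / sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar)
                              / sum_i (x_i - xbar)^2

    Weights default to the binary symmetrised kNN adjacency; `binary=False`
    uses the B edge weights instead.  Constant fields have no defined I.
    """
    x = np.asarray(values, dtype=float)
    if isinstance(weights, SpatialGraph):
        w = weights.symmetric_adjacency(binary=binary)
    else:
        w = np.asarray(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    n = len(x)
    if w.shape != (n, n):
        raise ValueError("weight matrix does not match value length")
    dev = x - x.mean()
    denom = (dev ** 2).sum()
    if denom == 0:
        raise ValueError("Moran's I is undefined for a constant field")
    return float(n / w.sum() * (dev @ w @ dev) / denom)


def clustering_ari(labels, truth_labels) -> float:
    """Adjusted Rand index between two partitions of the same spots."""
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(getattr(labels, "labels", labels))
    b = np.asarray(getattr(truth_labels, "labels", truth_labels))
    if len(a) != len(b):
        raise ValueError("partitions cover different spot sets")
    if len(a) < 2:
        raise ValueError("need at least two spots")
    return float(adjusted_rand_score(b, a))
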