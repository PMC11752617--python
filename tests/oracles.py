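"""Independent brute-force oracles used by the acceptance tests.

Every function here is a direct, loop-level evaluation of a definition,
kept deliberately separate from the package's implementations.
"""

import numpy as np


def mmd_double_loop(x, y):
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    k = lambda a, b: np.exp(-0.5 * np.sum((a - b) ** 2))
    n, m = x.shape[1], y.shape[1]
    kxx = sum(k(x[:, i], x[:, j]) for i in range(n) for j in range(n)) / n ** 2
    kyy = sum(k(y[:, i], y[:, j]) for i in range(m) for j in range(m)) / m ** 2
    kxy = sum(k(x[:, i], y[:, j]) for i in range(n) for j in range(m))
    return kxx + kyy - 2 * kxy / (n * m)


def manifold_residual_loops(layers1, layers2, z, b, alpha):
    n = b.shape[0]
    anchor = np.eye(n) + alpha * b
    total = 0.0
    for h1, h2 in zip(layers1, layers2):
        for h in (h1, h2):
            resid = h @ anchor - h @ z
            total += (resid ** 2).sum() / np.sqrt((h ** 2).sum())
    return total / len(layers1)


def contrastive_loops(layers1, layers2):
    total = 0.0
    for h1, h2 in zip(layers1, layers2):
        total += ((h1 - h2) ** 2).sum() / np.sqrt(((h1 + h2) ** 2).sum())
    return total / len(layers1)


def morans_double_sum(values, w):
    x = np.asarray(values, float)
    n = len(x)
    dev = x - x.mean()
    num = sum(w[i, j] * dev[i] * dev[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (dev ** 2).sum()


def auroc_threshold_sweep(labels, scores):
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    p, n = labels.sum(), (~labels).sum()
    for t in thresholds:
        pred = scores >= t
        pts.append(((pred & ~labels).sum() / n, (pred & labels).sum() / p))
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    return sum((x2 - x1) * (y1 + y2) / 2
               for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]))


def auprc_threshold_sweep(labels, scores):
    thresholds = np.unique(scores)[::-1]
    ap, prev_recall = 0.0, 0.0
    p = labels.sum()
    for t in thresholds:
        pred = scores >= t
        tp = (pred & labels).sum()
        ap += (tp / p - prev_recall) * (tp / pred.sum())
        prev_recall = tp / p
    return ap


def spearman_rank_pearson(a, b):
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    ra, rb = ranks(np.asarray(a, float)), ranks(np.asarray(b, float))
    ra -= ra.mean()
    rb -= rb.mean()
    return (ra * rb).sum() / np.sqrt((ra ** 2).sum() * (rb ** 2).sum())


def ari_pair_counting(a, b):
    from math import comb

    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    contingency = np.array([[(np.logical_and(a == ca, b == cb)).sum()
                             for cb in ub] for ca in ua])
    sum_ij = sum(comb(int(v), 2) for v in contingency.ravel())
    sum_a = sum(comb(int(v), 2) for v in contingency.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in contingency.sum(axis=0))
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)


def aucell_rank_walk(column, gene_ids, members, threshold_frac):
    m = len(gene_ids)
    top = int(np.ceil(threshold_frac * m))
    order = sorted(range(m), key=lambda i: (-column[i], gene_ids[i]))
    hits, area = 0, 0
    for r in range(top):
        if gene_ids[order[r]] in members:
            hits += 1
        area += hits
    n_set = len(members)
    best = sum(min(r, n_set) for r in range(1, top + 1))
    return area / best
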