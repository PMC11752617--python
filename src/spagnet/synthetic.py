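"""Synthetic spatially resolved transcriptomics with a planted regulatory
network.

The generator emulates the standard GRN-benchmark construction: single-cell
expression is produced by stochastic Hill-kinetics dynamics on a planted
TF -> target network (distinct regulatory regimes switch subsets of TFs on),
cells are embedded and binned into spatially arranged spots, and the true
edge set plus the spatial domain of every spot are returned as ground truth.

Regimes are what make domains: each regime activates its own subset of TFs,
cells of one regime are binned into one contiguous block of the spot grid,
so domain labels are spatially contiguous by construction and each domain
carries a distinct regulatory program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ExpressionMatrix, SpotCoordinates


@dataclass
class PlantedGRN:
    """Ground-truth network: genes, TF subset and signed directed edges.

    edges : list of (tf, target, sign) with sign +1 (activation) or -1
    (repression).  Every non-TF gene has at least one regulator.
    regime_tfs : per regulatory regime, the boolean mask of active TFs.
    """

    genes: list[str]
    tfs: list[str]
    edges: list[tuple[str, str, int]]
    regime_tfs: np.ndarray  # (n_regimes, n_tfs) activity mask
    hill_n: float = 2.0
    hill_k: float = 1.0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def adjacency(self) -> np.ndarray:
        """Signed adjacency, rows = regulators, cols = targets."""
        idx = {g: i for i, g in enumerate(self.genes)}
        a = np.zeros((self.n_genes, self.n_genes))
        for tf, tg, sign in self.edges:
            a[idx[tf], idx[tg]] = sign
        return a


def planted_grn(n_genes: int = 20, n_tfs: int = 5, n_regimes: int = 3,
                targets_per_tf: int = 3, repression_frac: float = 0.2,
                seed: int = 0) -> PlantedGRN:
    """Draw a random two-layer TF -> target network.

    Each TF regulates `targets_per_tf` targets; each non-TF gene is
    guaranteed at least one regulator.  A fraction of edges is repressive.
    Each regime activates a distinct subset of TFs (round-robin assignment)
    so regimes are separable in expression.
    """
    if n_tfs >= n_genes:
        raise ValueError("need at least one non-TF target gene")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    tfs = genes[:n_tfs]
    targets = genes[n_tfs:]

    edges: list[tuple[str, str, int]] = []
    chosen: set[tuple[str, str]] = set()
    # guarantee every target a regulator, then fill up per-TF quotas
    for i, tg in enumerate(targets):
        tf = tfs[i % n_tfs]
        edges.append((tf, tg, 1))
        chosen.add((tf, tg))
    for tf in tfs:
        have = sum(1 for a, _, _ in edges if a == tf)
        pool = [t for t in targets if (tf, t) not in chosen]
        extra = rng.choice(len(pool), size=min(max(0, targets_per_tf - have),
                                               len(pool)), replace=False)
        for j in sorted(int(e) for e in extra):
            sign = -1 if rng.random() < repression_frac else 1
            edges.append((tf, pool[j], sign))
            chosen.add((tf, pool[j]))

    # regimes switch TF subsets on/off; round-robin keeps them distinct
    regime_tfs = np.zeros((n_regimes, n_tfs), dtype=bool)
    for t in range(n_tfs):
        regime_tfs[t % n_regimes, t] = True
    return PlantedGRN(genes=genes, tfs=tfs, edges=edges, regime_tfs=regime_tfs)


def simulate_cells(grn: PlantedGRN, n_cells: int, noise_sd: float = 0.1,
                   seed: int = 0, n_steps: int = 200, dt: float = 0.1,
                   decay: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Integrate stochastic Hill dynamics to stationarity for each cell.

    TF g in a cell of regime r follows
        dx_g = (b_g(cell) * active_r(g) - decay * x_g) dt + noise_sd dW
    with a per-cell lognormal basal rate b_g; a target gene follows
        dx_g = v * meanHill(regulators) - decay * x_g + noise
    where Hill is x^n/(K^n + x^n) for activation and K^n/(K^n + x^n) for
    repression.  Returns (expression genes x cells, regime label per cell).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    regulated = {tg for _, tg, _ in grn.edges}
    orphans = [g for g in grn.genes if g not in grn.tfs and g not in regulated]
    if orphans:
        raise ValueError(f"genes without any regulator or rule: {orphans}")

    rng = np.random.default_rng(seed)
    m = grn.n_genes
    idx = {g: i for i, g in enumerate(grn.genes)}
    n_regimes = grn.regime_tfs.shape[0]
    regimes = rng.integers(0, n_regimes, size=n_cells)

    tf_rows = np.array([idx[t] for t in grn.tfs])
    active = grn.regime_tfs[regimes].T.astype(float)  # (n_tfs, n_cells)
    # per-cell lognormal basal transcription: within-regime TF variability
    basal = 2.0 * np.exp(rng.normal(0.0, 0.4, size=(len(tf_rows), n_cells)))

    # per-target regulator index/sign lists
    reg_of: dict[int, list[tuple[int, int]]] = {}
    for tf, tg, sign in grn.edges:
        reg_of.setdefault(idx[tg], []).append((idx[tf], sign))

    x = rng.uniform(0.0, 1.0, size=(m, n_cells))
    kn = grn.hill_k ** grn.hill_n
    v_target = 2.0
    for _ in range(n_steps):
        drift = np.empty_like(x)
        drift[tf_rows] = basal * active - decay * x[tf_rows]
        xn = np.clip(x, 0.0, None) ** grn.hill_n
        hill_act = xn / (kn + xn)
        for tg, regs in reg_of.items():
            h = np.mean([hill_act[r] if s > 0 else 1.0 - hill_act[r]
                         for r, s in regs], axis=0)
            drift[tg] = v_target * h - decay * x[tg]
        x = x + dt * drift
        if noise_sd > 0:
            x = x + noise_sd * np.sqrt(dt) * rng.normal(size=x.shape)
        x = np.clip(x, 0.0, None)
    return x, regimes


@dataclass
class SyntheticDataset:
    """A complete desk-scale SRT benchmark instance."""

    cells: np.ndarray                 # genes x cells
    cell_regimes: np.ndarray          # regime per cell
    expression: ExpressionMatrix      # genes x spots (member-cell sums)
    coordinates: SpotCoordinates
    domain_labels: np.ndarray         # regime per spot
    truth: PlantedGRN
    seed: int
    spot_cells: list[np.ndarray] = field(default_factory=list)


def _grid_coords(n_spots: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()])[:n_spots].astype(float)


def bin_to_spots(cells: np.ndarray, cell_regimes: np.ndarray,
                 grn: PlantedGRN, n_spots: int,
                 domain_layout: str = "grid_blocks",
                 cells_per_spot: int = 4, seed: int = 0) -> SyntheticDataset:
    """Group similar cells into spots laid out on a square grid.

    Cells are embedded (first two principal components), and within each
    regime ordered by their first-PC coordinate so that each spot pools
    `cells_per_spot` mutually similar cells; spot value is the member sum.
    `grid_blocks` assigns each regime a contiguous vertical band of the
    grid; `gradient` mixes regimes with probability varying along x.
    Domain label of a spot is the regime its member cells came from.
    """
    m, n_cells = cells.shape
    if n_spots * cells_per_spot > n_cells:
        raise ValueError(
            f"need {n_spots * cells_per_spot} cells for {n_spots} spots x "
            f"{cells_per_spot}, have {n_cells}")
    rng = np.random.default_rng(seed)
    n_regimes = grn.regime_tfs.shape[0]
    coords = _grid_coords(n_spots)

    # spot -> regime assignment
    if domain_layout == "grid_blocks":
        # contiguous vertical bands along x, proportional to regime frequency
        counts = np.bincount(cell_regimes, minlength=n_regimes)
        quota = np.maximum(1, np.floor(
            counts / counts.sum() * n_spots)).astype(int)
        while quota.sum() < n_spots:
            quota[np.argmax(counts / quota)] += 1
        while quota.sum() > n_spots:
            quota[np.argmax(quota)] -= 1
        order = np.lexsort((coords[:, 1], coords[:, 0]))  # sweep along x
        spot_regime = np.empty(n_spots, dtype=int)
        pos = 0
        for r in range(n_regimes):
            spot_regime[order[pos:pos + quota[r]]] = r
            pos += quota[r]
    elif domain_layout == "gradient":
        x = coords[:, 0]
        frac = (x - x.min()) / max(x.max() - x.min(), 1.0)
        spot_regime = np.minimum((frac * n_regimes).astype(int), n_regimes - 1)
        flip = rng.random(n_spots) < 0.15
        spot_regime[flip] = rng.integers(0, n_regimes, size=flip.sum())
    else:
        raise ValueError(f"unknown domain_layout {domain_layout!r}")

    # order cells within each regime by similarity (first PC)
    centred = cells - cells.mean(axis=1, keepdims=True)
    # two leading PCs of the cell cloud; deterministic sign convention
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    pc = vt[:2] * np.sign(u[0, :2])[:, None]

    spot_values = np.zeros((m, n_spots))
    spot_cells: list[np.ndarray] = [np.empty(0, dtype=int)] * n_spots
    for r in range(n_regimes):
        members = np.flatnonzero(cell_regimes == r)
        members = members[np.argsort(pc[0, members], kind="stable")]
        spots_r = np.flatnonzero(spot_regime == r)
        take = len(spots_r) * cells_per_spot
        if take > len(members):
            # borrow unused cells of other regimes is not meaningful; instead
            # recycle members (sampling with replacement, seeded)
            members = rng.choice(members, size=take, replace=True)
        chunks = members[:take].reshape(len(spots_r), cells_per_spot)
        for spot, chunk in zip(spots_r, chunks):
            spot_values[:, spot] = cells[:, chunk].sum(axis=1)
            spot_cells[spot] = chunk

    width = len(str(n_spots - 1))
    expr = ExpressionMatrix(spot_values, list(grn.genes),
                            [f"S{i:0{width}d}" for i in range(n_spots)])
    return SyntheticDataset(
        cells=cells, cell_regimes=cell_regimes, expression=expr,
        coordinates=SpotCoordinates(coords), domain_labels=spot_regime,
        truth=grn, seed=seed, spot_cells=spot_cells)


def make_dataset(n_genes: int = 20, n_tfs: int = 5, n_spots: int = 500,
                 n_regimes: int = 3, cells_per_spot: int = 4,
                 noise_sd: float = 0.1, domain_layout: str = "grid_blocks",
                 seed: int = 0) -> SyntheticDataset:
    """One-call benchmark instance; all randomness flows from `seed`."""
    grn = planted_grn(n_genes=n_genes, n_tfs=n_tfs, n_regimes=n_regimes,
                      seed=seed)
    # oversample cells so regime proportions cover every spot's quota
    n_cells = int(n_spots * cells_per_spot * 1.5) + n_regimes
    cells, regimes = simulate_cells(grn, n_cells=n_cells, noise_sd=noise_sd,
                                    seed=seed + 1)
    return bin_to_spots(cells, regimes, grn, n_spots=n_spots,
                        domain_layout=domain_layout,
                        cells_per_spot=cells_per_spot, seed=seed + 2)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write expression (MTX + sidecars), coords, truth edges, labels."""
    from . import data_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_io.write_expression(ds.expression, outdir / "expression.mtx")
    import pandas as pd

    pd.DataFrame(ds.coordinates.coords, index=ds.expression.spot_ids,
                 columns=["x", "y"]).to_csv(outdir / "coords.tsv", sep="\t")
    pd.DataFrame([(a, b, s) for a, b, s in ds.truth.edges],
                 columns=["tf", "target", "sign"]).to_csv(
        outdir / "truth_edges.tsv", sep="\t", index=False)
    pd.DataFrame({"spot": ds.expression.spot_ids,
                  "domain": ds.domain_labels}).to_csv(
        outdir / "domains.tsv", sep="\t", index=False)
    (outdir / "tfs.txt").write_text("\n".join(ds.truth.tfs) + "\n")
    return outdir
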