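"""Reading, writing and preprocessing of expression data, coordinates and
prior gene networks.

Expression is carried genes x spots throughout the package (matrix
``X1 in R^{M x N}``).  On-disk orientation is resolved against the id
sidecars/metadata; duplicate gene symbols are collapsed by summation after
case-folding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class ExpressionMatrix:
    """Gene x spot expression with identifiers.

    values : (M, N) non-negative matrix, genes on rows.
    gene_ids : M unique, standardised (upper-cased, stripped) symbols.
    spot_ids : N spot/cell identifiers.
    is_log : whether values are log1p-transformed.
    """

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    is_log: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 genes and 2 spots, got {m}x{n}")
        if np.isnan(self.values).any():
            raise ValueError("expression contains NaN")
        if len(self.gene_ids) != m or len(self.spot_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]


@dataclass
class SpotCoordinates:
    """Spatial locations of spots: (N, d) with d=2 (x, y) or d=3 (x, y, z).

    For 3-D multi-slice data `slice_id` holds the integer slice index of
    each spot and must agree with the z column.
    """

    coords: np.ndarray
    slice_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be (N, 2) or (N, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.coords.shape[1] == 3:
            if self.slice_id is None:
                self.slice_id = np.round(self.coords[:, 2]).astype(int)
            self.slice_id = np.asarray(self.slice_id, dtype=int)
            if len(self.slice_id) != len(self.coords):
                raise ValueError("slice_id length mismatch")
            if not np.allclose(self.coords[:, 2], self.slice_id):
                raise ValueError("slice_id inconsistent with z column")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def is_3d(self) -> bool:
        return self.coords.shape[1] == 3


@dataclass
class PriorNetwork:
    """Weighted gene-gene prior adjacency A (M x M), confidences in [0, 1]."""

    adjacency: np.ndarray
    gene_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        m = len(self.gene_ids)
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency must be square over gene_ids")
        if (self.adjacency < 0).any():
            raise ValueError("prior weights must be non-negative")


def standardize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _collapse_duplicate_genes(values: np.ndarray,
                              gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    symbols = [standardize_symbol(g) for g in gene_ids]
    if len(set(symbols)) == len(symbols):
        return values, symbols
    order: dict[str, int] = {}
    for s in symbols:
        order.setdefault(s, len(order))
    merged = np.zeros((len(order), values.shape[1]), dtype=np.float64)
    for row, s in enumerate(symbols):
        merged[order[s]] += values[row]
    return merged, list(order)


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from mtx (+ sidecars), dense csv/tsv or h5ad.

    Returns genes on rows regardless of on-disk orientation; orientation is
    resolved via the gene/barcode sidecars (mtx), the header layout (csv) or
    AnnData's cells x genes convention (h5ad).  Duplicate gene symbols are
    summed.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv", ".h5ad": "h5ad"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from {path.name}")
    if format == "mtx":
        return _read_mtx(path)
    if format == "csv":
        return _read_dense(path)
    if format == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {format!r}")


def _read_sidecar_ids(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    return [str(v) for v in df.iloc[:, 0]]


def _read_mtx(path: Path) -> ExpressionMatrix:
    try:
        mat = spio.mmread(path)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
    mat = np.asarray(sparse.coo_matrix(mat).todense(), dtype=np.float64)
    genes_f = path.with_name("genes.tsv")
    spots_f = path.with_name("barcodes.tsv")
    if not genes_f.exists() or not spots_f.exists():
        raise FileNotFoundError(
            f"{path} needs genes.tsv and barcodes.tsv sidecars to fix orientation")
    genes = _read_sidecar_ids(genes_f)
    spots = _read_sidecar_ids(spots_f)
    if mat.shape == (len(genes), len(spots)):
        pass
    elif mat.shape == (len(spots), len(genes)):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither ({len(genes)} genes, "
            f"{len(spots)} barcodes) orientation")
    values, gene_ids = _collapse_duplicate_genes(mat, genes)
    return ExpressionMatrix(values, gene_ids, spots)


def _read_dense(path: Path) -> ExpressionMatrix:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed dense table {path}: {exc}") from exc
    values, gene_ids = _collapse_duplicate_genes(
        df.to_numpy(dtype=np.float64), [str(g) for g in df.index])
    return ExpressionMatrix(values, gene_ids, [str(c) for c in df.columns])


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    x = adata.X
    if sparse.issparse(x):
        x = np.asarray(x.todense())
    # AnnData stores cells x genes; our convention is genes x spots.
    values, gene_ids = _collapse_duplicate_genes(
        np.asarray(x, dtype=np.float64).T, [str(g) for g in adata.var_names])
    expr = ExpressionMatrix(values, gene_ids, [str(c) for c in adata.obs_names])
    return expr


def read_coordinates(path: str | Path) -> SpotCoordinates:
    """Read spot coordinates from TSV with columns (spot, x, y[, z])."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SpotCoordinates(df.to_numpy(dtype=np.float64))


def read_coordinates_h5ad(path: str | Path) -> SpotCoordinates:
    """Read coordinates stored in a .h5ad 'spatial' obsm slot."""
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise KeyError(f"{path} has no obsm['spatial'] coordinates")
    return SpotCoordinates(np.asarray(adata.obsm["spatial"], dtype=np.float64))


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     format: str | None = None) -> Path:
    """Write expression to mtx (+ sidecars), csv/tsv or h5ad."""
    path = Path(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv",
                  ".h5ad": "h5ad"}.get(path.suffix.lower())
    if format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(expr.values))
        pd.DataFrame(expr.gene_ids).to_csv(
            path.with_name("genes.tsv"), sep="\t", header=False, index=False)
        pd.DataFrame(expr.spot_ids).to_csv(
            path.with_name("barcodes.tsv"), sep="\t", header=False, index=False)
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        pd.DataFrame(expr.values, index=expr.gene_ids,
                     columns=expr.spot_ids).to_csv(path, sep=sep)
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=expr.values.T.copy())
        adata.obs_names = expr.spot_ids
        adata.var_names = expr.gene_ids
        adata.uns["is_log"] = expr.is_log
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _normalized_dispersion(values: np.ndarray) -> np.ndarray:
    """Dispersion (variance/mean) of each gene on the pre-log scale."""
    mean = values.mean(axis=1)
    var = values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def preprocess(expr: ExpressionMatrix, n_hvg: int | None = None,
               pseudocount: float = 1.0) -> ExpressionMatrix:
    """Optional HVG selection then natural-log ``log(x + pseudocount)``.

    Highly variable genes are ranked by dispersion (variance over mean) on
    the pre-log matrix; ties are broken by gene id so selection is
    deterministic.  Raises if the matrix is already log-transformed.
    """
    if expr.is_log:
        raise ValueError("expression is already log-transformed")
    values, gene_ids = expr.values, list(expr.gene_ids)
    if n_hvg is not None:
        if n_hvg > expr.n_genes:
            raise ValueError(f"n_hvg={n_hvg} exceeds gene count {expr.n_genes}")
        disp = _normalized_dispersion(values)
        order = sorted(range(len(gene_ids)),
                       key=lambda i: (-disp[i], gene_ids[i]))
        keep = sorted(order[:n_hvg])
        values = values[keep]
        gene_ids = [gene_ids[i] for i in keep]
    return ExpressionMatrix(np.log(values + pseudocount), gene_ids,
                            list(expr.spot_ids), is_log=True)


def read_prior_network(path: str | Path, gene_ids: list[str]) -> PriorNetwork:
    """Assemble the prior adjacency A from a (geneA, geneB, confidence) TSV.

    Edges are restricted to `gene_ids`; confidences are rescaled to [0, 1]
    by the maximum confidence in the file; interactions are treated as
    undirected so A is symmetric.  Genes absent from the edge list keep
    zero rows/columns.
    """
    path = Path(path)
    gene_ids = [standardize_symbol(g) for g in gene_ids]
    index = {g: i for i, g in enumerate(gene_ids)}
    m = len(gene_ids)
    a = np.zeros((m, m), dtype=np.float64)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"prior network file {path} is empty; A is all-zero",
                      stacklevel=2)
        return PriorNetwork(a, gene_ids, source=str(path))
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (geneA, geneB, confidence)")
    conf = df.iloc[:, 2].to_numpy(dtype=np.float64)
    max_conf = conf.max() if len(conf) else 0.0
    if max_conf <= 0:
        raise ValueError(f"{path}: confidences must contain a positive value")
    hits = 0
    for (ga, gb), c in zip(df.iloc[:, :2].itertuples(index=False), conf):
        ia = index.get(standardize_symbol(ga))
        ib = index.get(standardize_symbol(gb))
        if ia is None or ib is None:
            continue
        w = c / max_conf
        a[ia, ib] = max(a[ia, ib], w)
        a[ib, ia] = max(a[ib, ia], w)
        hits += 1
    if hits == 0:
        raise ValueError(f"{path}: no edges overlap the given gene ids")
    return PriorNetwork(a, gene_ids, source=str(path))


def read_tf_list(path: str | Path) -> list[str]:
    """One TF symbol per line; standardised, order-preserving, de-duplicated."""
    seen: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        sym = standardize_symbol(line)
        if sym:
            seen.setdefault(sym, None)
    return list(seen)
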