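"""Reading, writing and preparing paired scRNA-seq / spatial expression data.

Two modalities enter the pipeline: a dissociated scRNA-seq matrix (cells x
genes, no coordinates) and a spatial transcriptomics (ST) matrix (spots x
genes) with a 2-D coordinate table.  Both are restricted to their overlapping
gene panel, library-size normalized, and the ST zero pattern is recorded as a
binary mask used by the masked reconstruction loss.  Cross-validation splits
are taken over *genes*, not observations.

Supported on-disk formats:

* ``csv`` / ``tsv`` -- dense, header row = gene IDs, first column = observation IDs
* ``mtx`` -- MatrixMarket coordinate triplets with ``<stem>_genes.txt`` /
  ``<stem>_obs.txt`` sidecars (one ID per line) and an optional
  ``<stem>_coords.tsv`` two-column table
* ``h5`` -- an HDF5 file following the h5ad convention (``X`` dense or CSR,
  ``obs``/``var`` ID arrays, 2-D coordinates under ``obsm['spatial']``)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FORMATS = ("csv", "tsv", "mtx", "h5")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """One modality's expression values plus gene/observation identifiers.

    ``values`` is observations x genes, finite and non-negative.  ``coords``
    (spots only) is an n_obs x 2 array in arbitrary spatial units, stored as
    given; observation indexing is 0-based throughout.
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.obs_ids)} observations x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.obs_ids), 2):
                raise ValueError("coords must be n_obs x 2")

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Column-subset (and reorder) to ``gene_ids``."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(self.values[:, idx], list(gene_ids),
                                list(self.obs_ids), self.coords)


@dataclass
class PairedDataset:
    """sc and ST matrices aligned on the overlapping gene panel.

    ``mask[i, j] = 1`` exactly where the ST entry is non-zero; the masked
    reconstruction loss therefore weights observed expression.
    """

    sc: ExpressionMatrix
    st: ExpressionMatrix
    overlap_genes: list[str]
    mask: np.ndarray

    def __post_init__(self):
        if self.sc.gene_ids != self.overlap_genes or self.st.gene_ids != self.overlap_genes:
            raise ValueError("both matrices must be column-aligned to overlap_genes")
        if len(self.overlap_genes) < 1:
            raise ValueError("overlap gene panel is empty")
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != self.st.values.shape:
            raise ValueError("mask shape must equal ST values shape")

    @property
    def n_genes(self) -> int:
        return len(self.overlap_genes)


@dataclass
class GeneFoldSplit:
    """A K-way partition of gene indices for gene-level cross-validation."""

    K: int
    folds: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.K != len(self.folds):
            raise ValueError("K must equal the number of folds")
        flat = np.concatenate(self.folds) if self.folds else np.array([], dtype=int)
        if len(np.unique(flat)) != flat.size:
            raise ValueError("folds must be disjoint")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _mtx_sidecars(path: Path) -> tuple[Path, Path, Path]:
    stem = path.with_suffix("")
    return (stem.parent / f"{stem.name}_genes.txt",
            stem.parent / f"{stem.name}_obs.txt",
            stem.parent / f"{stem.name}_coords.tsv")


def read_expression(path, fmt: str, coords_path=None) -> ExpressionMatrix:
    """Read one modality from disk; see module docstring for layouts.

    Orientation is observation-major; if sidecar/ID lengths only fit the
    transposed matrix, it is auto-transposed with a logged warning.
    """
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
        coords = _read_coords(coords_path) if coords_path else None
        return ExpressionMatrix(values, list(df.columns.astype(str)),
                                list(df.index.astype(str)), coords)

    if fmt == "mtx":
        from scipy.io import mmread

        genes_p, obs_p, coords_p = _mtx_sidecars(path)
        for p in (genes_p, obs_p):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX sidecar {p}")
        genes = genes_p.read_text().split()
        obs = obs_p.read_text().split()
        mat = np.asarray(mmread(path).todense(), dtype=float)
        if mat.shape != (len(obs), len(genes)):
            if mat.shape == (len(genes), len(obs)):
                logger.warning("MTX matrix %s is gene-major; transposing", path)
                mat = mat.T
            else:
                raise ValueError(
                    f"MTX shape {mat.shape} does not match sidecars "
                    f"({len(obs)} observations, {len(genes)} genes)")
        coords = None
        cp = Path(coords_path) if coords_path else coords_p
        if cp.exists():
            coords = _read_coords(cp)
        return ExpressionMatrix(mat, genes, obs, coords)

    # fmt == "h5": h5ad-convention layout
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = X.toarray()
    coords = None
    if "spatial" in adata.obsm:
        coords = np.asarray(adata.obsm["spatial"], dtype=float)
    return ExpressionMatrix(np.asarray(X, dtype=float),
                            list(adata.var_names.astype(str)),
                            list(adata.obs_names.astype(str)), coords)


def write_expression(mat: ExpressionMatrix, path, fmt: str) -> None:
    """Inverse of :func:`read_expression` for every supported format."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")

    if fmt in ("csv", "tsv"):
        df = pd.DataFrame(mat.values, index=mat.obs_ids, columns=mat.gene_ids)
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
        return

    if fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        genes_p, obs_p, coords_p = _mtx_sidecars(path)
        mmwrite(str(path), coo_matrix(mat.values))
        genes_p.write_text("\n".join(mat.gene_ids) + "\n")
        obs_p.write_text("\n".join(mat.obs_ids) + "\n")
        if mat.coords is not None:
            np.savetxt(coords_p, mat.coords, delimiter="\t")
        return

    import anndata as ad

    adata = ad.AnnData(X=mat.values,
                       obs=pd.DataFrame(index=pd.Index(mat.obs_ids)),
                       var=pd.DataFrame(index=pd.Index(mat.gene_ids)))
    if mat.coords is not None:
        adata.obsm["spatial"] = mat.coords
    adata.write_h5ad(path)


def _read_coords(path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"coordinate table {path} must have 2 columns")
    return arr


# ---------------------------------------------------------------------------
# pairing, normalization, folds
# ---------------------------------------------------------------------------

def compute_overlap(sc: ExpressionMatrix, st: ExpressionMatrix) -> PairedDataset:
    """Subset both modalities to their shared gene panel and build the mask.

    Gene IDs are matched by case-sensitive exact string equality and the
    intersection is ordered lexicographically so the result is independent of
    input file order.
    """
    if st.coords is None:
        raise ValueError("ST matrix must carry spatial coordinates")
    overlap = sorted(set(sc.gene_ids) & set(st.gene_ids))
    if not overlap:
        raise ValueError("no overlapping genes between the two modalities")
    sc_o = sc.subset_genes(overlap)
    st_o = st.subset_genes(overlap)
    mask = (st_o.values != 0).astype(float)
    return PairedDataset(sc=sc_o, st=st_o, overlap_genes=overlap, mask=mask)


def normalize(mat: ExpressionMatrix, target_sum: float = 1e4,
              log_transform: bool = True) -> ExpressionMatrix:
    """Library-size normalization: scale each observation with a nonzero
    total to ``target_sum``, then optionally log(1+x).  All-zero observations
    are left unchanged (no NaN)."""
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = mat.values.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.ones_like(totals),
                      where=totals > 0)
    values = mat.values * scale
    if log_transform:
        values = np.log1p(values)
    return ExpressionMatrix(values, list(mat.gene_ids), list(mat.obs_ids),
                            mat.coords)


def normalize_pair(ds: PairedDataset, target_sum: float = 1e4,
                   log_transform: bool = True) -> PairedDataset:
    """Normalize both modalities of a paired dataset; the zero pattern (and
    hence the mask) is unchanged by library-size scaling and log1p."""
    return PairedDataset(sc=normalize(ds.sc, target_sum, log_transform),
                         st=normalize(ds.st, target_sum, log_transform),
                         overlap_genes=list(ds.overlap_genes),
                         mask=ds.mask.copy())


def gene_kfold_split(n_genes: int, K: int, seed: int) -> GeneFoldSplit:
    """Seeded shuffle of gene indices followed by contiguous chunking into K
    folds whose sizes differ by at most one."""
    if not 2 <= K <= n_genes:
        raise ValueError(f"K={K} out of range for {n_genes} genes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    folds = [np.sort(chunk) for chunk in np.array_split(order, K)]
    return GeneFoldSplit(K=K, folds=folds)
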