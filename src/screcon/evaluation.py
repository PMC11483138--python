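"""Reconstruction metrics and gene-filtration diagnostics.

Per-gene metrics compare a predicted spot-expression vector with the
reference one:

* PCC / SPCC -- Pearson and Spearman (average ranks for ties) correlation
* SSIM -- structural similarity computed from *global* statistics (means,
  variances, covariance over all spots) of the two vectors after min-max
  scaling to [0, 1], with the standard constants C1 = 0.01^2, C2 = 0.03^2.
  Spots are not pixels, so no windowing or rasterization is involved.
* RMSE -- root mean squared error
* COSSIM -- cosine similarity (0 when either vector is all-zero)

Diagnostics for the gene-filtration module: the overlap rate of the selected
genes with a variance-ranked highly-variable-gene reference, the per-gene
fraction-of-variance score, and a per-gene rank-test p-value measuring
whether predicted expression separates the spatially high-signal spots from
the low-signal ones.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

METRIC_NAMES = ("pcc", "spcc", "ssim", "rmse", "cossim")


@dataclass
class MetricsReport:
    per_gene: pd.DataFrame  # columns: gene_id, pcc, spcc, ssim, rmse, cossim
    aggregate: dict
    fold_id: int = -1


@dataclass
class FiltrationDiagnostics:
    selected_genes: list
    overlap_rate: float
    fv_scores: np.ndarray
    neglog_p: np.ndarray
    elapsed_s: float

    def to_dict(self) -> dict:
        return {"selected_genes": list(self.selected_genes),
                "overlap_rate": self.overlap_rate,
                "fv_scores": np.asarray(self.fv_scores).tolist(),
                "neglog_p": np.asarray(self.neglog_p).tolist(),
                "elapsed_s": self.elapsed_s}


# ---------------------------------------------------------------------------
# per-gene metrics
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if den == 0:
        return 0.0
    return float((xc * yc).sum() / den)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _ssim_global(x: np.ndarray, y: np.ndarray) -> float:
    """Global-statistics SSIM of two min-max-scaled vectors on [0, 1]."""
    x = _minmax(x)
    y = _minmax(y)
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def _cosine(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(x @ y / (nx * ny))


def per_gene_metrics(pred: np.ndarray, target: np.ndarray, coords=None,
                     gene_ids=None, fold_id: int = -1) -> MetricsReport:
    """All five metrics for every gene column of ``pred`` vs ``target``.

    ``coords`` is accepted for API symmetry with spatial workflows; the
    global-statistics SSIM does not depend on spot geometry.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    n_genes = pred.shape[1]
    if gene_ids is None:
        gene_ids = [f"gene{j}" for j in range(n_genes)]

    rows = []
    for j in range(n_genes):
        x, y = pred[:, j], target[:, j]
        rx = stats.rankdata(x, method="average")
        ry = stats.rankdata(y, method="average")
        rows.append({
            "gene_id": gene_ids[j],
            "pcc": _pearson(x, y),
            "spcc": _pearson(rx, ry),
            "ssim": _ssim_global(x, y),
            "rmse": float(np.sqrt(((x - y) ** 2).mean())),
            "cossim": _cosine(x, y),
        })
    per_gene = pd.DataFrame(rows)
    aggregate = {m: float(per_gene[m].mean()) for m in METRIC_NAMES}
    return MetricsReport(per_gene=per_gene, aggregate=aggregate, fold_id=fold_id)


# ---------------------------------------------------------------------------
# gene-filtration diagnostics
# ---------------------------------------------------------------------------

def top_variable_genes(values: np.ndarray, gene_ids, n: int) -> list:
    """The ``n`` genes with the largest variance (ties toward lower index)."""
    var = np.asarray(values, dtype=float).var(axis=0)
    order = np.argsort(-var, kind="stable")[:n]
    return [gene_ids[i] for i in order]


def overlap_rate(selected, reference_hvg) -> float:
    """100 * |selected AND reference| / |selected|."""
    selected = list(selected)
    if not selected:
        raise ValueError("selected gene set is empty")
    ref = set(reference_hvg)
    return 100.0 * sum(g in ref for g in selected) / len(selected)


def fv_scores(matrix: np.ndarray) -> np.ndarray:
    """Fraction of variance per gene: var_g / sum_g var_g (sums to 1)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    var = matrix.var(axis=0)
    total = var.sum()
    if total == 0:
        raise ValueError("all-constant matrix has no variance to apportion")
    return var / total


def rank_test_pvalues(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-gene -log10 p of a two-sided Wilcoxon rank-sum test contrasting
    predicted expression in the top-quartile reference spots against the
    bottom-quartile ones (spatial-signal detectability of the prediction).

    Exact null when both groups have fewer than 25 spots and no ties occur;
    otherwise the normal approximation with tie correction.  A constant
    reference column has no quartile contrast and records p = 1.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    n = pred.shape[0]
    if n < 5:
        raise ValueError("need at least 5 spots")
    q = max(1, n // 4)
    out = np.zeros(pred.shape[1])
    for j in range(pred.shape[1]):
        t = target[:, j]
        if t.max() == t.min():
            out[j] = 0.0  # p = 1
            continue
        order = np.argsort(t, kind="stable")
        lo = pred[order[:q], j]
        hi = pred[order[-q:], j]
        if hi.max() == hi.min() and lo.max() == lo.min() and hi[0] == lo[0]:
            out[j] = 0.0  # constant prediction: no separation
            continue
        combined = np.concatenate([hi, lo])
        no_ties = len(np.unique(combined)) == len(combined)
        method = "exact" if (no_ties and len(hi) < 25 and len(lo) < 25) else "asymptotic"
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
        out[j] = -np.log10(max(res.pvalue, np.finfo(float).tiny))
    return out


def filtration_diagnostics(model, dataset, phi: float | None = None,
                           pred: np.ndarray | None = None) -> FiltrationDiagnostics:
    """Score genes with the trained model, select the top phi fraction, and
    compare against the variance-ranked reference.

    The overlap-rate reference is the top-|selected| genes of the single-cell
    matrix by variance; ``elapsed_s`` times scoring + selection only.
    """
    from .model import select_genes

    phi = phi if phi is not None else model.config.filtration_phi
    t0 = time.perf_counter()
    scores = model.contribution_scores(dataset.sc.values)
    filt = select_genes(scores, phi)
    elapsed = time.perf_counter() - t0
    selected = [dataset.overlap_genes[i] for i in filt.kept_indices]
    reference = top_variable_genes(dataset.sc.values, dataset.overlap_genes,
                                   len(selected))
    orate = overlap_rate(selected, reference)
    fv = fv_scores(dataset.st.values)
    if pred is not None:
        nlp = rank_test_pvalues(pred, dataset.st.values)
    else:
        nlp = np.zeros(dataset.n_genes)
    return FiltrationDiagnostics(selected_genes=selected, overlap_rate=orate,
                                 fv_scores=fv, neglog_p=nlp, elapsed_s=elapsed)


# ---------------------------------------------------------------------------
# distribution-level summaries
# ---------------------------------------------------------------------------

def correlation_heatmap_data(pred: np.ndarray, target: np.ndarray):
    """Pearson correlation matrices of the stacked [pred; target] blocks.

    Returns ``(spot_corr, gene_corr)``: spot_corr is (2 n_st x 2 n_st) over
    the row-stacked spots, gene_corr is (2 G x 2 G) over the column-stacked
    genes, each exposing within- and cross-block quadrants.  Zero-variance
    rows/columns yield 0 rather than NaN.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    spot_block = np.vstack([pred, target])          # rows = spots
    gene_block = np.hstack([pred, target])          # columns = genes
    with np.errstate(invalid="ignore", divide="ignore"):
        spot_corr = np.corrcoef(spot_block)
        gene_corr = np.corrcoef(gene_block, rowvar=False)
    return np.nan_to_num(spot_corr), np.nan_to_num(gene_corr)


def energy_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """Energy distance between two point clouds in gene-expression space:
    2 E||X - Y|| - E||X - X'|| - E||Y - Y'||."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    dxy = cdist(X, Y).mean()
    dxx = cdist(X, X).mean()
    dyy = cdist(Y, Y).mean()
    return float(2 * dxy - dxx - dyy)


def save_diagnostic_plots(pred: np.ndarray, target: np.ndarray, outdir,
                          fv: np.ndarray | None = None,
                          neglog_p: np.ndarray | None = None) -> list:
    """Write correlation heatmaps (and, when given, the FV vs -log10 p
    scatter) as PNGs; returns the written paths.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    spot_corr, gene_corr = correlation_heatmap_data(pred, target)
    for name, mat in (("spot_correlation", spot_corr),
                      ("gene_correlation", gene_corr)):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(name.replace("_", " "))
        fig.colorbar(im, ax=ax)
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if fv is not None and neglog_p is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(fv, neglog_p, s=12)
        ax.set_xlabel("fraction of variance")
        ax.set_ylabel("-log10 p (rank test)")
        path = outdir / "fv_vs_rank_test.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
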