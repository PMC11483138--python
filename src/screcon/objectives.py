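"""The three training loss terms and their weighted sum.

* ``recon_loss`` -- plain mean squared error over all (spot, gene) entries.
* ``mask_loss`` -- squared error restricted to observed (non-zero) ST
  entries, averaged over the masked entries so its scale stays comparable to
  ``recon_loss`` regardless of sparsity.
* ``corr_loss`` -- one minus the mean over gene columns of the Pearson
  correlation between predicted and reference spot-expression vectors;
  minimizing it pushes every gene's spatial profile toward the reference
  shape independently of its magnitude.

Total objective: ``recon + alpha1 * mask + alpha2 * corr``.

All three accept either numpy arrays or autodiff tensors and return a
scalar :class:`~screcon._autodiff.Tensor` (float() it for the value), so the
same code path serves both evaluation and gradient-based training.  Losses
are computed on normalized-space values, i.e. the space the network is
trained to output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    alpha1: float = 0.1
    alpha2: float = 0.5

    def __post_init__(self):
        if not (np.isfinite(self.alpha1) and np.isfinite(self.alpha2)):
            raise ValueError("loss weights must be finite")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossReport:
    recon: float
    mask: float
    corr: float
    total: float

    def to_dict(self) -> dict:
        return {"recon": self.recon, "mask": self.mask,
                "corr": self.corr, "total": self.total}


def _check_shapes(a, b) -> None:
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if sa != sb:
        raise ValueError(f"shape mismatch: {sa} vs {sb}")


def recon_loss(pred, target) -> Tensor:
    """Mean over all entries of the squared difference."""
    _check_shapes(pred, target)
    d = ad.sub(pred, target)
    return ad.mean_all(ad.mul(d, d))


def mask_loss(pred, target, mask) -> Tensor:
    """Squared error summed over mask-1 entries, divided by max(1, #ones)."""
    _check_shapes(pred, target)
    _check_shapes(pred, mask)
    m = mask.value if isinstance(mask, Tensor) else np.asarray(mask, dtype=float)
    if not np.all((m == 0) | (m == 1)):
        raise ValueError("mask must be binary")
    d = ad.sub(pred, target)
    s = ad.sum_all(ad.mul(m, ad.mul(d, d)))
    return ad.mul(s, 1.0 / max(1.0, float(m.sum())))


def gene_pearson(pred_col, target_col) -> float:
    """Pearson correlation of two spot vectors; 0 when either is constant."""
    x = np.asarray(pred_col, dtype=float).ravel()
    y = np.asarray(target_col, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("columns must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum()) * np.sqrt((yc ** 2).sum())
    if den < EPS:
        return 0.0
    return float((xc * yc).sum() / den)


class GeneCorrLoss:
    """Column-wise Pearson correlation loss against a fixed reference.

    The reference's centered columns and their norms are precomputed once,
    which matters when the same target is scored every training epoch.
    """

    def __init__(self, target):
        t = target.value if isinstance(target, Tensor) else np.asarray(target, dtype=float)
        if t.shape[-2] < 2:
            raise ValueError("need at least 2 observations per column")
        self.shape = t.shape
        self.tc = t - t.mean(axis=-2, keepdims=True)
        self.t_norm = np.sqrt((self.tc ** 2).sum(axis=-2, keepdims=True))

    def __call__(self, pred) -> Tensor:
        p = ad.as_tensor(pred)
        if p.shape != self.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {self.shape}")
        n = p.shape[-2]
        col_mean = ad.mul(ad.sum_axis0(p), 1.0 / n)
        pc = ad.sub(p, col_mean)
        num = ad.sum_axis0(ad.mul(pc, self.tc))
        p_ss = ad.sum_axis0(ad.mul(pc, pc))
        den = ad.mul(ad.sqrt(p_ss), self.t_norm)
        ok = (den.value >= EPS).astype(p.dtype)  # zero out degenerate columns
        rho = ad.mul(ad.div(num, ad.clamp_min(den, EPS)), ok)
        return ad.sub(1.0, ad.mean_all(rho))


def corr_loss(pred, target) -> Tensor:
    """1 - mean over gene columns of the per-gene Pearson correlation.

    Columns where either vector is (numerically) constant contribute rho = 0,
    keeping the loss finite on sparse data with all-zero genes.
    """
    _check_shapes(pred, target)
    return GeneCorrLoss(target)(pred)


def total_loss(pred, target, mask, weights: LossWeights) -> LossReport:
    """Weighted sum of the three terms; the returned report carries the
    scalar graph node as ``report.node`` when the inputs track gradients."""
    r = recon_loss(pred, target)
    m = mask_loss(pred, target, mask)
    c = corr_loss(pred, target)
    tot = ad.add(r, ad.add(ad.mul(m, weights.alpha1), ad.mul(c, weights.alpha2)))
    report = LossReport(recon=r.item(), mask=m.item(), corr=c.item(),
                        total=tot.item())
    report.node = tot
    return report
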