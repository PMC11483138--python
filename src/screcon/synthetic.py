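"""Synthetic paired scRNA-seq / spatial transcriptomics generator.

Real paired benchmarks (a dissociated single-cell matrix plus a spatial
panel measured on the same tissue) share a few structural features this
generator emulates: the two modalities overlap on a common gene panel; a
minority of genes carry clear spatial programs (stripes, blobs, gradients)
while the rest are spatially unstructured; the spatial matrix is highly
sparse; and the single-cell side is distorted by a per-gene batch effect
(multiplicative scale plus additive shift) relative to the spatial side.

Cells are given latent positions drawn uniformly over the same unit square
the spots tile, and pattern genes are evaluated from the *same* spatial
program in both modalities, so a reconstruction model has a recoverable
signal linking the two.  Platform-specific noise (UMI saturation,
segmentation error) is deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, PairedDataset, compute_overlap

PATTERN_KINDS = ("stripe", "blob", "gradient")


@dataclass
class SimConfig:
    """Study conditions for one synthetic paired dataset.

    Defaults are the package's standard benchmark: 300 cells x 200 spots over
    120 genes of which 24 carry spatial signal, 60% spatial zeros, and a
    per-gene batch distortion (scale drawn between 1 and ``batch_scale``,
    shift between 0 and ``batch_shift``) applied to the single-cell side.
    """

    n_sc: int = 300
    n_st: int = 200
    n_genes: int = 120
    n_pattern_genes: int = 24
    pattern_kinds: tuple = PATTERN_KINDS
    zero_fraction: float = 0.6
    batch_scale: float = 2.0
    batch_shift: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0
    sparsity_mode: str = "smallest"  # or "bernoulli"
    pattern_amplitude: float = 3.0
    background_loading: float = 0.3

    def validate(self) -> None:
        if self.n_pattern_genes > self.n_genes:
            raise ValueError("n_pattern_genes exceeds n_genes")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError(f"zero_fraction={self.zero_fraction} must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        unknown = set(self.pattern_kinds) - set(PATTERN_KINDS)
        if unknown:
            raise ValueError(f"unknown pattern kinds {sorted(unknown)}")
        if self.sparsity_mode not in ("smallest", "bernoulli"):
            raise ValueError("sparsity_mode must be 'smallest' or 'bernoulli'")


@dataclass
class SimTruth:
    """Ground truth for a generated pair: which genes are patterned, their
    noise-free spatial signals at the spots, and the per-cell loadings."""

    pattern_gene_indices: np.ndarray
    spot_patterns: np.ndarray  # n_st x n_pattern_genes, noise-free
    sc_latent: np.ndarray      # n_sc x n_pattern_genes pattern loadings
    cell_coords: np.ndarray = field(default=None)


def grid_coords(n: int) -> np.ndarray:
    """First ``n`` points of a regular unit-square grid (row-major)."""
    side = math.ceil(math.sqrt(n))
    xs, ys = np.meshgrid(np.linspace(0, 1, side), np.linspace(0, 1, side),
                         indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    return pts[:n]


def spatial_pattern(kind: str, coords: np.ndarray, params: dict) -> np.ndarray:
    """Evaluate one non-negative spatial program at ``coords``.

    * ``stripe``: sinusoid of frequency ``freq`` (period 1/freq) along axis 1,
      optional ``phase``
    * ``blob``: isotropic Gaussian bump at ``center`` with width ``width``
    * ``gradient``: linear ramp along ``axis`` (0 or 1), min-shifted to 0
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if kind == "stripe":
        freq = params.get("freq", 3.0)
        phase = params.get("phase", 0.0)
        v = 0.5 * (1.0 + np.cos(2 * np.pi * freq * coords[:, 1] - phase))
    elif kind == "blob":
        center = np.asarray(params.get("center", (0.5, 0.5)), dtype=float)
        width = params.get("width", 0.15)
        d2 = ((coords - center) ** 2).sum(axis=1)
        v = np.exp(-d2 / (2 * width ** 2))
    elif kind == "gradient":
        axis = int(params.get("axis", 0))
        sign = params.get("sign", 1.0)
        v = sign * coords[:, axis]
        v = v - v.min()
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return np.maximum(v, 0.0)


def _apply_sparsity(values: np.ndarray, zero_fraction: float, mode: str,
                    rng: np.random.Generator) -> np.ndarray:
    if zero_fraction <= 0:
        return values
    out = values.copy()
    if mode == "smallest":
        # deterministic: zero the smallest entries until the target is hit
        k = int(round(zero_fraction * out.size))
        if k > 0:
            flat = out.ravel()
            thresh_idx = np.argsort(flat, kind="stable")[:k]
            flat[thresh_idx] = 0.0
    else:
        drop = rng.random(out.shape) < zero_fraction
        out[drop] = 0.0
    return out


def generate_paired(cfg: SimConfig) -> tuple[PairedDataset, SimTruth]:
    """Generate a paired dataset with planted spatial structure.

    Fully reproducible from ``cfg.seed``; ST sparsity is imposed by zeroing
    the smallest entries (deterministic) unless ``sparsity_mode='bernoulli'``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    spot_coords = grid_coords(cfg.n_st)
    cell_coords = rng.uniform(0, 1, size=(cfg.n_sc, 2))

    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    pattern_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_pattern_genes,
                                     replace=False))

    # per-gene baseline expression shared by both modalities; lognormal,
    # like the orders-of-magnitude spread of real transcript abundances
    base = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=cfg.n_genes)
    # marker strengths vary too: some markers are strong, some subtle
    amp = cfg.pattern_amplitude * rng.lognormal(mean=0.0, sigma=0.5,
                                                size=cfg.n_pattern_genes)

    spot_patterns = np.zeros((cfg.n_st, cfg.n_pattern_genes))
    sc_latent = np.zeros((cfg.n_sc, cfg.n_pattern_genes))
    kinds = list(cfg.pattern_kinds)
    for j in range(cfg.n_pattern_genes):
        kind = kinds[j % len(kinds)]
        if kind == "stripe":
            params = {"freq": float(rng.integers(2, 5)),
                      "phase": rng.uniform(0, 2 * np.pi)}
        elif kind == "blob":
            params = {"center": rng.uniform(0.2, 0.8, size=2),
                      "width": rng.uniform(0.1, 0.2)}
        else:
            params = {"axis": int(rng.integers(0, 2)),
                      "sign": float(rng.choice([-1.0, 1.0]))}
        spot_patterns[:, j] = amp[j] * spatial_pattern(kind, spot_coords, params)
        sc_latent[:, j] = amp[j] * spatial_pattern(kind, cell_coords, params)

    # non-marker genes are not pure noise: like real co-expression modules,
    # each loads weakly on a couple of the latent spatial programs
    bg_idx = np.setdiff1d(np.arange(cfg.n_genes), pattern_idx)
    bg_load = np.zeros((cfg.n_pattern_genes, cfg.n_genes))
    if cfg.n_pattern_genes > 0 and cfg.background_loading > 0:
        for g in bg_idx:
            k = rng.choice(cfg.n_pattern_genes, size=min(2, cfg.n_pattern_genes),
                           replace=False)
            bg_load[k, g] = rng.normal(0, cfg.background_loading, size=k.size)

    st_vals = np.tile(base, (cfg.n_st, 1))
    st_vals[:, pattern_idx] += spot_patterns
    st_vals += spot_patterns @ bg_load[:, :]
    st_vals = st_vals + rng.normal(0, cfg.noise_sd, size=st_vals.shape)
    st_vals = np.maximum(st_vals, 0.0)
    st_vals = _apply_sparsity(st_vals, cfg.zero_fraction, cfg.sparsity_mode, rng)

    sc_vals = np.tile(base, (cfg.n_sc, 1))
    sc_vals[:, pattern_idx] += sc_latent
    sc_vals += sc_latent @ bg_load[:, :]
    sc_vals = sc_vals + rng.normal(0, cfg.noise_sd, size=sc_vals.shape)
    # per-gene batch distortion on the single-cell side only
    gene_scale = rng.uniform(min(1.0, cfg.batch_scale),
                             max(1.0, cfg.batch_scale), size=cfg.n_genes)
    gene_shift = rng.uniform(min(0.0, cfg.batch_shift),
                             max(0.0, cfg.batch_shift), size=cfg.n_genes)
    sc_vals = np.maximum(sc_vals * gene_scale + gene_shift, 0.0)

    sc = ExpressionMatrix(sc_vals, gene_ids,
                          [f"cell{i:04d}" for i in range(cfg.n_sc)])
    st = ExpressionMatrix(st_vals, gene_ids,
                          [f"spot{i:04d}" for i in range(cfg.n_st)],
                          coords=spot_coords)
    ds = compute_overlap(sc, st)
    truth = SimTruth(pattern_gene_indices=pattern_idx,
                     spot_patterns=spot_patterns, sc_latent=sc_latent,
                     cell_coords=cell_coords)
    return ds, truth
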