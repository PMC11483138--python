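"""Multi-scale gene-token attention network for spatial reconstruction.

Tokens are *genes*: the input to the network is the overlap-gene submatrix of
the scRNA-seq data transposed to (n_genes x n_cells), so each token's feature
vector is that gene's expression across all cells.  Per scale, queries, keys
and values are produced by LeakyReLU-activated affine projections; the
attended output is a row-stochastic scaled dot-product mixture of value rows
plus a lambda-weighted residual of the (affinely aligned) input.  A
gene-filtration variant scores each gene by the diagonal of the row-softmax
gene correlation matrix S = softmax(Q K^T / sqrt(L)), keeps the top
floor(phi * n_genes) genes, and cross-attends the full-gene queries against
keys/values projected from the retained genes only.  The per-scale outputs
are concatenated and a two-layer decoder maps each gene token to its
predicted expression over the n_st spots.

Because parameters are shared across tokens, genes never seen in training
are still valid inputs: held-out genes are predicted by running their token
vectors through the trained network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

DEFAULT_SCALES = (1024, 2048, 4096)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    scales            per-scale attention channel counts (Lambda_1..Lambda_N)
    residual_lambda   weight of the aligned-input residual (lambda >= 0)
    filtration_phi    fraction of genes retained by filtration, phi in (0, 1]
    decoder_hidden    hidden width of the two-layer decoder
    use_multiscale    when off, only the last (widest) scale is used
    use_filtration    when off, plain residual self-attention per scale
    learnable_lambda  treat lambda as a trained scalar instead of a constant
    leaky_slope       negative slope of every LeakyReLU
    dtype             'float64' (default) or 'float32'
    """

    scales: tuple = DEFAULT_SCALES
    residual_lambda: float = 1.0
    filtration_phi: float = 0.5
    decoder_hidden: int = 512
    use_multiscale: bool = True
    use_filtration: bool = True
    learnable_lambda: bool = False
    leaky_slope: float = 0.01
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self):
        self.scales = tuple(int(s) for s in self.scales)
        if not self.scales or any(s < 1 for s in self.scales):
            raise ValueError("scales must be positive integers")
        if not 0 < self.filtration_phi <= 1:
            raise ValueError("filtration_phi must lie in (0, 1]")
        if self.residual_lambda < 0:
            raise ValueError("residual_lambda must be >= 0")
        if self.decoder_hidden < 1:
            raise ValueError("decoder_hidden must be positive")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def active_scales(self) -> tuple:
        return self.scales if self.use_multiscale else (self.scales[-1],)


@dataclass
class AttentionState:
    """One scale's attention intermediates (numpy views for inspection)."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    S: np.ndarray  # gene correlation matrix, row-stochastic
    A: np.ndarray


@dataclass
class FiltrationResult:
    """Outcome of diagonal-score gene selection at one scale."""

    scores: np.ndarray
    kept_indices: np.ndarray
    filtered_input: np.ndarray | None = None


# ---------------------------------------------------------------------------
# functional building blocks (each independently testable)
# ---------------------------------------------------------------------------

def project_qkv(X, Wq, bq, Wk, bk, Wv, bv, slope: float = 0.01):
    """Q, K, V = LeakyReLU(X W + b), each with its own affine parameters."""
    X = ad.as_tensor(X)
    Q = ad.leaky_relu(ad.add(ad.matmul(X, ad.as_tensor(Wq)), ad.as_tensor(bq)), slope)
    K = ad.leaky_relu(ad.add(ad.matmul(X, ad.as_tensor(Wk)), ad.as_tensor(bk)), slope)
    V = ad.leaky_relu(ad.add(ad.matmul(X, ad.as_tensor(Wv)), ad.as_tensor(bv)), slope)
    return Q, K, V


def attention_weights(Q, K, channels: int) -> Tensor:
    """Row-stochastic softmax(Q K^T / sqrt(channels)), max-stabilized."""
    if channels <= 0:
        raise ValueError("channel count must be positive")
    Q, K = ad.as_tensor(Q), ad.as_tensor(K)
    logits = ad.mul(ad.matmul(Q, K.T), 1.0 / math.sqrt(channels))
    return ad.softmax_rows(logits)


def attention(Q, K, V, channels: int) -> Tensor:
    """Scaled dot-product attention: softmax(Q K^T / sqrt(channels)) V."""
    return ad.matmul(attention_weights(Q, K, channels), ad.as_tensor(V))


def residual_attention(X, Q, K, V, channels: int, lam, align=None) -> Tensor:
    """Attention output plus lambda times the (aligned) input.

    ``align`` is ``None`` for an identity residual (feature dims must match)
    or an affine pair ``(W, b)`` mapping input features to the scale width.
    """
    A = attention(Q, K, V, channels)
    X = ad.as_tensor(X)
    R = X if align is None else ad.add(ad.matmul(X, ad.as_tensor(align[0])),
                                       ad.as_tensor(align[1]))
    return ad.add(A, ad.mul(R, lam))


def gene_scores(S) -> np.ndarray:
    """Per-gene contribution scores: the diagonal of the gene correlation
    matrix (each diagonal entry is a gene's attention weight on itself)."""
    S = S.value if isinstance(S, Tensor) else np.asarray(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("gene correlation matrix must be square")
    return np.diag(S).copy()


def select_genes(scores: np.ndarray, phi: float) -> FiltrationResult:
    """Keep the top floor(n * phi) genes by score.

    Ties break toward the lower original index; kept indices are reported in
    original gene order, which makes the retained set monotone in phi.
    """
    if not 0 < phi <= 1:
        raise ValueError("phi must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    n_keep = int(math.floor(len(scores) * phi))
    n_keep = max(n_keep, 1)  # an empty key/value set is degenerate
    order = np.argsort(-scores, kind="stable")  # stable => lower index wins ties
    kept = np.sort(order[:n_keep])
    return FiltrationResult(scores=scores, kept_indices=kept)


def filtered_attention(X_full, kept_indices, Wq, bq, Wk, bk, Wv, bv,
                       channels: int, lam, align, slope: float = 0.01) -> Tensor:
    """Cross-attention of all gene tokens against the retained-gene subset.

    Queries come from the unfiltered tokens; keys and values are projected
    from the retained-gene submatrix.  The residual is the aligned filtered
    input scattered back to the kept rows (zero at dropped rows), so dropped
    genes contribute nothing to the residual path.
    """
    X_full = ad.as_tensor(X_full)
    n = X_full.shape[0]
    kept = np.asarray(kept_indices, dtype=np.intp)
    if kept.size and (kept.min() < 0 or kept.max() >= n):
        raise IndexError("kept_indices out of range")
    Q = ad.leaky_relu(ad.add(ad.matmul(X_full, ad.as_tensor(Wq)), ad.as_tensor(bq)), slope)
    Xf = ad.gather_rows(X_full, kept)
    Kf = ad.leaky_relu(ad.add(ad.matmul(Xf, ad.as_tensor(Wk)), ad.as_tensor(bk)), slope)
    Vf = ad.leaky_relu(ad.add(ad.matmul(Xf, ad.as_tensor(Wv)), ad.as_tensor(bv)), slope)
    A = ad.matmul(attention_weights(Q, Kf, channels), Vf)
    Rf = ad.add(ad.matmul(Xf, ad.as_tensor(align[0])), ad.as_tensor(align[1]))
    R = ad.scatter_rows(Rf, kept, n)
    return ad.add(A, ad.mul(R, lam))


def aggregate_scales(blocks) -> Tensor:
    """Feature-axis concatenation of per-scale outputs, in scale order."""
    blocks = [ad.as_tensor(b) for b in blocks]
    n = blocks[0].shape[0]
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("all scale outputs must share the token count")
    if len(blocks) == 1:
        return blocks[0]
    return ad.concat_cols(blocks)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _init_affine(rng, fan_in: int, fan_out: int, dtype):
    """Uniform fan-in scaled initialization for an affine map."""
    bound = 1.0 / math.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
    b = rng.uniform(-bound, bound, size=(fan_out,)).astype(dtype)
    return W, b


class GeneTokenModel:
    """The reconstruction network: gene tokens in, spot expression out.

    ``n_cells`` fixes the token feature width; ``n_spots`` fixes the decoder
    output width (spatial geometry is architectural, so cross-validation
    folds over genes share one trained output geometry).
    """

    def __init__(self, n_cells: int, n_spots: int, config: ModelConfig,
                 ensemble: int | None = None):
        """``ensemble=B`` builds B independent replicas whose parameters
        carry a leading batch axis; every replica starts from the same
        seeded initialization.  Used to train all cross-validation folds
        simultaneously as one batched computation."""
        self.n_cells = int(n_cells)
        self.n_spots = int(n_spots)
        self.config = config
        self.ensemble = ensemble
        self.last_filtration: list[FiltrationResult] = []
        self.last_states: list[AttentionState] = []
        dtype = np.float32 if config.dtype == "float32" else np.float64
        self._np_dtype = dtype
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}

        def param(name, W, b=None):
            if ensemble is not None:
                W = np.broadcast_to(W, (ensemble,) + W.shape).copy()
                if b is not None:
                    b = np.broadcast_to(b.reshape(1, -1),
                                        (ensemble, 1, b.size)).copy()
            self.params[name] = Tensor(W, requires_grad=True)
            if b is not None:
                self.params[name.replace("W", "b")] = Tensor(b, requires_grad=True)

        for i, lam_width in enumerate(config.active_scales):
            for proj in ("q", "k", "v", "kf", "vf"):
                W, b = _init_affine(rng, self.n_cells, lam_width, dtype)
                param(f"s{i}_W{proj}", W, b)
            Wa, ba = _init_affine(rng, self.n_cells, lam_width, dtype)
            param(f"s{i}_Walign", Wa, ba)
        width = sum(config.active_scales)
        W1, b1 = _init_affine(rng, width, config.decoder_hidden, dtype)
        W2, b2 = _init_affine(rng, config.decoder_hidden, self.n_spots, dtype)
        param("dec_W1", W1, b1)
        param("dec_W2", W2, b2)
        if config.learnable_lambda:
            lam = np.asarray(config.residual_lambda, dtype=dtype)
            if ensemble is not None:
                lam = np.broadcast_to(lam, (ensemble, 1, 1)).copy()
            self.params["lam"] = Tensor(lam, requires_grad=True)

    # -- forward ------------------------------------------------------------
    @property
    def _lam(self):
        if self.config.learnable_lambda:
            return self.params["lam"]
        return self.config.residual_lambda

    def forward_tokens(self, X: Tensor, record_states: bool = False) -> Tensor:
        """Forward from gene tokens X (n_genes x n_cells) to (n_spots x n_genes).

        All projections that share the input are evaluated as one fused GEMM
        (their weight matrices are column-concatenated in the graph), which
        is algebraically identical to applying them separately.
        """
        cfg = self.config
        scales = cfg.active_scales
        slope = cfg.leaky_slope
        n_tokens = X.shape[-2]
        self.last_filtration = []
        self.last_states = []

        # one fused GEMM for every projection that takes the full token set:
        # the LeakyReLU-activated [Q K V] blocks of all scales, followed by
        # the affine (unactivated) alignment maps.  The filtration-path K/V
        # are projected later, after the token gather (fewer rows).
        w_names = [f"s{i}_W{p}" for i in range(len(scales))
                   for p in ("q", "k", "v")]
        w_names += [f"s{i}_Walign" for i in range(len(scales))]
        b_names = [n.replace("W", "b") for n in w_names]
        Wcat = ad.concat_cols([self.params[n] for n in w_names])
        bias_cat = ad.concat_cols([_row(self.params[n]) for n in b_names])
        PR = ad.add(ad.matmul(X, Wcat), bias_cat)
        qkv_width = 3 * sum(scales)
        P = ad.leaky_relu(ad.col_slice(PR, 0, qkv_width), slope)
        R_all = ad.col_slice(PR, qkv_width, qkv_width + sum(scales))

        blocks = []
        off_p = 0
        off_r = 0
        lam = self._lam
        for i, width in enumerate(scales):
            Q = ad.col_slice(P, off_p, off_p + width)
            K = ad.col_slice(P, off_p + width, off_p + 2 * width)
            V = ad.col_slice(P, off_p + 2 * width, off_p + 3 * width)
            R = ad.col_slice(R_all, off_r, off_r + width)
            off_p += 3 * width
            off_r += width

            inv = 1.0 / math.sqrt(width)
            if cfg.use_filtration:
                # gene correlation matrix on the full token set (selection is
                # discrete, so it is computed outside the gradient graph)
                logits = Q.value @ np.swapaxes(K.value, -1, -2) * inv
                logits -= logits.max(axis=-1, keepdims=True)
                e = np.exp(logits)
                S = e / e.sum(axis=-1, keepdims=True)
                diag = np.diagonal(S, axis1=-2, axis2=-1)
                if diag.ndim == 1:
                    filt = select_genes(diag, cfg.filtration_phi)
                else:  # ensemble: stable top-k per replica
                    k = max(1, int(math.floor(n_tokens * cfg.filtration_phi)))
                    order = np.argsort(-diag, axis=-1, kind="stable")[..., :k]
                    filt = FiltrationResult(scores=diag,
                                            kept_indices=np.sort(order, axis=-1))
                kept = filt.kept_indices
                self.last_filtration.append(filt)
                # the filtration path has its own key/value weights,
                # applied to the retained tokens only
                Xf = ad.gather_rows(X, kept)
                Kf = ad.leaky_relu(ad.add(ad.matmul(Xf, self.params[f"s{i}_Wkf"]),
                                          _row(self.params[f"s{i}_bkf"])), slope)
                Vf = ad.leaky_relu(ad.add(ad.matmul(Xf, self.params[f"s{i}_Wvf"]),
                                          _row(self.params[f"s{i}_bvf"])), slope)
                W = ad.softmax_rows(ad.mul(ad.matmul(Q, Kf.T), inv))
                A = ad.matmul(W, Vf)
                Rs = ad.scatter_rows(ad.gather_rows(R, kept), kept, n_tokens)
                out = ad.add(A, ad.mul(Rs, lam))
            else:
                W = ad.softmax_rows(ad.mul(ad.matmul(Q, K.T), inv))
                S = W.value
                A = ad.matmul(W, V)
                out = ad.add(A, ad.mul(R, lam))
            if record_states:
                self.last_states.append(AttentionState(
                    Q=Q.value, K=K.value, V=V.value, S=S, A=A.value))
            blocks.append(out)

        agg = aggregate_scales(blocks)
        H = ad.leaky_relu(ad.add(ad.matmul(agg, self.params["dec_W1"]),
                                 _row(self.params["dec_b1"])), slope)
        Y = ad.add(ad.matmul(H, self.params["dec_W2"]), _row(self.params["dec_b2"]))
        return Y.T  # (n_spots, n_genes)

    def predict(self, sc_values: np.ndarray) -> np.ndarray:
        """Predict spot expression for the genes given as columns of
        ``sc_values`` (n_cells x n_genes); works for unseen genes because all
        parameters are shared across tokens."""
        sc_values = np.asarray(sc_values)
        if sc_values.shape[0] != self.n_cells:
            raise ValueError(
                f"expected {self.n_cells} cells, got {sc_values.shape[0]}")
        X = Tensor(np.ascontiguousarray(sc_values.T, dtype=self._np_dtype))
        return self.forward_tokens(X).value

    def contribution_scores(self, sc_values: np.ndarray) -> np.ndarray:
        """Mean diagonal gene-contribution score across scales."""
        sc_values = np.asarray(sc_values)
        X = Tensor(np.ascontiguousarray(sc_values.T, dtype=self._np_dtype))
        self.forward_tokens(X, record_states=True)
        diags = [np.diag(st.S) for st in self.last_states]
        return np.mean(diags, axis=0)

    # -- parameter plumbing --------------------------------------------------
    def parameter_list(self) -> list[Tensor]:
        return list(self.params.values())

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.value = np.asarray(state[k], dtype=self._np_dtype).reshape(t.value.shape)

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint with an embedded JSON config header."""
        header = json.dumps({"config": asdict(self.config),
                             "n_cells": self.n_cells, "n_spots": self.n_spots})
        arrays = {k: v.value for k, v in self.params.items()}
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GeneTokenModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"].tobytes()).decode())
            cfg_d = header["config"]
            cfg_d["scales"] = tuple(cfg_d["scales"])
            model = cls(header["n_cells"], header["n_spots"], ModelConfig(**cfg_d))
            model.set_state({k: data[k] for k in data.files if k != "__header__"})
        return model


def _row(t: Tensor) -> Tensor:
    """View a 1-D bias parameter as a (1, n) row for broadcasting in-graph;
    ensemble biases already carry a (B, 1, n) shape and pass through."""
    if t.value.ndim != 1:
        return t
    out = ad.Tensor(t.value.reshape(1, -1))
    if t.requires_grad:
        out.requires_grad = True
        out._parents = (t,)
        out._vjp = lambda g: (g.reshape(t.value.shape),)
    return out
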