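"""Low-level performance helpers for the full-batch training loop.

Training churns through large short-lived numpy arrays every epoch.  Two
measures keep that cheap on a single CPU:

* ``tune_malloc`` raises glibc's mmap threshold so big transient buffers are
  served from the heap and reused instead of being mmap'd and page-faulted
  on every epoch (no-op on non-glibc platforms).
* ``adam_ema_step`` is a fused single-pass Adam + EMA update, JIT-compiled
  with numba when available, with an equivalent numpy fallback.
"""

from __future__ import annotations

import ctypes

import numpy as np

_tuned = False


def tune_malloc() -> None:
    """Raise glibc malloc's mmap/trim thresholds (best effort, idempotent)."""
    global _tuned
    if _tuned:
        return
    _tuned = True
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


def _adam_ema_numpy(flat, m, v, g, shadow, b1, b2, bc1, bc2, lr, eps, decay):
    m *= b1
    m += (1 - b1) * g
    np.multiply(g, g, out=g)
    v *= b2
    v += (1 - b2) * g
    np.divide(v, bc2, out=g)
    np.sqrt(g, out=g)
    g += eps
    np.divide(m, g, out=g)
    g *= lr / bc1
    flat -= g
    shadow *= decay
    shadow += (1 - decay) * flat


try:
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_ema_numba(flat, m, v, g, shadow, b1, b2, bc1, bc2, lr, eps, decay):
        one = flat.dtype.type(1.0)
        b1t = flat.dtype.type(b1)
        b2t = flat.dtype.type(b2)
        inv_bc1 = flat.dtype.type(1.0 / bc1)
        inv_bc2 = flat.dtype.type(1.0 / bc2)
        lrt = flat.dtype.type(lr)
        epst = flat.dtype.type(eps)
        dt = flat.dtype.type(decay)
        for i in range(flat.size):
            gi = g[i]
            mi = b1t * m[i] + (one - b1t) * gi
            vi = b2t * v[i] + (one - b2t) * gi * gi
            m[i] = mi
            v[i] = vi
            fi = flat[i] - lrt * (mi * inv_bc1) / (np.sqrt(vi * inv_bc2) + epst)
            flat[i] = fi
            shadow[i] = dt * shadow[i] + (one - dt) * fi

    adam_ema_step = _adam_ema_numba
except Exception:  # pragma: no cover - numba is an optional accelerator
    adam_ema_step = _adam_ema_numpy
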