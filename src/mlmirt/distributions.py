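"""Reproducible truncated-normal sampling.

Draws are inverse-CDF based so that a fixed generator state yields identical
streams across platforms.  One-sided truncations further than ~6 standard
deviations into the tail switch to an exponential-proposal rejection sampler
(Robert, 1995), because the inverse CDF loses accuracy once the truncation
probability underflows.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

_TAIL = 6.0
_EPS = 1e-15


def _std_lower_truncated(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """X ~ N(0, 1) conditional on X > alpha (vectorized over alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty_like(alpha)
    easy = alpha < _TAIL
    if easy.any():
        a = alpha[easy]
        p = ndtr(a)
        q = p + rng.random(a.shape) * (1.0 - p)
        np.clip(q, _EPS, 1.0 - _EPS, out=q)
        out[easy] = np.maximum(ndtri(q), a)
    hard = ~easy
    if hard.any():
        a = alpha[hard]
        lam = 0.5 * (a + np.sqrt(a * a + 4.0))
        draws = np.empty_like(a)
        todo = np.ones(a.shape, dtype=bool)
        while todo.any():
            m = int(todo.sum())
            cand = a[todo] + rng.exponential(size=m) / lam[todo]
            accept = rng.random(m) <= np.exp(-0.5 * (cand - lam[todo]) ** 2)
            idx = np.flatnonzero(todo)[accept]
            draws[idx] = cand[accept]
            todo[idx] = False
        out[hard] = draws
    return out


def truncated_normal(
    rng: np.random.Generator,
    mean,
    sd,
    *,
    lower=-np.inf,
    upper=np.inf,
    size=None,
) -> np.ndarray:
    """Sample N(mean, sd^2) truncated to (lower, upper), elementwise.

    ``mean``, ``sd``, ``lower``, ``upper`` broadcast against each other and
    against ``size``.  Supports one-sided and two-sided truncation.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lo = np.broadcast_to(np.asarray(lower, dtype=float), np.broadcast_shapes(
        mean.shape, sd.shape, np.shape(lower), np.shape(upper),
        () if size is None else tuple(np.atleast_1d(size)),
    )).copy()
    shape = lo.shape
    mean = np.broadcast_to(mean, shape)
    sd = np.broadcast_to(sd, shape)
    hi = np.broadcast_to(np.asarray(upper, dtype=float), shape)

    a = (lo - mean) / sd
    b = (hi - mean) / sd
    out = np.empty(shape, dtype=float)

    lower_only = np.isposinf(b)
    upper_only = np.isneginf(a) & ~lower_only
    two_sided = ~lower_only & ~upper_only

    if lower_only.any():
        out[lower_only] = _std_lower_truncated(rng, a[lower_only])
    if upper_only.any():
        # mirror: X | X < b  ==  -(Y | Y > -b)
        out[upper_only] = -_std_lower_truncated(rng, -b[upper_only])
    if two_sided.any():
        pa = ndtr(a[two_sided])
        pb = ndtr(b[two_sided])
        q = pa + rng.random(pa.shape) * (pb - pa)
        np.clip(q, _EPS, 1.0 - _EPS, out=q)
        out[two_sided] = np.clip(ndtri(q), a[two_sided], b[two_sided])
    return mean + sd * out
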