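"""Count-statistics primitives: exact one-tail Poisson probabilities and
Benjamini-Hochberg FDR adjustment.

The one-tail Poisson test treats one condition's (pooled, spike-normalized)
count as a fixed rate ``lam`` and asks how extreme the other condition's
observed count ``k`` is under Poisson(lam).  Tails are computed exactly via
the regularized incomplete gamma function (scipy's Poisson cdf/sf), not by
normal approximation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["poisson_tail_p", "bh_adjust", "round_half_even"]


def round_half_even(x):
    """Banker's rounding to the nearest integer (numpy's default rounding)."""
    return np.rint(np.asarray(x, dtype=float)).astype(np.int64)


def poisson_tail_p(k, lam, tail: str):
    """Exact one-tail Poisson probability.

    Parameters
    ----------
    k
        Observed count(s), nonnegative integer(s).
    lam
        Poisson rate(s); must be > 0.
    tail
        ``"upper"`` for P(X >= k), ``"lower"`` for P(X <= k).

    Returns
    -------
    float or ndarray matching the broadcast shape of ``k`` and ``lam``.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ParameterError("poisson_tail_p requires lam > 0")
    if np.any(k_arr < 0) or np.any(k_arr != np.floor(k_arr)):
        raise ParameterError("poisson_tail_p requires nonnegative integer k")
    if tail == "upper":
        # P(X >= k) = sf(k - 1)
        out = sps.poisson.sf(k_arr - 1, lam_arr)
    elif tail == "lower":
        out = sps.poisson.cdf(k_arr, lam_arr)
    else:
        raise ParameterError(f"tail must be 'upper' or 'lower', got {tail!r}")
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1, returned in the
    original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ParameterError("bh_adjust expects a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
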