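"""Numba-compiled log-likelihood kernels for the Metropolis-within-Gibbs sampler.

All kernels work with the negative-binomial data log-likelihood under the
mean parameterization p = r/(r + lambda), lambda = exp(eta + lo) where
eta = alpha_j + x'beta and lo = ln(gamma). Terms constant across the proposals
a kernel serves are dropped:

  pll_*   : sum_n [ y*eta - (y + r) * ln(r + exp(eta + lo)) ]
            (valid for moves in beta and alpha at fixed r; the y*lo and
            gamma-function terms cancel in Metropolis ratios)
  ll_r    : sum_n [ lgamma(y+r) - lgamma(r) + r*ln r - (y+r)*ln(r+lambda) ]
            (the extra terms that move when r moves)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _log_r_plus_exp(v: float, r: float) -> float:
    # log(r + exp(v)) without overflow for large v
    if v > 33.0:
        return v + math.log1p(r * math.exp(-v))
    return math.log(r + math.exp(v))


@njit(cache=True)
def pll(eta, lo, y, r):
    s = 0.0
    for n in range(eta.shape[0]):
        s += y[n] * eta[n] - (y[n] + r) * _log_r_plus_exp(eta[n] + lo[n], r)
    return s


@njit(cache=True)
def pll_shift_col(eta, x, d, lo, y, r):
    """pll evaluated at eta + d*x (proposal for one regression coefficient)."""
    s = 0.0
    for n in range(eta.shape[0]):
        e = eta[n] + d * x[n]
        s += y[n] * e - (y[n] + r) * _log_r_plus_exp(e + lo[n], r)
    return s


@njit(cache=True)
def pll_by_focal(eta, lo, y, r, fidx, out):
    out[:] = 0.0
    for n in range(eta.shape[0]):
        out[fidx[n]] += y[n] * eta[n] - (y[n] + r) * _log_r_plus_exp(eta[n] + lo[n], r)


@njit(cache=True)
def pll_by_focal_shift(eta, dal, fidx, lo, y, r, out):
    """Per-focal pll at eta + dal[fidx] (simultaneous random-intercept proposals)."""
    out[:] = 0.0
    for n in range(eta.shape[0]):
        e = eta[n] + dal[fidx[n]]
        out[fidx[n]] += y[n] * e - (y[n] + r) * _log_r_plus_exp(e + lo[n], r)


@njit(cache=True)
def ll_r(eta, lo, y, r):
    """r-dependent part of the data log-likelihood (beta/alpha terms dropped)."""
    s = 0.0
    lgr = math.lgamma(r)
    rlr = r * math.log(r)
    for n in range(eta.shape[0]):
        s += (math.lgamma(y[n] + r) - lgr + rlr
              - (y[n] + r) * _log_r_plus_exp(eta[n] + lo[n], r))
    return s


def warm_up() -> None:
    """Trigger JIT compilation on tiny arrays (used at import of the sampler)."""
    eta = np.zeros(1)
    lo = np.zeros(1)
    y = np.zeros(1)
    fidx = np.zeros(1, dtype=np.int64)
    out = np.zeros(1)
    pll(eta, lo, y, 1.0)
    pll_shift_col(eta, eta, 0.1, lo, y, 1.0)
    pll_by_focal(eta, lo, y, 1.0, fidx, out)
    pll_by_focal_shift(eta, out, fidx, lo, y, 1.0, out.copy())
    ll_r(eta, lo, y, 1.0)
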