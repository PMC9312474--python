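"""Conway-Maxwell-Poisson (COM-Poisson) distribution.

The COM-Poisson pmf is P(Y = y) ∝ λ^y / (y!)^ν.  The extra shape ν bends
the Poisson tail: ν < 1 gives overdispersion, ν > 1 underdispersion, and
ν = 1 recovers Poisson(λ) exactly.  The normalizing constant
Z(λ, ν) = Σ_y λ^y/(y!)^ν has no closed form and is evaluated by series
summation in log space.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import NumericError

_MAX_TERMS = 10_000
_REL_TOL = 1e-12


def _log_terms(log_lam: float, nu: float) -> np.ndarray:
    """Log series terms y*log(lam) - nu*log(y!) up to adaptive truncation.

    Terms rise to a mode near λ^(1/ν) then fall super-geometrically; the
    series is truncated once a post-mode term drops below _REL_TOL relative
    to the running maximum (log-scale gap of log(1/_REL_TOL) + margin).
    """
    mode = np.exp(log_lam / max(nu, 1e-10))
    block = int(min(_MAX_TERMS, max(64, 4 * mode + 32)))
    y = np.arange(block, dtype=float)
    terms = y * log_lam - nu * gammaln(y + 1.0)
    gap = np.log(1.0 / _REL_TOL) + 10.0
    while True:
        peak = terms.max()
        if len(terms) >= 2 and terms[-1] < peak - gap and terms[-1] < terms[-2]:
            return terms
        if len(terms) >= _MAX_TERMS:
            raise NumericError(
                f"COM-Poisson series did not converge within {_MAX_TERMS} terms "
                f"(log_lam={log_lam}, nu={nu})"
            )
        extra = np.arange(len(terms), min(_MAX_TERMS, 2 * len(terms)), dtype=float)
        terms = np.concatenate([terms, extra * log_lam - nu * gammaln(extra + 1.0)])


def com_poisson_logz(lam: float, nu: float) -> float:
    """log of the normalizing constant Z(λ, ν)."""
    if lam <= 0 or nu <= 0:
        raise ValueError("lam and nu must be positive")
    return float(logsumexp(_log_terms(np.log(lam), nu)))


def com_poisson_logpmf(y, lam: float, nu: float):
    """Log-pmf log P(Y=y) = y log λ − ν log y! − log Z(λ, ν)."""
    if lam <= 0 or nu <= 0:
        raise ValueError("lam and nu must be positive")
    y_arr = np.asarray(y)
    if (y_arr < 0).any() or not np.issubdtype(y_arr.dtype, np.integer) and not np.allclose(
        y_arr, np.round(y_arr)
    ):
        raise ValueError("y must be non-negative integers")
    yf = y_arr.astype(float)
    logz = com_poisson_logz(lam, nu)
    out = yf * np.log(lam) - nu * gammaln(yf + 1.0) - logz
    return out if out.shape else float(out)


def com_poisson_moments(log_lam: float, nu: float) -> tuple[float, float, float]:
    """(log Z, E[Y], Var[Y]) from the truncated series."""
    terms = _log_terms(log_lam, nu)
    logz = logsumexp(terms)
    w = np.exp(terms - logz)
    y = np.arange(len(terms), dtype=float)
    m1 = float((w * y).sum())
    m2 = float((w * y * y).sum())
    return float(logz), m1, m2 - m1 * m1


def com_poisson_sample(lam, nu: float, rng, size=None):
    """Draw COM-Poisson variates by truncated-CDF inversion.

    ``lam`` may be a scalar or an array (one rate per draw); ``rng`` is a
    :class:`numpy.random.Generator` or an integer seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if size is None:
        size = lam_arr.shape[0]
        if lam_arr.shape[0] not in (1, size):
            raise ValueError("size incompatible with lam shape")
    if lam_arr.shape[0] == 1:
        lam_arr = np.repeat(lam_arr, size)
    if (lam_arr <= 0).any() or nu <= 0:
        raise ValueError("lam and nu must be positive")
    u = rng.random(size)
    out = np.empty(size, dtype=int)
    # group identical rates so the pmf series is computed once per rate
    order = np.argsort(lam_arr)
    sorted_lam = lam_arr[order]
    start = 0
    for stop in list(np.nonzero(np.diff(sorted_lam))[0] + 1) + [size]:
        lam_val = sorted_lam[start]
        terms = _log_terms(np.log(lam_val), nu)
        cdf = np.cumsum(np.exp(terms - logsumexp(terms)))
        idx = order[start:stop]
        out[idx] = np.searchsorted(cdf, u[idx])
        start = stop
    if np.isscalar(lam) and size == 1:
        return int(out[0])
    return out
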