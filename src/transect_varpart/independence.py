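"""Temporal-dependence and observer-effect diagnostics.

Successive passes of a transect are minutes apart, so a fish lingering in
the strip (or fleeing from the first observer) induces dependence between
passes.  Three diagnostics quantify this:

* per-species autocorrelation of the 18 ordered counts of each transect,
  with the full-series mean and denominator (biased estimator)::

      r_k = sum_{i=1}^{n-k} (Y_i - Ybar)(Y_{i+k} - Ybar) / sum_i (Y_i - Ybar)^2

* a mixed logistic regression of presence/absence on the pass order with a
  Gaussian random intercept per transect — a positive order coefficient
  means the species is seen more often late in the sequence (attraction),
  a negative one means deterrence;

* a partial Mantel correlogram relating assemblage dissimilarity to the
  temporal lag between passes, partialling out transect and observer
  membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "AcfResult",
    "OrderEffectFit",
    "MantelCorrelogram",
    "species_acf",
    "mean_acf",
    "fit_order_effect",
    "partial_mantel_correlogram",
    "holm_correction",
]


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def species_acf(series, max_lag: int) -> np.ndarray:
    """Autocorrelation r_0..r_K of one transect's ordered counts.

    Returns an array of length K+1; a constant series has zero denominator
    and yields all-NaN (flagged as undefined, not an error).
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("series must have at least 2 observations")
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    ybar = y.mean()
    dev = y - ybar
    denom = float((dev**2).sum())
    out = np.empty(max_lag + 1)
    if denom == 0.0:
        out[:] = np.nan
        return out
    for k in range(max_lag + 1):
        out[k] = float((dev[: n - k] * dev[k:]).sum()) / denom
    return out


def mean_acf(acfs) -> tuple[np.ndarray, np.ndarray]:
    """Average per-lag ACF over transects, skipping undefined values.

    Returns ``(mean, n_contributing)``; a lag with no defined value is NaN.
    """
    arr = np.asarray(list(acfs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need at least one ACF")
    n = np.sum(~np.isnan(arr), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(arr, axis=0), np.nan)
    return mean, n


@dataclass
class AcfResult:
    """Per-transect and averaged autocorrelation of one species."""

    species_id: str
    per_transect: np.ndarray  # transects x (K+1), NaN where undefined
    mean: np.ndarray
    n_contributing: np.ndarray

    @classmethod
    def from_series(cls, species_id: str, series_per_transect, max_lag: int
                    ) -> "AcfResult":
        per = np.vstack([species_acf(s, max_lag) for s in series_per_transect])
        m, n = mean_acf(per)
        return cls(species_id=species_id, per_transect=per, mean=m, n_contributing=n)


# ---------------------------------------------------------------------------
# order-effect mixed logistic model
# ---------------------------------------------------------------------------

@dataclass
class OrderEffectFit:
    """Mixed logistic fit of presence on pass order.

    ``beta`` is the log-odds change per pass; ``sigma2_transect`` the
    random-intercept variance; ``p_value`` the Wald p for beta.
    """

    species_id: str
    scope: str
    alpha: float
    beta: float
    sigma2_transect: float
    se_beta: float
    p_value: float
    n_series: int
    converged: bool
    separation: bool


_GH_NODES, _GH_WEIGHTS = hermegauss(21)  # probabilists' Hermite: weight e^{-z^2/2}


def _group_loglik(y: np.ndarray, x: np.ndarray, alpha: float, beta: float,
                  sigma: float) -> float:
    """log integral over the scalar random intercept, by Gauss-Hermite."""
    # probabilists' Gauss-Hermite with weight exp(-z^2/2): sum w_k f(z_k)
    # approximates integral f(z) exp(-z^2/2) dz; divide by sqrt(2 pi).
    eta = alpha + beta * x[:, None] + sigma * _GH_NODES[None, :]
    ll = np.where(y[:, None] == 1, -np.logaddexp(0, -eta), -np.logaddexp(0, eta))
    per_node = ll.sum(axis=0) + np.log(_GH_WEIGHTS) - 0.5 * np.log(2 * np.pi)
    m = per_node.max()
    return float(m + np.log(np.exp(per_node - m).sum()))


def fit_order_effect(series, scope: str = "all_18", species_id: str = "",
                     ) -> OrderEffectFit:
    """Fit the order-effect mixed logistic model.

    ``series`` is an iterable of (group_label, order_array, presence_array);
    series without any observed presence are dropped (they carry no signal
    about when the species was seen).  ``scope`` records whether the order
    runs over all 18 passes or the 6 passes of one observer.
    """
    kept = [(g, np.asarray(o, dtype=float), np.asarray(p, dtype=float))
            for g, o, p in series if np.asarray(p).sum() >= 1]
    if len(kept) < 2:
        raise ValueError("need at least 2 series with >= 1 presence")

    groups: dict = {}
    for g, o, p in kept:
        acc = groups.setdefault(g, ([], []))
        acc[0].append(o)
        acc[1].append(p)
    data = [(np.concatenate(o), np.concatenate(p)) for o, p in groups.values()]
    all_p = np.concatenate([p for _, p in data])
    separation = bool(all_p.min() == all_p.max())

    x_center = float(np.mean(np.concatenate([o for o, _ in data])))

    def nll(theta):
        alpha, beta, log_sigma = theta
        sigma = np.exp(log_sigma)
        return -sum(
            _group_loglik(p, o - x_center, alpha, beta, sigma) for o, p in data
        )

    theta0 = np.array([np.log((all_p.mean() + 1e-3) / (1 - all_p.mean() + 1e-3)), 0.0,
                       np.log(0.5)])
    res = minimize(nll, theta0, method="L-BFGS-B",
                   bounds=[(None, None), (None, None), (-8.0, 3.0)],
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    alpha, beta, log_sigma = res.x
    converged = bool(res.success)
    if abs(beta) > 10:
        separation = True

    # Wald SE for beta from a central-difference Hessian; when the
    # random-effect variance sits at its zero boundary the log-sigma
    # direction is flat and is dropped from the inversion
    se_beta = np.nan
    p_value = np.nan
    if converged and not separation:
        active = [0, 1] if log_sigma <= -7.9 else [0, 1, 2]
        h = 1e-4
        k = len(active)
        hess = np.zeros((k, k))
        eye = np.eye(3)
        for a in range(k):
            for b in range(a, k):
                ea, eb = eye[active[a]] * h, eye[active[b]] * h
                hess[a, b] = hess[b, a] = (
                    nll(res.x + ea + eb) - nll(res.x + ea - eb)
                    - nll(res.x - ea + eb) + nll(res.x - ea - eb)
                ) / (4 * h * h)
        try:
            cov = np.linalg.inv(hess)
            if cov[1, 1] > 0:
                se_beta = float(np.sqrt(cov[1, 1]))
                p_value = float(2 * norm.sf(abs(beta) / se_beta))
        except np.linalg.LinAlgError:
            converged = False
    if separation:
        p_value = 1.0  # boundary: no information against the null from Wald

    return OrderEffectFit(
        species_id=species_id,
        scope=scope,
        alpha=float(alpha),
        beta=float(beta),
        sigma2_transect=float(np.exp(2 * log_sigma)),
        se_beta=se_beta,
        p_value=p_value,
        n_series=len(kept),
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# partial Mantel correlogram
# ---------------------------------------------------------------------------

def holm_correction(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    idx = np.where(~np.isnan(p))[0]
    if len(idx) == 0:
        return out
    order = idx[np.argsort(p[idx])]
    m = len(order)
    running = 0.0
    for rank, i in enumerate(order):
        adj = min(1.0, (m - rank) * p[i])
        running = max(running, adj)
        out[i] = running
    return out


@dataclass
class MantelCorrelogram:
    """Partial Mantel statistic per temporal lag within transects."""

    lags: np.ndarray
    statistic: np.ndarray
    p_values: np.ndarray       # raw permutation p, (b+1)/(m+1)
    p_holm: np.ndarray
    n_pairs: np.ndarray
    n_permutations: int


def partial_mantel_correlogram(
    d: np.ndarray,
    order_index,
    transect,
    observer,
    n_perm: int = 999,
    seed: int = 0,
    max_lag: int | None = None,
) -> MantelCorrelogram:
    """Lag-wise partial correlation of dissimilarity with temporal lag.

    Only within-transect pairs enter the lag classes (between-transect
    pairs have no temporal order).  Both the dissimilarities and the
    lag-class indicators are residualized on transect- and observer-pair
    membership dummies before correlating; the statistic's sign follows
    the correlogram convention (positive at a lag = passes that many
    steps apart are more similar than average).  Significance is assessed by
    permuting the order labels within each transect; Holm correction is
    applied across lags.
    """
    import warnings

    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("d must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("d must be symmetric")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p-value")

    order_index = np.asarray(order_index)
    transect = np.asarray(transect)
    observer = np.asarray(observer)
    n = d.shape[0]
    rng = np.random.default_rng(seed)

    ii, jj = [], []
    for t in np.unique(transect):
        members = np.where(transect == t)[0]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ii.append(members[a])
                jj.append(members[b])
    ii = np.array(ii)
    jj = np.array(jj)
    y = d[ii, jj]

    # covariates: transect membership and observer-pair category dummies
    tr_codes = np.unique(transect, return_inverse=True)[1]
    obs_codes = np.unique(observer, return_inverse=True)[1]
    tcol = tr_codes[ii]
    opair = np.array([
        f"{min(a, b)}-{max(a, b)}" for a, b in zip(obs_codes[ii], obs_codes[jj])
    ])
    ocol = np.unique(opair, return_inverse=True)[1]

    def dummies(codes):
        k = codes.max() + 1
        m = np.zeros((len(codes), k))
        m[np.arange(len(codes)), codes] = 1.0
        return m[:, :-1]  # drop one level; intercept added separately

    x = np.column_stack([np.ones(len(ii)), dummies(tcol), dummies(ocol)])
    pinv_x = np.linalg.pinv(x)

    def residualize(v):
        v = np.atleast_2d(v.T).T
        return v - x @ (pinv_x @ v)

    y_res = residualize(y)[:, 0]
    y_norm = np.linalg.norm(y_res)
    if y_norm <= 1e-10 * max(1.0, float(np.abs(y).max())) * np.sqrt(len(y)):
        y_norm = 0.0  # dissimilarities carry no variance beyond the covariates

    lag_of = {i: o for i, o in zip(range(n), order_index)}
    max_possible = int(np.max([abs(lag_of[a] - lag_of[b]) for a, b in zip(ii, jj)]))
    k_max = max_possible if max_lag is None else min(max_lag, max_possible)
    lags = np.arange(1, k_max + 1)

    def lag_matrix(order_labels):
        lag = np.abs(order_labels[ii] - order_labels[jj])
        lmat = np.zeros((len(ii), len(lags)))
        for c, k in enumerate(lags):
            lmat[:, c] = lag == k
        return lmat

    def statistics(order_labels):
        lmat = lag_matrix(order_labels)
        counts = lmat.sum(axis=0)
        lres = residualize(lmat)
        out = np.full(len(lags), np.nan)
        for c in range(len(lags)):
            if counts[c] < 2:
                continue
            if y_norm == 0:
                out[c] = 0.0  # no dissimilarity variance at all
                continue
            denom = y_norm * np.linalg.norm(lres[:, c])
            if denom > 0:
                # sign flipped so a positive value at a small lag means
                # passes close in time are MORE similar (autocorrelation)
                out[c] = -float(y_res @ lres[:, c]) / denom
        return out, counts

    obs_stat, n_pairs = statistics(order_index)

    exceed = np.zeros(len(lags))
    valid = ~np.isnan(obs_stat)
    for _ in range(n_perm):
        perm_order = order_index.copy()
        for t in np.unique(transect):
            members = np.where(transect == t)[0]
            perm_order[members] = perm_order[rng.permutation(members)]
        perm_stat, _ = statistics(perm_order)
        with np.errstate(invalid="ignore"):
            exceed += np.where(valid & ~np.isnan(perm_stat),
                               np.abs(perm_stat) >= np.abs(obs_stat), 0.0)

    p = np.where(valid, (exceed + 1) / (n_perm + 1), np.nan)
    return MantelCorrelogram(
        lags=lags,
        statistic=obs_stat,
        p_values=p,
        p_holm=holm_correction(p),
        n_pairs=n_pairs.astype(int),
        n_permutations=n_perm,
    )
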