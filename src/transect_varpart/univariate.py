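"""Univariate variance partitioning: mixed models and intraclass correlations.

Species density and Shannon diversity are partitioned with a linear mixed
model (Island fixed; Location, Transect nested random; Observer crossed
random with its Location and Transect interactions).  For the balanced
design the ANOVA method-of-moments solution obtained by equating mean
squares to their Cornfield-Tukey expectations is exact, coincides with
REML whenever all component estimates are interior, and is used here.

The intraclass correlation of random factor r is::

    ICC_r = sigma_r^2 / (sum_r sigma_r^2 + sigma_eps^2)

and the *sampling variability* share — the part of the variance that
replication has to absorb (counting errors, observer effects,
instantaneous fish displacement) — is::

    ICC_Sampling = ICC_eps + ICC_Observer:Transect + ICC_Observer:Location

Counts of single species are modelled with a zero-inflated COM-Poisson
GLMM (log link), fitted by maximum likelihood with a Laplace approximation
over the Gaussian random effects; Poisson and negative-binomial families
are available for AIC comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .core import StudyDesign
from .ems import VarPartModel, standard_design_model
from .errors import NumericError

__all__ = [
    "UniVarianceComponents",
    "IccTable",
    "ComPoissonFit",
    "fit_lmm",
    "icc_table",
    "icc_sampling_from_total",
    "com_poisson_logpmf",
    "fit_zicomp_glmm",
]

# re-exported for convenience: the pmf lives with the sampler
from .compoisson import com_poisson_logpmf  # noqa: E402

RANDOM_TERMS = ("location", "transect", "observer", "location:observer",
                "transect:observer")


def design_from_labels(labels: pd.DataFrame) -> StudyDesign:
    """Reconstruct the balanced design integers from factor labels."""
    n_isl = labels["island"].nunique()
    loc_per_isl = labels.groupby("island")["location"].nunique()
    tr_per_loc = labels.groupby(["island", "location"])["transect"].nunique()
    n_obs = labels["observer"].nunique()
    reps = labels.groupby(["island", "location", "transect", "observer"]).size()
    return StudyDesign(
        n_islands=n_isl,
        locations_per_island=int(loc_per_isl.iloc[0]),
        transects_per_location=int(tr_per_loc.iloc[0]),
        n_observers=n_obs,
        repeats_per_observer=int(reps.iloc[0]),
    )


@dataclass
class UniVarianceComponents:
    """Variance components of one response under the mixed model."""

    response: str
    components: pd.Series          # raw signed method-of-moments estimates
    truncated: pd.Series           # negatives set to 0 (used for ICC)
    island_means: pd.Series
    ms_table: pd.DataFrame
    method: str = "anova-mom"
    converged: bool = True
    aic: float | None = None


@dataclass
class IccTable:
    """Intraclass-correlation decomposition."""

    icc: pd.Series       # per random factor
    icc_total: float
    icc_eps: float
    icc_sampling: float


def fit_lmm(y, labels: pd.DataFrame, model: VarPartModel | None = None,
            response: str = "response") -> UniVarianceComponents:
    """Balanced-design variance components by ANOVA method of moments.

    ``labels`` must carry one column per factor of ``model``; by default
    the study's model (Island fixed; Location, Transect, Observer,
    Observer:Location, Observer:Transect random) is reconstructed from the
    labels.  Raw signed estimates are kept; the truncated (non-negative)
    copies feed the ICC.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response must be finite")
    if model is None:
        model = standard_design_model(design_from_labels(labels),
                                      include_island_observer=False)
    projections = model.projections(labels)
    yc = y - y.mean()
    g = np.outer(yc, yc)
    ms = model.mean_squares(projections, g)
    comps = model.solve_components(ms["MS"])
    fixed_terms = [model._term_name(t) for t in model.terms if not model.is_random(t)]
    random_comps = comps.drop(index=fixed_terms)
    island_means = (
        pd.Series(y).groupby(labels["island"].to_numpy()).mean()
        if "island" in labels
        else pd.Series(dtype=float)
    )
    return UniVarianceComponents(
        response=response,
        components=random_comps,
        truncated=random_comps.clip(lower=0.0),
        island_means=island_means,
        ms_table=ms,
    )


def icc_table(components: UniVarianceComponents | pd.Series) -> IccTable:
    """Evaluate the ICC decomposition from non-negative variance components.

    Accepts either a fitted :class:`UniVarianceComponents` (its truncated
    components are used) or a Series with one entry per random factor plus
    ``Residual``.
    """
    if isinstance(components, UniVarianceComponents):
        sig = components.truncated
    else:
        sig = pd.Series(components, dtype=float)
    if (sig < 0).any():
        raise ValueError("variance components must be non-negative (truncate first)")
    total = float(sig.sum())
    if total == 0:
        raise ValueError("all variance components are zero; ICC undefined")
    resid = float(sig.get("Residual", 0.0))
    factors = sig.drop(index="Residual", errors="ignore")
    icc = factors / total
    icc_eps = resid / total
    sampling = icc_eps
    for name in ("transect:observer", "location:observer"):
        if name in icc.index:
            sampling += float(icc[name])
    return IccTable(
        icc=icc,
        icc_total=float(icc.sum()),
        icc_eps=icc_eps,
        icc_sampling=float(sampling),
    )


def icc_sampling_from_total(icc_total: float, icc_obs_transect: float,
                            icc_obs_location: float) -> float:
    """ICC_Sampling from the reported totals: (1 - ICC_Total) is the
    residual share, to which the observer-interaction shares are added."""
    return (1.0 - icc_total) + icc_obs_transect + icc_obs_location


# ---------------------------------------------------------------------------
# zero-inflated COM-Poisson GLMM (Laplace)
# ---------------------------------------------------------------------------

@dataclass
class ComPoissonFit:
    """Maximum-likelihood fit of a (possibly zero-inflated) count GLMM."""

    response: str
    family: str
    coefficients: pd.Series        # fixed effects on the log-lambda scale
    nu: float | None               # COM-Poisson shape (None for other families)
    dispersion: float | None       # NB2 alpha (None otherwise)
    pi: float                      # zero-inflation probability
    variance_components: pd.Series
    loglik: float
    aic: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def _compois_grid_stats(eta: np.ndarray, nu: float):
    """(logZ, E[Y], Var[Y]) per observation, vectorized over a shared y-grid."""
    log_mode = np.max(eta) / max(nu, 1e-6)
    if log_mode > 7.3:  # mode beyond the largest supported grid
        raise NumericError("COM-Poisson rate too large for the y-grid")
    mode = np.exp(log_mode)
    ymax = int(min(5000, max(40, 3 * mode + 12 * np.sqrt(mode + 1) + 40)))
    ygrid = np.arange(ymax + 1, dtype=float)
    terms = eta[:, None] * ygrid[None, :] - nu * gammaln(ygrid + 1.0)[None, :]
    peak = terms.max(axis=1)
    if np.any(terms[:, -1] > peak - 25):
        raise NumericError("COM-Poisson grid too short; lambda too large")
    logz = logsumexp(terms, axis=1)
    w = np.exp(terms - logz[:, None])
    m1 = w @ ygrid
    m2 = w @ (ygrid**2)
    return logz, m1, np.maximum(m2 - m1**2, 1e-10)


def _count_loglik_parts(y: np.ndarray, eta: np.ndarray, family: str, shape: float):
    """Per-observation count log-pmf pieces and eta-derivatives.

    Returns (ll, d1, d2, log_p0, dlog_p0, d2log_p0) where the p0 columns
    describe the probability of a zero count (needed for the zero-inflation
    mixture at y = 0).
    """
    mu = np.exp(eta)
    if family == "compoisson":
        logz, m1, var = _compois_grid_stats(eta, shape)
        ll = y * eta - shape * gammaln(y + 1.0) - logz
        return ll, y - m1, -var, -logz, -m1, -var
    if family == "poisson":
        ll = y * eta - mu - gammaln(y + 1.0)
        return ll, y - mu, -mu, -mu, -mu, -mu
    if family == "nb2":
        r = 1.0 / max(shape, 1e-8)
        ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
              + r * np.log(r / (r + mu)) + y * (eta - np.log(r + mu)))
        d1 = (y - mu) * r / (r + mu)
        d2 = -mu * r * (r + y) / (r + mu) ** 2
        logp0 = r * np.log(r / (r + mu))
        dlogp0 = -r * mu / (r + mu)
        d2logp0 = -r * mu * r / (r + mu) ** 2
        return ll, d1, d2, logp0, dlogp0, d2logp0
    raise ValueError(f"unknown family {family!r}")


def _mixture_loglik(y, eta, family, shape, pi):
    """Zero-inflated log-likelihood and first/second eta-derivatives."""
    ll, d1, d2, logp0, dlogp0, d2logp0 = _count_loglik_parts(y, eta, family, shape)
    out_ll = np.log1p(-pi) + ll
    out_d1, out_d2 = d1.copy(), d2.copy()
    zero = y == 0
    if np.any(zero):
        p0 = np.exp(logp0[zero])
        g = pi + (1 - pi) * p0
        q = (1 - pi) * p0
        out_ll[zero] = np.log(np.maximum(g, 1e-300))
        out_d1[zero] = q * dlogp0[zero] / g
        # d/deta of q*dlogp0/g with q' = q*dlogp0, g' = q*dlogp0
        num = q * (dlogp0[zero] ** 2 + d2logp0[zero]) * g - (q * dlogp0[zero]) ** 2
        out_d2[zero] = num / g**2
    return out_ll, out_d1, out_d2


def _random_design(labels: pd.DataFrame, terms) -> tuple[np.ndarray, np.ndarray]:
    """Sparse-ish indicator matrix Z and block index per column."""
    cols = []
    block = []
    for bi, term in enumerate(terms):
        parts = term.split(":")
        key = labels[parts].astype(str).agg("|".join, axis=1)
        codes, uniques = pd.factorize(key)
        z = np.zeros((len(labels), len(uniques)))
        z[np.arange(len(labels)), codes] = 1.0
        cols.append(z)
        block.extend([bi] * len(uniques))
    return np.hstack(cols), np.asarray(block)


def fit_zicomp_glmm(
    y,
    labels: pd.DataFrame,
    family: str = "compoisson",
    random_terms=RANDOM_TERMS,
    zero_inflated: bool = True,
    response: str = "count",
    maxiter: int = 200,
) -> ComPoissonFit:
    """Laplace-approximate ML fit of a zero-inflated count GLMM.

    Fixed effects: intercept and island; random intercepts for each entry
    of ``random_terms`` (colon-joined factor columns of ``labels``).  The
    zero-inflation probability is a single intercept on the logit scale.
    AIC is comparable across ``family`` in {'poisson', 'nb2', 'compoisson'}.
    """
    y = np.asarray(y, dtype=float)
    if y.sum() < 1:
        raise ValueError("need at least one nonzero count")
    flags: list[str] = []

    islands = pd.factorize(labels["island"])[1]
    x_cols = {"intercept": np.ones(len(y))}
    codes = pd.factorize(labels["island"])[0]
    for k in range(1, len(islands)):
        x_cols[f"island[{islands[k]}]"] = (codes == k).astype(float)
    x = np.column_stack(list(x_cols.values()))
    z, block = _random_design(labels, random_terms)
    n_blocks = len(random_terms)
    q = z.shape[1]

    has_shape = family in ("compoisson", "nb2")

    def unpack(theta):
        k = x.shape[1]
        beta = theta[:k]
        log_s2 = theta[k:k + n_blocks]
        pos = k + n_blocks
        shape = 1.0
        if has_shape:
            shape = float(np.exp(theta[pos]))
            pos += 1
        pi = float(1 / (1 + np.exp(-theta[pos]))) if zero_inflated else 0.0
        return beta, np.exp(log_s2), shape, pi

    b_warm = np.zeros(q)

    def neg_marginal(theta):
        nonlocal b_warm
        beta, s2, shape, pi = unpack(theta)
        d_inv = 1.0 / np.maximum(s2, 1e-10)[block]
        xb = x @ beta
        b = b_warm.copy()
        f_prev = -np.inf
        try:
            _mixture_loglik(y, xb + z @ b, family, shape, pi)
        except NumericError:
            b = np.zeros_like(b)  # warm start infeasible under this theta
        for _ in range(50):
            eta = xb + z @ b
            try:
                ll, d1, d2 = _mixture_loglik(y, eta, family, shape, pi)
            except NumericError:
                return 1e10
            f = ll.sum() - 0.5 * np.sum(d_inv * b * b)
            grad = z.T @ d1 - d_inv * b
            w = np.maximum(-d2, 1e-8)
            h = (z.T * w) @ z
            h[np.diag_indices_from(h)] += d_inv
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                h[np.diag_indices_from(h)] += 1e-6
                step = np.linalg.solve(h, grad)
            if np.abs(f - f_prev) < 1e-10 and np.linalg.norm(grad) < 1e-7:
                break
            # halving line search on the penalized joint log-likelihood
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                eta_new = xb + z @ b_new
                try:
                    ll_new, _, _ = _mixture_loglik(y, eta_new, family, shape, pi)
                    f_new = ll_new.sum() - 0.5 * np.sum(d_inv * b_new * b_new)
                except NumericError:
                    f_new = -np.inf
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            b = b + t * step
            f_prev = f
        b_warm = b
        eta = xb + z @ b
        try:
            ll, d1, d2 = _mixture_loglik(y, eta, family, shape, pi)
        except NumericError:
            return 1e10
        w = np.maximum(-d2, 1e-8)
        h = (z.T * w) @ z
        h[np.diag_indices_from(h)] += d_inv
        sign, logdet_h = np.linalg.slogdet(h)
        if sign <= 0:
            return 1e10
        joint = ll.sum() - 0.5 * np.sum(d_inv * b * b) + 0.5 * np.sum(np.log(d_inv))
        return -(joint - 0.5 * logdet_h)

    k = x.shape[1]
    theta0 = np.concatenate([
        [np.log(max(y.mean(), 0.05))], np.zeros(k - 1),
        np.full(n_blocks, np.log(0.1)),
        [0.0] if has_shape else [],
        [-2.0] if zero_inflated else [],
    ])
    if family != "poisson":
        # warm start at the Poisson solution (shape at its Poisson value)
        pois = fit_zicomp_glmm(y, labels, family="poisson",
                               random_terms=random_terms,
                               zero_inflated=zero_inflated, response=response,
                               maxiter=maxiter)
        theta0[:k] = pois.coefficients.to_numpy()
        theta0[k:k + n_blocks] = np.log(
            np.maximum(pois.variance_components.to_numpy(), 1e-5))
        if zero_inflated:
            p0 = np.clip(pois.pi, 1e-3, 1 - 1e-3)
            theta0[-1] = np.log(p0 / (1 - p0))
    bounds = ([(None, None)] * k + [(-12, 4)] * n_blocks
              + ([(-3, 3)] if has_shape else [])
              + ([(-8, 8)] if zero_inflated else []))
    res = minimize(neg_marginal, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7,
                            "eps": 1e-5})
    beta, s2, shape, pi = unpack(res.x)
    if not res.success:
        flags.append("non-convergence")
    if has_shape and (res.x[k + n_blocks] <= -2.95 or res.x[k + n_blocks] >= 2.95):
        flags.append("shape-boundary")
    if np.any(res.x[k:k + n_blocks] <= -11.5):
        flags.append("variance-boundary")

    loglik = -float(res.fun)
    n_par = len(res.x)
    return ComPoissonFit(
        response=response,
        family=family,
        coefficients=pd.Series(beta, index=list(x_cols.keys())),
        nu=shape if family == "compoisson" else None,
        dispersion=shape if family == "nb2" else None,
        pi=pi,
        variance_components=pd.Series(s2, index=list(random_terms)),
        loglik=loglik,
        aic=2 * n_par - 2 * loglik,
        converged=res.success and "shape-boundary" not in flags,
        flags=flags,
    )
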