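"""Multivariate variance partitioning of assemblage structure.

PERMANOVA partitions the total sum of squared dissimilarities among the
terms of the balanced mixed design (Island fixed; Location, Transect
nested random; Observer crossed random).  Equating the resulting mean
squares to their Cornfield-Tukey expectations yields multivariate
components of variation; their signed square roots sigma' are reported as
in the PERMANOVA tradition (a negative component estimate keeps its sign
rather than being hidden).  Pseudo-F denominators are derived from the
expected-mean-square table (quasi-F combinations where no single mean
square matches), and p-values come from permutation of residuals under
the reduced model (Freedman-Lane), permuting observations within the
strata defined by the tested term's nesting parents.

CAP (canonical analysis of principal coordinates) assesses how well the
assemblages discriminate groups: a canonical discriminant analysis on the
first m PCO axes, scored by leave-one-out classification error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_rel
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import CommunityMatrix, DISTANCE_WINDOWS, build_community_matrix
from .ems import VarPartModel, standard_design_model
from .errors import DesignError
from .univariate import design_from_labels

__all__ = [
    "DissimilarityMatrix",
    "PermanovaTable",
    "CapResult",
    "SweepResult",
    "dissimilarity",
    "ems_table",
    "permanova",
    "sweep_configurations",
    "pco",
    "cap_loocv",
    "window_for_length",
]

DISSIMILARITY_METHODS = ("bray_curtis", "euclidean", "gower", "kulczynski")


def window_for_length(length_m: float) -> tuple[float, float]:
    """Central distance window realizing an effective transect length."""
    for lo, hi in DISTANCE_WINDOWS:
        if abs((hi - lo) - length_m) < 1e-9:
            return (lo, hi)
    raise ValueError(f"no standard window of length {length_m}")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with provenance."""

    values: np.ndarray
    method: str
    transform: str = "none"
    metric: str = "MaxCount"
    window_m: tuple[float, float] | None = None
    row_meta: pd.DataFrame | None = None
    undefined_pairs: np.ndarray | None = None  # both-zero pairs, flagged

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("dissimilarities must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dissimilarity(matrix: CommunityMatrix, method: str) -> DissimilarityMatrix:
    """Pairwise dissimilarities of the (transformed) community matrix.

    Methods: ``bray_curtis`` sum|x-y| / sum(x+y); ``euclidean``;
    ``gower`` mean over species of |x-y| / range (zero-range species
    contribute 0); quantitative ``kulczynski``
    1 - (sum min / sum x + sum min / sum y) / 2.  Pairs of all-zero rows
    are undefined for the [0, 1] indices: they are flagged and set to 0.
    """
    x = matrix.values
    n, p = x.shape
    undefined = None
    if method == "euclidean":
        d = squareform(pdist(x, "euclidean"))
    elif method == "gower":
        rng = x.max(axis=0) - x.min(axis=0)
        keep = rng > 0
        scaled = x[:, keep] / rng[keep]
        d = squareform(pdist(scaled, "cityblock")) / p
    elif method in ("bray_curtis", "kulczynski"):
        ct = squareform(pdist(x, "cityblock"))
        s = x.sum(axis=1)
        ssum = s[:, None] + s[None, :]
        both_zero = (s[:, None] == 0) & (s[None, :] == 0)
        undefined = both_zero & ~np.eye(n, dtype=bool)
        if method == "bray_curtis":
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(ssum > 0, ct / np.where(ssum > 0, ssum, 1.0), 0.0)
        else:
            smin = (ssum - ct) / 2.0
            with np.errstate(invalid="ignore", divide="ignore"):
                t1 = np.where(s[:, None] > 0, smin / np.where(s[:, None] > 0, s[:, None], 1), 0.0)
                t2 = np.where(s[None, :] > 0, smin / np.where(s[None, :] > 0, s[None, :], 1), 0.0)
            d = 1.0 - 0.5 * (t1 + t2)
            d[both_zero] = 0.0
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(
            f"unknown method {method!r}; choose from {DISSIMILARITY_METHODS}"
        )
    return DissimilarityMatrix(
        values=d,
        method=method,
        transform=matrix.transform,
        metric=matrix.metric,
        window_m=matrix.window_m,
        row_meta=matrix.row_meta,
        undefined_pairs=undefined,
    )


def ems_table(model: VarPartModel) -> pd.DataFrame:
    """Expected-mean-square coefficient table of a balanced mixed model."""
    return model.ems_matrix()


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTable:
    """PERMANOVA partition with components of variation."""

    table: pd.DataFrame            # df, SS, MS, pseudo_F, p_perm per term
    components: pd.Series          # signed sigma'^2 per component
    sigma_prime: pd.Series         # signed square roots
    percent: pd.Series             # % of total variation (negatives truncated)
    r2: pd.Series                  # SS_term / SS_total per model term
    r2_total: float
    n_permutations: int
    method: str = ""
    not_testable: list[str] = field(default_factory=list)

    @property
    def percent_sampling(self) -> float:
        """Sampling-variability share: residual + observer-interaction %."""
        out = float(self.percent.get("Residual", 0.0))
        for name in ("location:observer", "transect:observer"):
            out += float(self.percent.get(name, 0.0))
        return out


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def sampling_to_spatial_ratio(percent: pd.Series) -> float:
    """Ratio of the sampling-variability share to the spatial share
    (Location + Transect) of the percentage components."""
    sampling = float(percent.get("Residual", 0.0)
                     + percent.get("location:observer", 0.0)
                     + percent.get("transect:observer", 0.0))
    spatial = float(percent.get("location", 0.0) + percent.get("transect", 0.0))
    if spatial == 0:
        raise ValueError("spatial share is zero")
    return sampling / spatial


def permanova(
    d: DissimilarityMatrix | np.ndarray,
    labels: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    model: VarPartModel | None = None,
    truncate_negative: bool = True,
    exhaustive: bool = False,
) -> PermanovaTable:
    """Balanced mixed-model PERMANOVA with components of variation.

    ``labels`` needs one column per design factor.  ``truncate_negative``
    controls whether negative component estimates are zeroed before the
    percentage normalization (the signed values are always reported).
    With ``exhaustive=True`` (tiny problems only) the permutation p is an
    exact enumeration over all within-strata relabelings.
    """
    values = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, float)
    method = d.method if isinstance(d, DissimilarityMatrix) else ""
    n = values.shape[0]
    if len(labels) != n:
        raise ValueError("labels must have one row per observation")
    if model is None:
        model = standard_design_model(design_from_labels(labels))
    rng = np.random.default_rng(seed)

    projections = model.projections(labels)
    g = _gower_center(values)
    ms = model.mean_squares(projections, g)
    ss_total = float(ms["SS"].sum())

    f_obs = model.pseudo_f(ms)
    comps = model.solve_components(ms["MS"])
    sigma_prime = np.sign(comps) * np.sqrt(np.abs(comps))
    pos = comps.clip(lower=0.0) if truncate_negative else comps
    percent = 100.0 * pos / pos.sum() if pos.sum() > 0 else pos * 0.0

    # permutation p-values per term: Freedman-Lane residuals of the reduced
    # model, observations permuted within the term's nesting-parent strata
    pvals = {}
    not_testable = []
    h0 = np.full((n, n), 1.0 / n)
    denom_weights = {t: model.denominator(t) for t in model.term_names}
    for term, tname in zip(model.terms, model.term_names):
        if n_perm < 1 and not exhaustive:
            pvals[tname] = np.nan
            continue
        reduced = h0.copy()
        for other in model.term_names:
            if other != tname:
                reduced = reduced + projections[other]
        r = np.eye(n) - reduced
        g_res = r @ g @ r

        brackets = sorted(model.subscripts(term) - set(term))
        if brackets:
            strata = pd.factorize(
                labels[brackets].astype(str).agg("|".join, axis=1))[0]
        else:
            strata = np.zeros(n, dtype=int)
        strata_members = [np.where(strata == s)[0] for s in np.unique(strata)]
        if all(len(m) < 2 for m in strata_members):
            pvals[tname] = np.nan
            not_testable.append(tname)
            continue

        w = denom_weights[tname]

        def f_stat(gm) -> float:
            ss_t = float(np.sum(projections[tname] * gm))
            ms_t = ss_t / model.df(term)
            denom = 0.0
            for other, wt in w.items():
                if wt == 0:
                    continue
                h = projections[other]
                dfo = model.residual_df if other == "Residual" else model.df(
                    tuple(other.split(":")))
                denom += wt * float(np.sum(h * gm)) / dfo
            return ms_t / denom if denom > 0 else np.inf

        stat0 = float(f_obs[tname])

        if exhaustive:
            perms = [list(p) for p in _strata_permutations(strata_members, n)]
            count = 0
            for perm in perms:
                gp = g_res[np.ix_(perm, perm)]
                if f_stat(gp) >= stat0 - 1e-12:
                    count += 1
            pvals[tname] = count / len(perms)
        else:
            exceed = 0
            perm = np.arange(n)
            for _ in range(n_perm):
                for members in strata_members:
                    perm[members] = members[rng.permutation(len(members))]
                gp = g_res[np.ix_(perm, perm)]
                if f_stat(gp) >= stat0 - 1e-12:
                    exceed += 1
            pvals[tname] = (exceed + 1) / (n_perm + 1)

    table = ms.copy()
    table["pseudo_F"] = pd.Series(f_obs)
    table["p_perm"] = pd.Series(pvals)
    if ss_total > 0:
        r2 = ms["SS"] / ss_total
        r2_total = float(1.0 - ms.loc["Residual", "SS"] / ss_total)
    else:  # all observations identical
        r2 = ms["SS"] * 0.0
        r2_total = 0.0

    return PermanovaTable(
        table=table,
        components=comps,
        sigma_prime=sigma_prime,
        percent=percent,
        r2=r2.drop(index="Residual"),
        r2_total=r2_total,
        n_permutations=n_perm,
        method=method,
        not_testable=not_testable,
    )


def _strata_permutations(strata_members, n):
    """All relabelings permuting observations within each stratum."""
    pools = [list(itertools.permutations(m)) for m in strata_members]
    for combo in itertools.product(*pools):
        perm = np.arange(n)
        for members, arrangement in zip(strata_members, combo):
            perm[np.asarray(members)] = np.asarray(arrangement)
        yield perm


# ---------------------------------------------------------------------------
# configuration sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """R-squared comparison over the methodological configuration grid."""

    configs: pd.DataFrame          # one row per model: parameters + R2
    pairwise_tests: pd.DataFrame   # paired t-tests per parameter, Bonferroni

    @property
    def n_models(self) -> int:
        return len(self.configs)


def sweep_configurations(
    records,
    lengths=(10.0, 20.0, 30.0, 40.0, 50.0),
    metrics=("MaxCount", "MinCount"),
    transforms=("fourth_root", "log1p", "presence_absence"),
    methods=DISSIMILARITY_METHODS,
    n_perm: int = 0,
    seed: int = 0,
) -> SweepResult:
    """Fit a PERMANOVA for every (length, metric, transform, method) combo.

    The default grid is 5 x 2 x 3 x 4 = 120 models.  Goodness-of-fit is
    compared through the total R^2; levels of each parameter are compared
    with pairwise paired t-tests over the configurations they share, with
    Bonferroni correction.  ``n_perm=0`` skips permutation p-values (R^2
    does not need them).
    """
    records = list(records)
    species = sorted({ev.species_id for r in records for ev in r.events})
    model = None
    rows = []
    for li, length in enumerate(lengths):
        window = window_for_length(length)
        for metric in metrics:
            base = build_community_matrix(records, metric=metric, window=window,
                                          species=species)
            for transform in transforms:
                from .core import transform_counts
                cm = transform_counts(base, transform)
                for method in methods:
                    dm = dissimilarity(cm, method)
                    if model is None:
                        model = standard_design_model(design_from_labels(dm.row_meta))
                    res = permanova(dm, dm.row_meta, n_perm=n_perm, seed=seed,
                                    model=model)
                    rows.append(
                        dict(length=length, metric=metric, transform=transform,
                             method=method, r2_total=res.r2_total)
                    )
    configs = pd.DataFrame(rows)

    tests = []
    for param in ("length", "metric", "transform", "method"):
        levels = sorted(configs[param].unique(), key=str)
        others = [c for c in ("length", "metric", "transform", "method") if c != param]
        n_comparisons = len(levels) * (len(levels) - 1) // 2
        for a, b in itertools.combinations(levels, 2):
            sub_a = configs[configs[param] == a].set_index(others)["r2_total"]
            sub_b = configs[configs[param] == b].set_index(others)["r2_total"]
            common = sub_a.index.intersection(sub_b.index)
            stat, p = ttest_rel(sub_a.loc[common], sub_b.loc[common])
            tests.append(
                dict(parameter=param, level_a=a, level_b=b,
                     mean_diff=float((sub_a.loc[common] - sub_b.loc[common]).mean()),
                     t=float(stat), p=float(p),
                     p_bonferroni=float(min(1.0, p * n_comparisons)))
            )
    return SweepResult(configs=configs, pairwise_tests=pd.DataFrame(tests))


# ---------------------------------------------------------------------------
# PCO and CAP
# ---------------------------------------------------------------------------

def pco(d: DissimilarityMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates analysis (classical scaling).

    Returns (scores, eigenvalues): scores span the positive-eigenvalue
    axes (columns ordered by decreasing eigenvalue); the full eigenvalue
    spectrum, including negative values from semi-metric dissimilarities,
    is returned alongside.
    """
    values = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, float)
    g = _gower_center(values)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > 1e-9 * max(1.0, abs(eigval[0]))
    scores = eigvec[:, pos] * np.sqrt(eigval[pos])
    return scores, eigval


@dataclass
class CapResult:
    """Leave-one-out classification of a CAP discriminant analysis."""

    grouping: str
    m: int
    predicted: np.ndarray
    groups: np.ndarray
    error_pct: float


def _project_new_point(scores: np.ndarray, eigval_pos: np.ndarray,
                       d_new_sq: np.ndarray) -> np.ndarray:
    """Gower add-a-point: coordinates of a new object from its squared
    distances to the training objects."""
    q = (scores**2).sum(axis=1)
    c = d_new_sq - q
    c = c - c.mean()
    return -0.5 * (scores / eigval_pos).T @ c


def cap_loocv(d: DissimilarityMatrix | np.ndarray, groups, m: int = 8,
              grouping: str = "group") -> CapResult:
    """CAP leave-one-out cross-validation classification error.

    For each held-out observation a PCO and canonical discriminant
    analysis are computed on the remaining data's first ``m`` PCO axes;
    the held-out point is projected in and assigned to the nearest group
    centroid in canonical space.  ``m`` is clipped to the available
    positive-eigenvalue axes.
    """
    values = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, float)
    groups = np.asarray(groups)
    n = values.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")

    from scipy.linalg import eigh as scipy_eigh

    predicted = np.empty(n, dtype=groups.dtype)
    clipped = False
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        g = _gower_center(values[np.ix_(keep, keep)])
        k = len(keep)
        lo = max(0, k - (m + 5))
        eigval, eigvec = scipy_eigh((g + g.T) / 2.0, subset_by_index=[lo, k - 1])
        order = np.argsort(eigval)[::-1]
        eigval = eigval[order]
        eigvec = eigvec[:, order]
        pos = eigval > 1e-9 * max(1.0, abs(eigval[0]))
        scores = eigvec[:, pos] * np.sqrt(eigval[pos])
        eigval = eigval[pos]
        m_i = min(m, scores.shape[1], len(keep) - len(np.unique(groups[keep])))
        if m_i < m:
            clipped = True
        m_i = max(m_i, 1)
        x_train = scores[:, :m_i]
        lam = eigval[:m_i]
        x_new = _project_new_point(x_train, lam, values[i, keep] ** 2)

        lda = LinearDiscriminantAnalysis()
        lda.fit(x_train, groups[keep])
        z_train = lda.transform(x_train)
        z_new = lda.transform(x_new.reshape(1, -1))
        centroids = {gname: z_train[groups[keep] == gname].mean(axis=0)
                     for gname in np.unique(groups[keep])}
        names = list(centroids)
        dists = [np.linalg.norm(z_new[0] - centroids[gname]) for gname in names]
        predicted[i] = names[int(np.argmin(dists))]

    if clipped:
        import warnings

        warnings.warn("m clipped to the available positive PCO axes")
    error = 100.0 * float(np.mean(predicted != groups))
    return CapResult(grouping=grouping, m=m, predicted=predicted, groups=groups,
                     error_pct=error)
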