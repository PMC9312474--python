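"""Precision of repeated observations versus repeats and swim distance.

Univariate precision is the inverse of the standard error (of the mean)
to mean ratio; the curves here report SE/mean itself, so smaller is more
precise.  For each transect, k of its 18 passes are drawn without
replacement many times; the ratio (sd / sqrt(k)) / mean is averaged over
draws and then over transects.  Because a 10 m transect costs less swim
distance than a 50 m one, configurations are also compared at matched
total swim distance = repeats x transect length.

The multivariate analogue is the pseudo standard error
multSE = sqrt(MS_residual / k) from a PERMANOVA without the observer
factor (Island fixed; Location, Transect nested random), computed on the
same per-transect subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ems import FactorSpec, VarPartModel
from .multivariate import DissimilarityMatrix, _gower_center

__all__ = [
    "PrecisionPoint",
    "PrecisionCurve",
    "MultSEPoint",
    "univariate_precision",
    "precision_curve",
    "precision_vs_swim_distance",
    "turbidity_stratified_precision",
    "mult_se",
]


@dataclass
class PrecisionPoint:
    """SE/mean at one number of repeats, averaged over transects."""

    k_repeats: int
    estimate: float
    ci_lo: float
    ci_hi: float
    per_transect: np.ndarray
    n_excluded: int  # draws with zero subsample mean (ratio undefined)


@dataclass
class PrecisionCurve:
    """SE/mean as a function of repeats for one response and length."""

    response: str
    transect_length_m: float
    points: pd.DataFrame  # k, distance, estimate, ci_lo, ci_hi, n_excluded


def univariate_precision(
    series_per_transect,
    k_repeats: int,
    n_sim: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
) -> PrecisionPoint:
    """SE/mean ratio for subsamples of k repeats per transect.

    Draws with a zero subsample mean (the ratio is undefined for a species
    absent from the whole draw) are excluded and counted rather than
    silently dropped as NaN.  The confidence interval uses the pooled
    standard deviation of the per-draw estimates across transects.
    """
    if k_repeats < 2:
        raise ValueError("k_repeats must be >= 2 (SE undefined for k < 2)")
    rng = np.random.default_rng(seed)
    series = [np.asarray(s, dtype=float) for s in series_per_transect]
    per_transect = []
    per_transect_var = []
    excluded = 0
    for s in series:
        if k_repeats > len(s) and not with_replacement:
            raise ValueError("k_repeats exceeds the series length")
        draws = np.empty(n_sim)
        draws[:] = np.nan
        for i in range(n_sim):
            pick = rng.choice(len(s), size=k_repeats, replace=with_replacement)
            sub = s[pick]
            m = sub.mean()
            if m == 0:
                excluded += 1
                continue
            draws[i] = (sub.std(ddof=1) / np.sqrt(k_repeats)) / m
        valid = draws[~np.isnan(draws)]
        per_transect.append(valid.mean() if len(valid) else np.nan)
        per_transect_var.append(valid.var(ddof=1) if len(valid) > 1 else np.nan)
    per_transect = np.asarray(per_transect)
    ok = ~np.isnan(per_transect)
    est = float(per_transect[ok].mean())
    pooled_sd = float(np.sqrt(np.nanmean(per_transect_var))) if np.any(ok) else np.nan
    half = 1.96 * pooled_sd / np.sqrt(ok.sum()) if ok.sum() else np.nan
    return PrecisionPoint(
        k_repeats=k_repeats,
        estimate=est,
        ci_lo=est - half,
        ci_hi=est + half,
        per_transect=per_transect,
        n_excluded=excluded,
    )


def precision_curve(
    series_per_transect,
    transect_length_m: float,
    ks=None,
    n_sim: int = 1000,
    seed: int = 0,
    response: str = "response",
) -> PrecisionCurve:
    """SE/mean for every number of repeats in ``ks`` (default 2..18)."""
    n_pass = len(np.asarray(series_per_transect[0]))
    ks = range(2, n_pass + 1) if ks is None else ks
    rows = []
    for k in ks:
        pt = univariate_precision(series_per_transect, k, n_sim=n_sim,
                                  seed=seed + k)
        rows.append(
            dict(k=k, distance=k * transect_length_m, estimate=pt.estimate,
                 ci_lo=pt.ci_lo, ci_hi=pt.ci_hi, n_excluded=pt.n_excluded)
        )
    return PrecisionCurve(response=response, transect_length_m=transect_length_m,
                          points=pd.DataFrame(rows))


def precision_vs_swim_distance(curves: dict[float, PrecisionCurve]) -> pd.DataFrame:
    """Align precision curves on total swim distance.

    Returns one row per (distance, length, repeats) with a ``best`` flag
    marking the configuration(s) minimizing SE/mean at that distance;
    exact ties are all flagged.
    """
    rows = []
    for length, curve in curves.items():
        for _, r in curve.points.iterrows():
            rows.append(dict(distance=r["distance"], length=length, k=int(r["k"]),
                             estimate=r["estimate"]))
    df = pd.DataFrame(rows).sort_values(["distance", "length"]).reset_index(drop=True)
    df["best"] = False
    for dist, sub in df.groupby("distance"):
        best = sub["estimate"].min()
        df.loc[sub.index[sub["estimate"] <= best + 1e-12], "best"] = True
    return df


def turbidity_stratified_precision(
    series_per_transect,
    turbidity_grades,
    transect_length_m: float,
    ks=None,
    n_sim: int = 500,
    seed: int = 0,
    response: str = "response",
) -> dict[str, PrecisionCurve]:
    """Precision curves per turbidity tercile.

    Transects are ranked by their visually graded turbidity (ties broken
    by stable input order) and split into three equal-size groups.
    """
    series = list(series_per_transect)
    grades = np.asarray(turbidity_grades)
    if len(series) != len(grades):
        raise ValueError("need one turbidity grade per transect")
    if len(series) < 3:
        raise ValueError("need at least 3 transects for terciles")
    order = np.argsort(grades, kind="stable")
    terciles = np.array_split(order, 3)
    out = {}
    for name, members in zip(("low", "mid", "high"), terciles):
        out[name] = precision_curve(
            [series[i] for i in members], transect_length_m, ks=ks,
            n_sim=n_sim, seed=seed, response=f"{response}[{name} turbidity]",
        )
    return out


# ---------------------------------------------------------------------------
# multivariate pseudo standard error
# ---------------------------------------------------------------------------

@dataclass
class MultSEPoint:
    """multSE = sqrt(MS_residual / k) at one number of repeats."""

    k_repeats: int
    estimate: float
    ci_lo: float
    ci_hi: float
    draws: np.ndarray


def mult_se(
    d: DissimilarityMatrix | np.ndarray,
    labels: pd.DataFrame,
    k_repeats: int,
    n_sim: int = 200,
    seed: int = 0,
) -> MultSEPoint:
    """Multivariate pseudo standard error at k repeats per transect.

    For each draw, k of the passes of every transect are subsampled
    without replacement; the PERMANOVA residual mean square of the reduced
    model (Island fixed, Location and Transect nested random, no observer
    factor) gives multSE = sqrt(MS_residual / k).  The CI is the normal
    interval from the standard deviation over draws.
    """
    if k_repeats < 2:
        raise ValueError("k_repeats must be >= 2")
    values = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, float)
    rng = np.random.default_rng(seed)

    tr_key = labels[["island", "location", "transect"]].astype(str).agg("|".join, axis=1)
    transects = sorted(tr_key.unique())
    members = {t: np.where((tr_key == t).to_numpy())[0] for t in transects}
    n_pass = len(members[transects[0]])
    if any(len(m) != n_pass for m in members.values()):
        raise ValueError("unbalanced passes per transect")
    if k_repeats > n_pass:
        raise ValueError("k_repeats exceeds passes per transect")

    n_isl = labels["island"].nunique()
    loc_per_isl = labels.groupby("island")["location"].nunique().iloc[0]
    tr_per_loc = labels.groupby(["island", "location"])["transect"].nunique().iloc[0]
    model = VarPartModel(
        [
            FactorSpec("island", n_isl, fixed=True),
            FactorSpec("location", int(loc_per_isl), nested_in=("island",)),
            FactorSpec("transect", int(tr_per_loc), nested_in=("location",)),
        ],
        [("island",), ("location",), ("transect",)],
        n_replicates=k_repeats,
    )

    draws = np.empty(n_sim)
    proj = None
    for i in range(n_sim):
        idx = np.concatenate([
            rng.choice(members[t], size=k_repeats, replace=False) for t in transects
        ])
        sub_labels = labels.iloc[idx].reset_index(drop=True)
        if proj is None:
            proj = model.projections(sub_labels)  # same balanced layout each draw
        g = _gower_center(values[np.ix_(idx, idx)])
        ss_res = float(np.sum(proj["Residual"] * g))
        ms_res = ss_res / model.residual_df
        draws[i] = np.sqrt(max(ms_res, 0.0) / k_repeats)
    est = float(draws.mean())
    half = 1.96 * float(draws.std(ddof=1)) / np.sqrt(n_sim) if n_sim > 1 else np.nan
    return MultSEPoint(k_repeats=k_repeats, estimate=est, ci_lo=est - half,
                       ci_hi=est + half, draws=draws)
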