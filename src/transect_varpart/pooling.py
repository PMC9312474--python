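"""Monte-Carlo pooling of observations: design-error assessment.

If transects are too short, single passes may record so few fish that
pairs of passes share no species at all — Bray-Curtis dissimilarity 1, an
uninformative value — and the passes would have to be pooled before any
multivariate analysis.  The assessment draws, within each level of a
spatial factor (transect or location), two disjoint random subsets of k
passes, averages the raw counts within each subset, fourth-root transforms
the pooled profiles and computes their Bray-Curtis dissimilarity.  The
frequency distribution of these dissimilarities over many random draws
shows whether single passes behave as solid repeats (few values near 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis

from .core import CommunityMatrix, _apply_transform

__all__ = ["PoolingDistribution", "pooled_dissimilarity_distribution", "count_uninformative"]

HIST_BINS = np.round(np.arange(0.0, 1.05, 0.05), 10)  # bin width 0.05 on [0, 1]

_FACTOR_COLS = {"transect": ["island", "location", "transect"],
                "location": ["island", "location"]}


@dataclass
class PoolingDistribution:
    """Dissimilarity samples between pooled subsets, per factor level."""

    factor: str
    pool_size: int
    window_m: tuple[float, float] | None
    levels: list[str]
    samples: np.ndarray            # levels x n_perm, NaN where undefined
    histograms: np.ndarray         # levels x bins
    average_histogram: np.ndarray  # mean over levels, bin by bin
    uninformative_count: int       # samples equal to 1
    undefined_count: int           # both pooled profiles all-zero

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def count_uninformative(samples) -> tuple[int, int]:
    """(number of samples equal to 1, number of undefined samples).

    A dissimilarity of exactly 1 means the two pooled profiles share no
    species; NaN marks pairs where both profiles were all-zero (undefined
    Bray-Curtis, recorded separately, never imputed).
    """
    arr = np.asarray(samples, dtype=float).ravel()
    ones = int(np.sum(arr == 1.0))
    undefined = int(np.sum(np.isnan(arr)))
    return ones, undefined


def pooled_dissimilarity_distribution(
    matrix: CommunityMatrix,
    factor: str = "transect",
    pool_size: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    transform: str = "fourth_root",
    transform_before_pooling: bool = False,
) -> PoolingDistribution:
    """Dissimilarity distribution between disjoint pooled subsets.

    Pooling is the arithmetic mean of raw counts; the transform is applied
    after pooling (``transform_before_pooling`` flips the order).  The two
    subsets are drawn without replacement and are disjoint, so a shared
    pass can never bias the dissimilarity downward.
    """
    if factor not in _FACTOR_COLS:
        raise ValueError("factor must be 'transect' or 'location'")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)

    counts = matrix.counts.to_numpy(dtype=float)
    if transform_before_pooling:
        counts = _apply_transform(counts, transform)
    meta = matrix.row_meta
    key = meta[_FACTOR_COLS[factor]].astype(str).agg("|".join, axis=1)
    levels = sorted(key.unique())

    samples = np.full((len(levels), n_perm), np.nan)
    for li, level in enumerate(levels):
        members = np.where((key == level).to_numpy())[0]
        if len(members) < 2 * pool_size:
            raise ValueError(
                f"level {level!r} has {len(members)} observations; "
                f"needs >= {2 * pool_size} for pool_size={pool_size}"
            )
        for p in range(n_perm):
            pick = rng.choice(members, size=2 * pool_size, replace=False)
            a = counts[pick[:pool_size]].mean(axis=0)
            b = counts[pick[pool_size:]].mean(axis=0)
            if not transform_before_pooling:
                a = _apply_transform(a, transform)
                b = _apply_transform(b, transform)
            if a.sum() == 0 and b.sum() == 0:
                continue  # undefined, stays NaN
            samples[li, p] = braycurtis(a, b)

    histograms = np.vstack([
        np.histogram(row[~np.isnan(row)], bins=HIST_BINS)[0] for row in samples
    ]).astype(float)
    ones, undefined = count_uninformative(samples)
    return PoolingDistribution(
        factor=factor,
        pool_size=pool_size,
        window_m=matrix.window_m,
        levels=levels,
        samples=samples,
        histograms=histograms,
        average_histogram=histograms.mean(axis=0),
        uninformative_count=ones,
        undefined_count=undefined,
    )
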