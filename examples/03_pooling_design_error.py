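"""Assess design error: would single passes need to be pooled?

Within each transect, two disjoint random subsets of k passes are pooled
(mean of raw counts), fourth-root transformed and compared with
Bray-Curtis.  Values near 1 are uninformative (no shared species) and
would indicate transects too short to treat passes as solid repeats.
"""

import numpy as np

from transect_varpart import build_community_matrix
from transect_varpart.multivariate import window_for_length
from transect_varpart.pooling import pooled_dissimilarity_distribution
from transect_varpart.simulate import SimulationConfig, simulate_study

records, _ = simulate_study(SimulationConfig(seed=2, n_species=36))

for length in (10.0, 50.0):
    cm = build_community_matrix(records, "MaxCount",
                                window=window_for_length(length))
    print(f"\n-- effective transect length {length:.0f} m --")
    for k in (1, 2, 4, 6):
        dist = pooled_dissimilarity_distribution(cm, "transect", k,
                                                 n_perm=300, seed=0)
        mean = np.nanmean(dist.samples)
        print(f"pool size {k}: mean dissimilarity {mean:.3f}, "
              f"uninformative values {dist.uninformative_count} "
              f"(undefined {dist.undefined_count}) over "
              f"{dist.n_levels} transects x 300 draws")

print("\nPooled subsets become more similar as the pool grows, and more so "
      "on long transects; with almost no uninformative values even at "
      "10 m, single passes can serve as repeats without pooling.")
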