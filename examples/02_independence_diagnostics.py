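"""Diagnose temporal dependence and observer effects on a synthetic study.

Three diagnostics: per-species autocorrelation of the 18 ordered counts of
each transect, a mixed logistic regression of presence on pass order
(attraction/deterrence by observers), and a partial Mantel correlogram of
assemblage dissimilarity against temporal lag.
"""

import numpy as np

from transect_varpart import build_community_matrix
from transect_varpart.core import StudyDesign
from transect_varpart.independence import (
    AcfResult,
    fit_order_effect,
    partial_mantel_correlogram,
)
from transect_varpart.multivariate import dissimilarity
from transect_varpart.simulate import SimulationConfig, SpeciesTraits, simulate_study

# a compact design with the full 18 passes per transect; the community
# shares AR(1) memory across passes (fish lingering between passes), and
# one species is additionally deterred by observers
design = StudyDesign(n_islands=2, locations_per_island=2,
                     transects_per_location=2, n_observers=3,
                     repeats_per_observer=6)
traits = [SpeciesTraits(name=f"sp{s:02d}", base_log_abundance=0.6,
                        island_effect=(0.0, 0.0), ar1_rho=0.7)
          for s in range(8)]
traits[0] = SpeciesTraits(name="sp00", base_log_abundance=0.6,
                          island_effect=(0.0, 0.0), order_effect=-0.35,
                          detectability=0.8, ar1_rho=0.7)
traits[1] = SpeciesTraits(name="sp01", base_log_abundance=0.6,
                          island_effect=(0.0, 0.0), ar1_rho=0.8)
config = SimulationConfig(design=design, n_species=8, seed=3,
                          species_traits=tuple(traits),
                          sigma2_residual=0.8,
                          turbidity=(1,) * design.n_transects)
records, _ = simulate_study(config)
cm = build_community_matrix(records, "MaxCount", window=(0, 50))
meta = cm.row_meta
transects = meta[["island", "location", "transect"]].agg("|".join, axis=1)

# --- autocorrelation of the species with injected AR(1) memory -----------
series = []
for t in sorted(transects.unique()):
    mask = (transects == t).to_numpy()
    order = meta.loc[mask, "order_index"].to_numpy()
    series.append(cm.counts["sp01"].to_numpy()[mask][np.argsort(order)])
acf = AcfResult.from_series("sp01", series, max_lag=4)
print("mean ACF of sp01 (AR(1) injected), lags 0..4:",
      np.round(acf.mean, 3))
print("  -> positive lag-1 autocorrelation: successive passes are not "
      "independent for this species")

# --- order effect of the deterred species --------------------------------
presence_series = []
for t in sorted(transects.unique()):
    mask = (transects == t).to_numpy()
    order = np.sort(meta.loc[mask, "order_index"].to_numpy())
    y = cm.counts["sp00"].to_numpy()[mask][np.argsort(meta.loc[mask, "order_index"].to_numpy())]
    presence_series.append((t, order, (y > 0).astype(float)))
fit = fit_order_effect(presence_series, scope="all_18", species_id="sp00")
print(f"order effect of sp00 (deterrence injected): beta = {fit.beta:.3f}, "
      f"p = {fit.p_value:.3g}")
print("  -> negative log-odds per pass: the species is seen less and less "
      "as observers keep passing")

# --- partial Mantel correlogram of the whole assemblage ------------------
cm4 = build_community_matrix(records, "MaxCount", window=(0, 50),
                             transform="fourth_root")
dm = dissimilarity(cm4, "bray_curtis")
mc = partial_mantel_correlogram(
    dm.values, meta["order_index"].to_numpy(), transects.to_numpy(),
    meta["observer"].to_numpy(), n_perm=199, seed=0, max_lag=4)
for lag, stat, p in zip(mc.lags, mc.statistic, mc.p_holm):
    print(f"lag {lag}: partial Mantel = {stat: .3f}, Holm p = {p:.3f}")
print("  -> a positive, significant small-lag statistic means assemblages "
      "recorded close in time are more similar than expected")
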