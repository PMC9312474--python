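import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import transect_varpart as tv
from transect_varpart.core import StudyDesign
from transect_varpart.independence import (
    AcfResult,
    fit_order_effect,
    holm_correction,
    mean_acf,
    partial_mantel_correlogram,
    species_acf,
)
from transect_varpart.multivariate import dissimilarity
from transect_varpart.simulate import SimulationConfig, SpeciesTraits, simulate_study


def brute_acf(y, k):
    """Direct double-loop evaluation of the autocorrelation estimator."""
    y = np.asarray(y, float)
    n = len(y)
    ybar = y.mean()
    num = sum((y[i] - ybar) * (y[i + k] - ybar) for i in range(n - k))
    den = sum((y[i] - ybar) ** 2 for i in range(n))
    return num / den


class TestAcf:
    def test_lag_zero_is_one(self, rng):
        y = rng.integers(0, 10, size=18)
        if y.min() == y.max():
            y[0] += 1
        assert species_acf(y, 3)[0] == pytest.approx(1.0)

    def test_constant_series_flagged(self):
        out = species_acf([3, 3, 3, 3], 2)
        assert np.isnan(out).all()

    def test_hand_evaluated_example(self):
        # numerator 1.25, denominator 5 at lag 1
        assert species_acf([1, 2, 3, 4], 1)[1] == pytest.approx(0.25)

    @settings(max_examples=1000, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=4, max_size=18),
           st.integers(1, 3))
    def test_matches_brute_force(self, y, k):
        y = np.asarray(y)
        out = species_acf(y, k)
        if y.min() == y.max():
            assert np.isnan(out).all()
        else:
            assert out[k] == pytest.approx(brute_acf(y, k), abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            species_acf([1], 0)
        with pytest.raises(ValueError):
            species_acf([1, 2, 3], 3)


class TestMeanAcf:
    def test_idempotent_on_identical(self):
        a = species_acf([1, 2, 3, 4], 1)
        m, n = mean_acf([a, a])
        assert np.allclose(m, a)
        assert (n == 2).all()

    def test_undefined_excluded(self):
        defined = species_acf([1, 2, 3, 4], 1)
        undefined = species_acf([2, 2, 2, 2], 1)
        m, n = mean_acf([defined, undefined])
        assert np.allclose(m, defined)
        assert (n == 1).all()

    def test_simple_mean(self):
        m, _ = mean_acf([np.array([1.0, 0.2]), np.array([1.0, 0.4])])
        assert m[1] == pytest.approx(0.3)

    def test_from_series_helper(self):
        res = AcfResult.from_series("sp", [[1, 2, 3, 4], [4, 3, 2, 1]], 1)
        assert res.per_transect.shape == (2, 2)
        assert res.mean[0] == pytest.approx(1.0)


def make_presence_series(gamma, seed, n_tr=25, n=18, sigma=0.7, alpha=-0.5):
    r = np.random.default_rng(seed)
    out = []
    for j in range(n_tr):
        b = r.normal(0, sigma)
        order = np.arange(1, n + 1)
        eta = alpha + b + gamma * (order - (n + 1) / 2)
        p = 1 / (1 + np.exp(-eta))
        out.append((f"t{j}", order, (r.random(n) < p).astype(float)))
    return out


class TestOrderEffect:
    def test_null_beta_near_zero(self):
        fit = fit_order_effect(make_presence_series(0.0, 1))
        assert abs(fit.beta) < 0.05
        assert fit.p_value > 0.05

    def test_sign_recovery(self):
        up = fit_order_effect(make_presence_series(0.3, 2))
        assert up.beta > 0 and up.p_value < 0.05
        down = fit_order_effect(make_presence_series(-0.3, 3))
        assert down.beta < 0 and down.p_value < 0.05

    def test_type_one_error_near_nominal(self):
        # 40 null fits; binomial(40, 0.05) stays below 7 rejections with
        # probability > 0.999
        rejections = sum(
            fit_order_effect(make_presence_series(0.0, 100 + s, n_tr=15)).p_value < 0.05
            for s in range(40)
        )
        assert rejections <= 7

    def test_all_present_is_separation(self):
        series = [(f"t{j}", np.arange(1, 7), np.ones(6)) for j in range(4)]
        fit = fit_order_effect(series, scope="per_observer_6")
        assert fit.separation

    def test_needs_two_series_with_presence(self):
        with pytest.raises(ValueError):
            fit_order_effect([("t0", np.arange(1, 7), np.zeros(6))])

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4 Laplace fit on the same data."""
        series = make_presence_series(0.2, 7, n_tr=12)
        rows = [(g, o_i, p_i) for g, o, p in series for o_i, p_i in zip(o, p)]
        csv = tmp_path / "oe.csv"
        pd.DataFrame(rows, columns=["transect", "order", "presence"]).to_csv(
            csv, index=False)
        script = tmp_path / "oe.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$order <- d$order - mean(d$order)
            m <- glmer(presence ~ order + (1|transect), data=d, family=binomial)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, check=True)
        alpha_r, beta_r, sd_r = map(float, proc.stdout.strip().split("\n"))
        fit = fit_order_effect(series)
        assert fit.alpha == pytest.approx(alpha_r, abs=5e-3)
        assert fit.beta == pytest.approx(beta_r, abs=5e-3)
        assert np.sqrt(fit.sigma2_transect) == pytest.approx(sd_r, abs=0.05)


def holm_reference(p):
    order = np.argsort(p)
    out = np.empty_like(p)
    prev = 0.0
    for rank, i in enumerate(order):
        prev = max(prev, min(1.0, (len(p) - rank) * p[i]))
        out[i] = prev
    return out


def test_holm_correction_matches_reference(rng):
    p = rng.random(8)
    assert np.allclose(holm_correction(p), holm_reference(p))


def _mantel_study(rho, seed, n_species=10):
    design = StudyDesign(n_islands=2, locations_per_island=3,
                         transects_per_location=2, n_observers=3,
                         repeats_per_observer=3)
    traits = tuple(
        SpeciesTraits(name=f"sp{s:02d}", base_log_abundance=0.8,
                      island_effect=(0.0, 0.0), ar1_rho=rho)
        for s in range(n_species)
    )
    cfg = SimulationConfig(design=design, n_species=n_species,
                           sigma2_location=0.2, sigma2_transect=0.2,
                           sigma2_observer=0.01, sigma2_obs_location=0.02,
                           sigma2_obs_transect=0.05, sigma2_residual=0.5,
                           seed=seed, species_traits=traits,
                           turbidity=(1,) * design.n_transects)
    records, _ = simulate_study(cfg)
    cm = tv.build_community_matrix(records, "MaxCount", window=(0, 50),
                                   transform="fourth_root")
    dm = dissimilarity(cm, "bray_curtis")
    meta = cm.row_meta
    transects = meta[["island", "location", "transect"]].agg("|".join, axis=1)
    return dm, meta, transects


class TestMantelCorrelogram:
    def test_constant_dissimilarity_gives_zero_statistic(self):
        n = 12
        d = np.ones((n, n)) - np.eye(n)
        order = np.tile(np.arange(1, 7), 2)
        transect = np.repeat(["a", "b"], 6)
        observer = np.tile(["o1", "o2", "o3"], 4)
        mc = partial_mantel_correlogram(d, order, transect, observer,
                                        n_perm=99, seed=0, max_lag=3)
        assert np.allclose(mc.statistic, 0.0)

    def test_pvalues_in_unit_interval(self):
        dm, meta, transects = _mantel_study(0.0, 1)
        mc = partial_mantel_correlogram(
            dm.values, meta["order_index"].to_numpy(), transects.to_numpy(),
            meta["observer"].to_numpy(), n_perm=99, seed=0, max_lag=4)
        valid = ~np.isnan(mc.p_values)
        assert (mc.p_values[valid] > 0).all() and (mc.p_values[valid] <= 1).all()

    def test_detects_injected_temporal_dependence(self):
        dm, meta, transects = _mantel_study(0.8, 2)
        mc = partial_mantel_correlogram(
            dm.values, meta["order_index"].to_numpy(), transects.to_numpy(),
            meta["observer"].to_numpy(), n_perm=199, seed=0, max_lag=4)
        assert mc.statistic[0] > 0
        assert mc.p_values[0] < 0.05

    def test_null_calibrated(self):
        hits = 0
        for seed in range(3):
            dm, meta, transects = _mantel_study(0.0, 10 + seed)
            mc = partial_mantel_correlogram(
                dm.values, meta["order_index"].to_numpy(), transects.to_numpy(),
                meta["observer"].to_numpy(), n_perm=99, seed=seed, max_lag=4)
            hits += int(np.nanmin(mc.p_holm) < 0.05)
        assert hits <= 1
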