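import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import transect_varpart as tv
from transect_varpart.core import StudyDesign, build_community_matrix
from transect_varpart.ems import FactorSpec, VarPartModel, standard_design_model
from transect_varpart.multivariate import (
    cap_loocv,
    dissimilarity,
    pco,
    permanova,
    sweep_configurations,
    window_for_length,
)

from conftest import full_design_labels


class TestDissimilarity:
    def test_identical_rows_are_zero(self, small_matrix):
        cm = small_matrix
        dup = cm.counts.copy()
        dup.iloc[1] = dup.iloc[0]
        from transect_varpart.core import CommunityMatrix
        cm2 = CommunityMatrix(counts=dup, row_meta=cm.row_meta)
        for method in ("bray_curtis", "euclidean", "gower", "kulczynski"):
            d = dissimilarity(cm2, method)
            assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        from transect_varpart.core import CommunityMatrix
        counts = pd.DataFrame([[3.0, 0.0], [0.0, 5.0]], columns=["a", "b"])
        meta = pd.DataFrame({"island": ["i", "i"]})
        cm = CommunityMatrix(counts=counts, row_meta=meta)
        assert dissimilarity(cm, "bray_curtis").values[0, 1] == pytest.approx(1.0)
        assert dissimilarity(cm, "kulczynski").values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        from transect_varpart.core import CommunityMatrix
        counts = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], columns=["a", "b"])
        cm = CommunityMatrix(counts=counts, row_meta=pd.DataFrame({"i": [0, 1]}))
        # (|1-2| + |2-1|) / (3 + 3) = 1/3
        assert dissimilarity(cm, "bray_curtis").values[0, 1] == pytest.approx(1 / 3)

    def test_gower_hand_value(self):
        from transect_varpart.core import CommunityMatrix
        counts = pd.DataFrame([[0.0, 0.0, 5.0], [4.0, 2.0, 5.0], [2.0, 1.0, 5.0]],
                              columns=list("abc"))
        cm = CommunityMatrix(counts=counts, row_meta=pd.DataFrame({"i": [0, 1, 2]}))
        d = dissimilarity(cm, "gower")
        # ranges are 4, 2, 0; zero-range species contributes 0:
        # d(0,1) = (4/4 + 2/2 + 0)/3 = 2/3
        assert d.values[0, 1] == pytest.approx(2 / 3)
        assert d.values[0, 2] == pytest.approx((0.5 + 0.5) / 3)

    def test_unknown_method_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            dissimilarity(small_matrix, "chebyshev")

    def test_both_zero_pairs_flagged(self):
        from transect_varpart.core import CommunityMatrix
        counts = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]],
                              columns=["a", "b"])
        cm = CommunityMatrix(counts=counts, row_meta=pd.DataFrame({"i": [0, 1, 2]}))
        d = dissimilarity(cm, "bray_curtis")
        assert d.undefined_pairs[0, 1] and not d.undefined_pairs[0, 2]
        assert d.values[0, 1] == 0.0

    def test_skbio_cross_check(self, small_matrix):
        """scipy/our implementation versus scikit-bio's Bray-Curtis."""
        from skbio.diversity import beta_diversity
        x = small_matrix.counts.to_numpy()[:20]
        from transect_varpart.core import CommunityMatrix
        cm = CommunityMatrix(counts=small_matrix.counts.iloc[:20],
                             row_meta=small_matrix.row_meta.iloc[:20])
        ours = dissimilarity(cm, "bray_curtis").values
        theirs = beta_diversity("braycurtis", x).data
        assert np.allclose(ours, theirs, atol=1e-12)


def anova_oracle(y, labels):
    """Classical balanced ANOVA sums of squares via cell means.

    Independent of the projection machinery: every term's SS is computed
    from group-mean contrasts with explicit nesting/crossing algebra.
    """
    df = labels.copy()
    df["y"] = y
    n = len(df)
    grand = df["y"].mean()

    def cell_mean(cols):
        return df.groupby(cols)["y"].transform("mean")

    m_i = cell_mean(["island"])
    m_l = cell_mean(["island", "location"])
    m_t = cell_mean(["island", "location", "transect"])
    m_o = cell_mean(["observer"])
    m_io = cell_mean(["island", "observer"])
    m_lo = cell_mean(["island", "location", "observer"])
    m_to = cell_mean(["island", "location", "transect", "observer"])

    ss = {
        "island": ((m_i - grand) ** 2).sum(),
        "location": ((m_l - m_i) ** 2).sum(),
        "transect": ((m_t - m_l) ** 2).sum(),
        "observer": ((m_o - grand) ** 2).sum(),
        "island:observer": ((m_io - m_i - m_o + grand) ** 2).sum(),
        "location:observer": ((m_lo - m_l - m_io + m_i) ** 2).sum(),
        "transect:observer": ((m_to - m_t - m_lo + m_l) ** 2).sum(),
    }
    ss["Residual"] = ((df["y"] - m_to) ** 2).sum()
    return ss


class TestPermanova:
    def test_four_point_anova_worked_example(self):
        y = np.array([0.0, 1.0, 10.0, 11.0])
        d = np.abs(y[:, None] - y[None, :])
        model = VarPartModel([FactorSpec("g", 2)], [("g",)], n_replicates=2)
        res = permanova(d, pd.DataFrame({"g": list("aabb")}), model=model, n_perm=0)
        # MS between = 100, MS within = 0.5 -> F = 200
        assert res.table.loc["g", "SS"] == pytest.approx(100.0)
        assert res.table.loc["Residual", "MS"] == pytest.approx(0.5)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(200.0)

    def test_identical_observations_degenerate(self):
        d = np.zeros((8, 8))
        model = VarPartModel([FactorSpec("g", 2)], [("g",)], n_replicates=4)
        res = permanova(d, pd.DataFrame({"g": list("aaaabbbb")}), model=model,
                        n_perm=0)
        assert res.table["SS"].abs().sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.components.to_numpy(), 0.0, atol=1e-12)

    def test_every_term_matches_classical_anova(self, rng):
        """Euclidean single-variable PERMANOVA = univariate ANOVA, all terms."""
        design = StudyDesign()
        labels = full_design_labels(design)
        y = rng.normal(0, 1, len(labels))
        d = np.abs(y[:, None] - y[None, :])
        model = standard_design_model(design)
        res = permanova(d, labels, model=model, n_perm=0)
        oracle = anova_oracle(y, labels)
        for term, ss in oracle.items():
            assert res.table.loc[term, "SS"] == pytest.approx(ss, rel=1e-8), term
        # pseudo-F of transect must equal the classical mixed-model F
        f_tr = ((oracle["transect"] / 20) / (oracle["transect:observer"] / 40))
        assert res.table.loc["transect", "pseudo_F"] == pytest.approx(f_tr, rel=1e-8)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        d = np.abs(y[:, None] - y[None, :])
        labels = pd.DataFrame({"g": list("aaabbb")})
        model = VarPartModel([FactorSpec("g", 2)], [("g",)], n_replicates=3)
        exact = permanova(d, labels, model=model, exhaustive=True)
        mc = permanova(d, labels, model=model, n_perm=9999, seed=5)
        p_exact = exact.table.loc["g", "p_perm"]
        assert p_exact == pytest.approx(0.1)  # 72 of 720 relabelings tie or beat
        assert mc.table.loc["g", "p_perm"] == pytest.approx(p_exact, abs=0.02)

    def test_skbio_pseudo_f_cross_check(self, rng):
        """One-way pseudo-F against scikit-bio's PERMANOVA."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        x = rng.normal(0, 1, (12, 4))
        x[6:] += 0.8
        d = squareform(pdist(x))
        groups = ["a"] * 6 + ["b"] * 6
        model = VarPartModel([FactorSpec("g", 2)], [("g",)], n_replicates=6)
        ours = permanova(d, pd.DataFrame({"g": groups}), model=model, n_perm=0)
        theirs = skbio_permanova(DistanceMatrix(d), grouping=groups,
                                 permutations=0)
        assert ours.table.loc["g", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], rel=1e-10)

    def test_signed_components_and_percentages(self, full_study):
        records, _ = full_study
        cm = build_community_matrix(records, "MaxCount", window=(0, 50),
                                    transform="fourth_root")
        dm = dissimilarity(cm, "bray_curtis")
        res = permanova(dm, cm.row_meta, n_perm=0)
        # percentages from truncated components sum to 100
        assert res.percent.sum() == pytest.approx(100.0)
        assert (res.percent >= 0).all()
        # SS partition is exact
        total = res.table["SS"].sum()
        g = dm.values
        gc = -0.5 * g**2
        n = g.shape[0]
        j = np.eye(n) - 1.0 / n
        assert total == pytest.approx(np.trace(j @ gc @ j), rel=1e-8)
        assert 0 < res.r2_total < 1


class TestSweep:
    def test_grid_enumerates_120_models(self, small_study):
        records, _ = small_study
        sweep = sweep_configurations(records, n_perm=0, seed=0)
        assert sweep.n_models == 120
        assert sweep.configs["r2_total"].between(0, 1).all()

    def test_presence_absence_collapses_metrics(self, small_study):
        records, _ = small_study
        sweep = sweep_configurations(records, n_perm=0, seed=0)
        pa = sweep.configs[sweep.configs["transform"] == "presence_absence"]
        piv = pa.pivot_table(index=["length", "method"], columns="metric",
                             values="r2_total")
        assert np.allclose(piv["MaxCount"], piv["MinCount"], atol=1e-10)

    def test_pairwise_tests_cover_all_parameters(self, small_study):
        records, _ = small_study
        sweep = sweep_configurations(records, n_perm=0, seed=0)
        counts = sweep.pairwise_tests.groupby("parameter").size()
        assert counts["length"] == 10 and counts["method"] == 6
        assert counts["metric"] == 1 and counts["transform"] == 3
        assert sweep.pairwise_tests["p_bonferroni"].between(0, 1).all()


class TestPco:
    def test_two_points(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        scores, eig = pco(d)
        assert scores.shape[1] == 1
        assert abs(scores[0, 0] - scores[1, 0]) == pytest.approx(3.0)

    def test_euclidean_identity(self, rng):
        x = rng.normal(0, 1, (15, 4))
        d = squareform(pdist(x))
        scores, eig = pco(d)
        # classical scaling reproduces all pairwise distances exactly
        assert np.allclose(squareform(pdist(scores)), d, atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, small_matrix):
        dm = dissimilarity(small_matrix, "bray_curtis")
        g = dm.values
        n = g.shape[0]
        j = np.eye(n) - 1.0 / n
        centered = j @ (-0.5 * g**2) @ j
        _, eig = pco(dm)
        assert eig.sum() == pytest.approx(np.trace(centered), abs=1e-8)


class TestCap:
    def make_clusters(self, rng, sep=5.0, n=10):
        x = np.vstack([rng.normal(0, 0.1, (n, 3)), rng.normal(sep, 0.1, (n, 3))])
        groups = np.array(["a"] * n + ["b"] * n)
        return squareform(pdist(x)), groups

    def test_separable_clusters_zero_error(self, rng):
        d, groups = self.make_clusters(rng)
        assert cap_loocv(d, groups, m=3).error_pct == 0.0

    def test_relabeling_invariance(self, rng):
        d, groups = self.make_clusters(rng, sep=0.5)
        renamed = np.where(groups == "a", "x", "y")
        assert (cap_loocv(d, groups, m=3).error_pct
                == cap_loocv(d, renamed, m=3).error_pct)

    def test_permuted_labels_near_chance(self, rng):
        d, groups = self.make_clusters(rng, sep=5.0, n=12)
        errs = []
        for s in range(6):
            perm = np.random.default_rng(s).permutation(groups)
            errs.append(cap_loocv(d, perm, m=3).error_pct)
        # chance is 1 - 1/2 = 50%; the average over shuffles should be near it
        assert 25.0 <= np.mean(errs) <= 75.0

    def test_m_clipped_with_warning(self, rng):
        d, groups = self.make_clusters(rng, n=4)
        with pytest.warns(UserWarning):
            cap_loocv(d, groups, m=50)

    def test_preconditions(self, rng):
        d, groups = self.make_clusters(rng)
        with pytest.raises(ValueError):
            cap_loocv(d, groups, m=0)
        with pytest.raises(ValueError):
            cap_loocv(d, np.array(["a"] * 19 + ["b"]), m=2)


def test_window_for_length():
    assert window_for_length(50) == (0, 50)
    assert window_for_length(10) == (20, 30)
    with pytest.raises(ValueError):
        window_for_length(15)
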