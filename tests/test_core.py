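import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transect_varpart.core import (
    DetectionEvent,
    ObservationRecord,
    StudyDesign,
    build_community_matrix,
    max_count,
    min_count,
    read_observations,
    shannon_diversity,
    species_density,
    split_distance_window,
    transform_counts,
    write_observations,
)
from transect_varpart.errors import FormatError, IntegrityError


def make_record(events, duration=100.0, **kw):
    base = dict(island="i1", location="l1", transect="t1", observer="o1",
                repeat_index=1, order_index=1, duration_s=duration)
    base.update(kw)
    return ObservationRecord(events=events, **base)


class TestEvents:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DetectionEvent("a", -1.0, 2.0, 1)
        with pytest.raises(ValueError):
            DetectionEvent("a", 3.0, 2.0, 1)
        with pytest.raises(ValueError):
            DetectionEvent("a", 1.0, 2.0, 0)


class TestIO:
    def test_round_trip(self, tmp_path, small_study):
        records, _ = small_study
        path = tmp_path / "obs.csv"
        write_observations(records, path)
        back = read_observations(path)
        assert len(back) == len(records)
        key = lambda r: r.key
        for a, b in zip(sorted(records, key=key), sorted(back, key=key)):
            assert a.key == b.key
            assert a.order_index == b.order_index
            assert len(a.events) == len(b.events)
            for ea, eb in zip(a.events, b.events):
                assert ea.species_id == eb.species_id
                assert ea.t_start == pytest.approx(eb.t_start)
                assert ea.n_individuals == eb.n_individuals

    def test_single_pass_three_events(self, tmp_path):
        rec = make_record([DetectionEvent("a", 1, 2), DetectionEvent("b", 3, 4),
                           DetectionEvent("a", 5, 6, 2)])
        path = tmp_path / "one.csv"
        write_observations([rec], path)
        back = read_observations(path)
        assert len(back) == 1 and len(back[0].events) == 3

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"island": ["a"], "species": ["x"]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_observations(path)

    def test_duplicate_order_index_is_integrity_error(self, tmp_path):
        r1 = make_record([DetectionEvent("a", 1, 2)], observer="o1", order_index=1)
        r2 = make_record([DetectionEvent("a", 1, 2)], observer="o2", order_index=1)
        path = tmp_path / "dup.csv"
        write_observations([r1, r2], path)
        with pytest.raises(IntegrityError):
            read_observations(path)


class TestDistanceWindow:
    def test_full_window_keeps_everything(self):
        rec = make_record([DetectionEvent("a", t, t + 1) for t in (0, 50, 99)])
        out = split_distance_window(rec, (0, 50), 50.0)
        assert len(out.events) == 3
        assert out.window_m == (0, 50)

    def test_midpoint_maps_to_mid_distance(self):
        rec = make_record([DetectionEvent("a", 50.0, 51.0)], duration=100.0)
        out = split_distance_window(rec, (20, 30), 50.0)
        assert len(out.events) == 1  # d = 25

    def test_hand_evaluated_window(self):
        # mapped distances 2, 25 and 49 m on a 50 m transect; (5, 45) keeps 25
        rec = make_record([DetectionEvent("a", 4.0, 5.0),
                           DetectionEvent("b", 50.0, 51.0),
                           DetectionEvent("c", 98.0, 99.0)], duration=100.0)
        out = split_distance_window(rec, (5, 45), 50.0)
        assert [e.species_id for e in out.events] == ["b"]

    def test_bad_window_rejected(self):
        rec = make_record([])
        with pytest.raises(ValueError):
            split_distance_window(rec, (30, 30), 50.0)
        with pytest.raises(ValueError):
            split_distance_window(rec, (10, 60), 50.0)

    def test_nested_windows_monotone(self, small_study):
        records, _ = small_study
        species = sorted({e.species_id for r in records for e in r.events})
        prev = None
        for window in ((0, 50), (5, 45), (10, 40)):
            cm = build_community_matrix(records, "MaxCount", window=window,
                                        species=species)
            if prev is not None:
                assert (cm.counts.to_numpy() <= prev.counts.to_numpy()).all()
            prev = cm


class TestCountingMetrics:
    def test_max_count_sums_events(self):
        rec = make_record([DetectionEvent("a", 0, 1, 2), DetectionEvent("a", 5, 6, 3)])
        assert max_count(rec)["a"] == 5
        rec2 = make_record([DetectionEvent("a", 0, 1), DetectionEvent("b", 2, 3),
                            DetectionEvent("a", 4, 5)])
        out = max_count(rec2)
        assert out["a"] == 2 and out["b"] == 1

    def test_empty_record_all_zero(self):
        out = max_count(make_record([]), species=["a", "b"])
        assert (out == 0).all()

    def test_min_count_disjoint_and_overlapping(self):
        disjoint = make_record([DetectionEvent("a", 0, 1, 2), DetectionEvent("a", 5, 6, 3)])
        assert min_count(disjoint)["a"] == 3
        overlapping = make_record([DetectionEvent("a", 0, 10, 2), DetectionEvent("a", 0, 10, 3)])
        assert min_count(overlapping)["a"] == 5

    def test_min_count_sweep_line_example(self):
        rec = make_record([DetectionEvent("a", 0, 2), DetectionEvent("a", 1, 3),
                           DetectionEvent("a", 2.5, 4)])
        assert min_count(rec)["a"] == 2

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(0, 50), st.floats(0, 10), st.integers(1, 4)),
        min_size=1, max_size=8))
    def test_min_count_matches_dense_time_grid(self, raw):
        events = [DetectionEvent("a", t0, t0 + span, k) for t0, span, k in raw]
        rec = make_record(events)
        # oracle: evaluate simultaneous totals on a dense grid of candidate
        # instants (all interval endpoints)
        instants = sorted({e.t_start for e in events} | {e.t_end for e in events})
        brute = max(
            sum(e.n_individuals for e in events if e.t_start <= t <= e.t_end)
            for t in instants
        )
        assert min_count(rec)["a"] == brute

    def test_min_never_exceeds_max(self, small_study):
        records, _ = small_study
        species = sorted({e.species_id for r in records for e in r.events})
        for rec in records[:30]:
            assert (min_count(rec, species) <= max_count(rec, species)).all()


class TestTransforms:
    def test_elementwise_definitions(self, small_matrix):
        cm = small_matrix
        fr = transform_counts(cm, "fourth_root")
        assert np.allclose(fr.counts.to_numpy(), cm.counts.to_numpy() ** 0.25)
        lg = transform_counts(cm, "log1p")
        assert np.allclose(lg.counts.to_numpy(), np.log1p(cm.counts.to_numpy()))
        pa = transform_counts(cm, "presence_absence")
        assert set(np.unique(pa.counts.to_numpy())) <= {0.0, 1.0}

    @pytest.mark.parametrize("value,transform,expected", [
        (16, "fourth_root", 2.0), (0, "fourth_root", 0.0), (0, "log1p", 0.0),
        (0, "presence_absence", 0.0), (7, "presence_absence", 1.0),
    ])
    def test_scalar_examples(self, value, transform, expected, small_matrix):
        cm = small_matrix
        cm2 = cm.counts.copy()
        cm2.iloc[0, 0] = value
        from transect_varpart.core import CommunityMatrix
        out = transform_counts(
            CommunityMatrix(counts=cm2, row_meta=cm.row_meta), transform)
        assert out.counts.iloc[0, 0] == pytest.approx(expected)

    def test_unknown_transform_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            transform_counts(small_matrix, "sqrt")

    def test_presence_absence_commutes_with_monotone_transforms(self, small_matrix):
        pa_direct = transform_counts(small_matrix, "presence_absence")
        for tf in ("fourth_root", "log1p"):
            pa_after = transform_counts(transform_counts(small_matrix, tf),
                                        "presence_absence")
            assert pa_after.counts.equals(pa_direct.counts)


class TestDiversity:
    def test_two_equal_classes(self):
        assert species_density([10, 10]) == 2
        assert shannon_diversity([10, 10]) == pytest.approx(np.log(2))

    def test_single_class(self):
        assert species_density([5, 0, 0]) == 1
        assert shannon_diversity([5, 0, 0]) == 0.0

    def test_direct_formula(self):
        p = np.array([1, 2, 3]) / 6
        assert shannon_diversity([1, 2, 3]) == pytest.approx(-(p * np.log(p)).sum())
        assert shannon_diversity([1, 2, 3]) == pytest.approx(1.0114, abs=1e-4)

    def test_all_zero_row(self):
        assert species_density([0, 0]) == 0
        assert shannon_diversity([0, 0]) == 0.0

    def test_uniform_row_is_maximal(self, rng):
        for s in (3, 7):
            uniform = shannon_diversity([4] * s)
            assert uniform == pytest.approx(np.log(s))
            ragged = rng.integers(1, 20, size=s)
            assert shannon_diversity(ragged) <= uniform + 1e-12

    def test_base_conversion(self):
        assert shannon_diversity([10, 10], base=2) == pytest.approx(1.0)


class TestStudyDesign:
    def test_default_matches_study_layout(self):
        d = StudyDesign()
        assert (d.n_islands, d.locations_per_island, d.transects_per_location,
                d.n_observers, d.repeats_per_observer) == (2, 5, 3, 3, 6)
        assert d.n_observations == 540

    def test_positive_integers_required(self):
        with pytest.raises(ValueError):
            StudyDesign(n_islands=0)
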