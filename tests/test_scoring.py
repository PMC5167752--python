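import numpy as np
import pandas as pd
import pytest

from bna.errors import GeometryMismatchError
from bna.network import BnaModel, GroupStep, ModelConfig, NetworkEdge, MemberInfo
from bna.preprocess import GridGeometry
from bna.scoring import (
    FeatureTable,
    build_feature_table,
    connection_features,
    gfp,
    match_step,
    scale_features,
    topo_corr,
    topo_corr_steps,
    topo_cov,
)
from bna.segmentation import Peak

SHAPE = (8, 8, 20)


def _vox(*triples):
    return np.array(triples, dtype=np.int64)


class TestTopoCov:
    def test_two_voxel_toy(self):
        """s = {1, 3} (mean 2), g = {2, 6} (mean 4) on shared voxels:
        (1-2)(2-4) + (3-2)(6-4) = 4."""
        vox = _vox((1, 1, 1), (1, 1, 2))
        assert topo_cov(vox, np.array([1.0, 3.0]), vox,
                        np.array([2.0, 6.0]), SHAPE) == pytest.approx(4.0)

    def test_self_covariance_is_sum_of_squares(self):
        vox = _vox((0, 0, 0), (1, 2, 3), (4, 4, 4))
        amps = np.array([2.0, 5.0, -1.0])
        expected = np.sum((amps - amps.mean()) ** 2)
        assert topo_cov(vox, amps, vox, amps, SHAPE) == pytest.approx(expected)

    def test_disjoint_supports_zero(self):
        a = _vox((0, 0, 0), (0, 0, 1))
        b = _vox((5, 5, 5), (5, 5, 6))
        assert topo_cov(a, np.array([1.0, 2.0]), b, np.array([3.0, 4.0]),
                        SHAPE) == 0.0


class TestTopoCorr:
    def test_self_correlation_is_one(self, make_step):
        st = make_step([[2, 2, 5], [2, 3, 5], [3, 2, 6]], [6.0, 3.5, 3.2],
                       (2, 2, 5))
        assert topo_corr_steps(st, st, SHAPE) == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_anti_correlation_is_minus_one(self, make_step):
        st = make_step([[2, 2, 5], [2, 3, 5], [3, 2, 6]], [6.0, 3.5, 3.2],
                       (2, 2, 5))
        neg = make_step([[2, 2, 5], [2, 3, 5], [3, 2, 6]],
                        [-6.0, -3.5, -3.2], (2, 2, 5))
        assert topo_corr_steps(st, neg, SHAPE) == pytest.approx(-1.0,
                                                                abs=1e-12)

    def test_window_violation_scores_exactly_zero(self, make_step):
        st = make_step([[2, 2, 5], [2, 3, 5]], [6.0, 3.5], (2, 2, 5),
                       dt_ms=40.0)  # peak at 200 ms
        ref = make_step([[2, 2, 8], [2, 3, 8]], [6.0, 3.5], (2, 2, 8),
                        dt_ms=40.0)  # peak at 320 ms: 120 ms away
        assert topo_corr_steps(st, ref, SHAPE, temporal_window_ms=50.0,
                               spatial_window_px=4.0) == 0.0
        near = make_step([[2, 2, 5], [2, 3, 5], [2, 2, 6]],
                         [5.0, 3.5, 6.0], (2, 2, 6), dt_ms=40.0)  # 240 ms
        assert topo_corr_steps(st, near, SHAPE, temporal_window_ms=50.0,
                               spatial_window_px=4.0) != 0.0

    def test_bounded_and_symmetric_on_shared_support(self):
        rng = np.random.default_rng(0)
        vox = _vox(*[(i, j, 3) for i in range(3) for j in range(3)])
        for _ in range(25):
            a = rng.normal(size=9)
            b = rng.normal(size=9)
            r = topo_corr(vox, a, vox, b, SHAPE)
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            assert r == pytest.approx(topo_corr(vox, b, vox, a, SHAPE))

    def test_zero_variance_overlap_returns_zero(self):
        vox = _vox((1, 1, 1), (1, 1, 2))
        assert topo_corr(vox, np.array([2.0, 2.0]), vox,
                         np.array([1.0, 5.0]), SHAPE) == 0.0


class TestGfp:
    def test_constant_field(self):
        assert gfp(np.full(7, 2.0)) == pytest.approx(4.0)

    def test_direct_mean_square(self):
        assert gfp(np.array([3.0, 4.0])) == pytest.approx(12.5)

    def test_rms_mode(self):
        assert gfp(np.array([3.0, 4.0]), mode="rms") == pytest.approx(
            np.sqrt(12.5))

    def test_quadratic_homogeneity(self):
        amps = np.array([1.0, -2.0, 3.0])
        assert gfp(3.0 * amps) == pytest.approx(9.0 * gfp(amps))


def _group_step_from(st, step_id="g0"):
    return GroupStep(
        id=step_id, band=st.band, polarity=st.polarity, peak=st.peak,
        voxels=st.voxels.copy(), amplitudes=st.amplitudes.copy(),
        rise_time_ms=st.rise_time_ms,
        members={st.subject_id: MemberInfo(st.subject_id, st.peak,
                                           st.rise_time_ms)},
        coverage=1.0,
    )


class TestMatchStep:
    def test_identical_subject_matches_with_unit_score(self, make_step):
        st = make_step([[2, 2, 5], [2, 3, 5], [3, 2, 6]], [6.0, 3.5, 3.2],
                       (2, 2, 5))
        gs = _group_step_from(st)
        m = match_step([st], gs, SHAPE, 50.0, 4.0)
        assert m.subject_step is st
        assert m.topo_score == pytest.approx(1.0, abs=1e-12)
        assert m.gfp == pytest.approx(np.mean(np.array([6.0, 3.5, 3.2]) ** 2))

    def test_better_correlated_candidate_wins(self, make_step):
        gs = _group_step_from(make_step(
            [[2, 2, 5], [2, 3, 5], [3, 2, 5]], [6.0, 4.0, 2.0], (2, 2, 5)))
        # overlapping candidate with a matching amplitude gradient
        good = make_step([[2, 2, 5], [2, 3, 5], [3, 2, 5], [2, 2, 6]],
                         [6.2, 4.1, 2.2, 3.2], (2, 2, 5))
        # overlapping candidate with a scrambled gradient
        bad = make_step([[2, 2, 5], [2, 3, 5], [3, 2, 5]],
                        [6.0, 1.0, 5.9], (2, 2, 5))
        m = match_step([bad, good], gs, SHAPE, 50.0, 4.0)
        # brute-force oracle over the two candidates
        scores = {id(c): topo_corr_steps(c, gs, SHAPE) for c in (good, bad)}
        assert id(m.subject_step) == max(scores, key=scores.get)

    def test_no_candidate_within_windows(self, make_step):
        st = make_step([[7, 7, 18]], [6.0], (7, 7, 18))
        gs = _group_step_from(make_step([[1, 1, 2]], [6.0], (1, 1, 2)))
        m = match_step([st], gs, SHAPE, 50.0, 4.0)
        assert m.subject_step is None
        assert m.topo_score == 0.0 and m.gfp == 0.0

    def test_band_and_polarity_filtered(self, make_step):
        st = make_step([[2, 2, 5]], [-6.0], (2, 2, 5))  # negative
        gs = _group_step_from(make_step([[2, 2, 5]], [6.0], (2, 2, 5)))
        assert match_step([st], gs, SHAPE, 50.0, 4.0).subject_step is None


class TestConnectionFeatures:
    def _edge(self):
        return NetworkEdge(id="e0", step_a="a", step_b="b",
                           kind="peak_sync", delta_t_ms=20.0, coverage=1.0)

    def test_signed_differences(self, make_step):
        from bna.scoring import MatchResult

        sa = make_step([[2, 2, 10]], [6.0], (2, 2, 10))   # 100 ms
        sb = make_step([[4, 4, 12]], [6.0], (4, 4, 12))   # 120 ms
        matches = {
            "a": MatchResult("a", sa, 1.0, 1.0),
            "b": MatchResult("b", sb, 1.0, 1.0),
        }
        feats = connection_features(matches, [self._edge()])
        dt_peak, dt_rise = feats["e0"]
        assert dt_peak == pytest.approx(20.0)
        assert dt_rise == pytest.approx(sb.rise_time_ms - sa.rise_time_ms)

    def test_unmatched_endpoint_zeroed(self, make_step):
        from bna.scoring import MatchResult

        sa = make_step([[2, 2, 10]], [6.0], (2, 2, 10))
        matches = {"a": MatchResult("a", sa, 1.0, 1.0),
                   "b": MatchResult("b", None, 0.0, 0.0)}
        assert connection_features(matches, [self._edge()])["e0"] == (0.0,
                                                                      0.0)


def _toy_model(make_step, condition, n_steps=3, with_edge=True):
    times = 10.0 * np.arange(SHAPE[2])
    geom = GridGeometry(n_lr=SHAPE[0], n_ap=SHAPE[1],
                        mask=np.ones(SHAPE[:2], dtype=bool))
    group_steps = []
    for k in range(n_steps):
        st = make_step([[2 + k, 2, 5 + 3 * k], [2 + k, 3, 5 + 3 * k]],
                       [6.0, 3.5], (2 + k, 2, 5 + 3 * k))
        group_steps.append(_group_step_from(st, step_id=f"s{k:02d}"))
    edges = []
    if with_edge and n_steps >= 2:
        edges.append(NetworkEdge(id="e00", step_a="s00", step_b="s01",
                                 kind="peak_sync", delta_t_ms=30.0,
                                 coverage=1.0))
    return BnaModel(condition=condition, bands=["theta"], geometry=geom,
                    times_ms=times, group_steps=group_steps, edges=edges,
                    config=ModelConfig(), n_subjects=1)


class TestFeatureTable:
    def test_column_count_three_steps_one_edge_two_networks(self, make_step):
        models = {"Target": _toy_model(make_step, "Target"),
                  "Novel": _toy_model(make_step, "Novel")}
        sets = {("s0", "V1", "Target"): [], ("s0", "V1", "Novel"): []}
        table = build_feature_table(sets, models)
        assert table.values.shape == (2, 16)  # 2 x (3*2 + 1*2)

    def test_template_subject_scores_unit_topo(self, make_step):
        model = _toy_model(make_step, "Target")
        subject_steps = [
            make_step([[2 + k, 2, 5 + 3 * k], [2 + k, 3, 5 + 3 * k]],
                      [6.0, 3.5], (2 + k, 2, 5 + 3 * k))
            for k in range(3)
        ]
        table = build_feature_table({("s0", "V1", "Target"): subject_steps},
                                    {"Target": model})
        topo_cols = [c for c in table.values.columns if c.endswith("/topo")]
        assert np.allclose(table.values.iloc[0][topo_cols], 1.0, atol=1e-12)
        # the subject's dt equals the model's group delta-t
        assert table.values.iloc[0]["Target/e00/dt_peak"] == pytest.approx(
            30.0)

    def test_row_permutation_only_permutes_rows(self, make_step):
        model = _toy_model(make_step, "Target")
        mk = lambda sid: [make_step([[2, 2, 5], [2, 3, 5]], [6.0, 3.5],
                                    (2, 2, 5), subject_id=sid)]
        sets = {(s, "V1", "Target"): mk(s) for s in ("a", "b", "c")}
        t1 = build_feature_table(sets, {"Target": model})
        t2 = build_feature_table(dict(reversed(list(sets.items()))),
                                 {"Target": model})
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_mean_imputation_for_unmatched(self, make_step):
        model = _toy_model(make_step, "Target", n_steps=1, with_edge=False)
        matched = [make_step([[2, 2, 5], [2, 3, 5]], [6.0, 3.5], (2, 2, 5),
                             subject_id=s) for s in ("a", "b")]
        sets = {("a", "V1", "Target"): [matched[0]],
                ("b", "V1", "Target"): [matched[1]],
                ("c", "V1", "Target"): []}  # subject c matches nothing
        zeroed = build_feature_table(sets, {"Target": model})
        imputed = build_feature_table(sets, {"Target": model},
                                      unmatched="mean")
        gcol = "Target/s00/gfp"
        assert zeroed.values.loc["c|V1|Target", gcol] == 0.0
        assert imputed.values.loc["c|V1|Target", gcol] == pytest.approx(
            zeroed.values.loc[["a|V1|Target", "b|V1|Target"], gcol].mean())

    def test_geometry_mismatch_rejected(self, make_step):
        model = _toy_model(make_step, "Target")
        st = make_step([[2, 2, 5]], [6.0], (2, 2, 5), shape=(9, 9, 20))
        with pytest.raises(GeometryMismatchError):
            build_feature_table({("s0", "V1", "Target"): [st]},
                                {"Target": model})


class TestScaling:
    def _table(self, cols):
        idx = [f"s{i}|V1|Target" for i in range(len(next(iter(cols.values()))))]
        values = pd.DataFrame(cols, index=idx, dtype=float)
        meta = pd.DataFrame({"subject": [i.split("|")[0] for i in idx],
                             "visit": "V1", "condition": "Target"}, index=idx)
        return FeatureTable(values=values, meta=meta)

    def test_population_sd_scaling(self):
        t = self._table({"f": [1.0, 2.0, 3.0]})
        s = scale_features(t, list(t.values.index))
        np.testing.assert_allclose(
            s.values["f"], [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(1)
        t = self._table({f"f{k}": rng.normal(5, 3, size=12)
                         for k in range(4)})
        train = list(t.values.index)[:8]
        s = scale_features(t, train)
        tr = s.values.loc[train]
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_column_zeroed_and_flagged(self):
        t = self._table({"f": [1.0, 2.0, 3.0], "const": [4.0, 4.0, 4.0]})
        s = scale_features(t, list(t.values.index))
        assert (s.values["const"] == 0.0).all()
        assert bool(s.scaling.loc["const", "constant"]) is True
        assert bool(s.scaling.loc["f", "constant"]) is False

    def test_test_rows_use_training_statistics(self):
        t = self._table({"f": [0.0, 2.0, 100.0]})
        s = scale_features(t, list(t.values.index)[:2])  # mean 1, sd 1
        assert s.values["f"].iloc[2] == pytest.approx(99.0)
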