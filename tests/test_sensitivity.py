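import numpy as np
import pandas as pd
import pytest

from ofvplan.sensitivity import (METRIC_COLUMNS, SCORED_METRICS, MetricTrace,
                                 SensitivityConfig, analyze_trace,
                                 change_rates, criticality_masks,
                                 derive_tuning_points, run_schedule,
                                 sensitivity_score, smooth_trace)


def _trace(columns: dict) -> MetricTrace:
    n = len(next(iter(columns.values())))
    data = {"step": np.arange(1, n + 1)}
    for col in METRIC_COLUMNS:
        data[col] = np.asarray(columns.get(col, np.zeros(n)), dtype=float)
    return MetricTrace(pd.DataFrame(data), "lung_ipsi",
                       tuple([float("nan")] + [1.0] * (n - 1)))


class TestSmoothTrace:
    def test_constant_series_unchanged(self):
        tr = _trace({"oar_mean_gy": [4.0] * 5})
        sm = smooth_trace(tr, 3)
        np.testing.assert_allclose(sm.data["oar_mean_gy"], 4.0)

    def test_three_point_average_interior_and_truncated_edges(self):
        tr = _trace({"oar_mean_gy": [0.0, 3.0, 0.0]})
        sm = smooth_trace(tr, 3)
        np.testing.assert_allclose(sm.data["oar_mean_gy"], [1.5, 1.0, 1.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(_trace({"oar_mean_gy": [1, 2, 3]}), 2)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(_trace({"oar_mean_gy": [1, 2]}), 5)


class TestChangeRates:
    def test_forward_differences(self):
        r = change_rates(_trace({"oar_mean_gy": [1.0, 3.0, 6.0]}))
        np.testing.assert_allclose(r["oar_mean_gy"], [2.0, 3.0])
        assert list(r["step"]) == [1, 2]

    def test_constant_metric_gives_zero_rates(self):
        r = change_rates(_trace({"external_max_gy": [5.0] * 4}))
        np.testing.assert_allclose(r["external_max_gy"], 0.0)

    def test_linear_series_has_constant_rates(self):
        r = change_rates(_trace({"ptv95vol_gy": [47.0, 46.0, 45.0, 44.0]}))
        np.testing.assert_allclose(r["ptv95vol_gy"], -1.0)

    def test_single_step_trace_rejected(self):
        with pytest.raises(ValueError):
            change_rates(_trace({"oar_mean_gy": [1.0]}))


class TestCriticalityMasks:
    def test_covered_target_never_critical(self):
        tr = _trace({"ptv95vol_gy": [48.0] * 5})
        masks = criticality_masks(tr, change_rates(tr))
        assert not masks["ptv95vol_gy"].any()

    def test_hot_external_step_flagged(self):
        tr = _trace({"external_max_gy": [50.0, 53.0, 50.0, 50.0]})
        masks = criticality_masks(tr, change_rates(tr))
        assert list(masks["external_max_gy"]) == [False, True, False]

    def test_stalling_organ_dose_flagged_below_median(self):
        """|Delta| series [1, 2, 3]: only the entry under the median counts."""
        tr = _trace({"oar_mean_gy": [10.0, 9.0, 7.0, 4.0]})
        masks = criticality_masks(tr, change_rates(tr))
        assert list(masks["oar_mean_gy"]) == [True, False, False]


class TestSensitivityScore:
    def test_all_false_masks_warn_and_zero(self):
        tr = _trace({"oar_mean_gy": [5.0, 4.0, 3.0]})
        rates = change_rates(tr)
        masks = criticality_masks(tr, rates)
        for col in SCORED_METRICS:
            masks[col] = False
        with pytest.warns(UserWarning):
            res = sensitivity_score(rates, masks, tr)
        assert (res.scores == 0).all()
        assert res.jstar == 1

    def test_single_gated_metric(self):
        tr = _trace({"external_max_gy": [50.0, 50.0, 53.5, 50.0]})
        rates = change_rates(tr)
        masks = criticality_masks(tr, rates)
        res = sensitivity_score(rates, masks, tr)
        # only step 3 exceeds 52.5, contributing |50 - 53.5| = 3.5
        assert res.scores.loc[3] == pytest.approx(3.5)
        assert res.jstar == 3

    def test_matches_brute_force_oracle_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            tr = _trace({c: rng.uniform(0, 60, n) for c in METRIC_COLUMNS})
            rates = change_rates(tr)
            masks = criticality_masks(tr, rates)
            res = sensitivity_score(rates, masks, tr)
            # independent recomputation: loop over metrics and steps
            expected = np.zeros(n - 1)
            for j in range(n - 1):
                for col in SCORED_METRICS:
                    if bool(masks[col].iloc[j]):
                        expected[j] += abs(float(rates[col].iloc[j]))
            np.testing.assert_allclose(res.scores.to_numpy(), expected)
            assert res.jstar == int(np.argmax(expected)) + 1

    def test_score_invariant_to_metric_ordering(self):
        rng = np.random.default_rng(7)
        tr = _trace({c: rng.uniform(0, 60, 6) for c in METRIC_COLUMNS})
        rates = change_rates(tr)
        masks = criticality_masks(tr, rates)
        base = sensitivity_score(rates, masks, tr).scores
        perm = sensitivity_score(rates[rates.columns[::-1]],
                                 masks[masks.columns[::-1]], tr).scores
        np.testing.assert_allclose(base.to_numpy(), perm.to_numpy())

    def test_argmax_tie_breaks_to_earliest_step(self):
        tr = _trace({"external_max_gy": [53.0, 55.0, 53.0, 55.0, 53.0]})
        rates = change_rates(tr)
        masks = criticality_masks(tr, rates)
        res = sensitivity_score(rates, masks, tr)
        assert res.jstar == 1  # equal |Delta| at every step


@pytest.fixture(scope="module")
def schedule(small_phantom, small_beamset, small_influence):
    cfg = SensitivityConfig(n_steps=6)
    return cfg, run_schedule(small_phantom, small_beamset, cfg,
                             influence=small_influence)


class TestRunSchedule:

    def test_first_step_has_no_oar_objective(self, schedule):
        _, trace = schedule
        assert np.isnan(trace.limits_gy[0])
        assert trace.data["oar_ofv"].iloc[0] == 0.0

    def test_limits_follow_geometric_schedule(self, schedule):
        _, trace = schedule
        limits = trace.limits_gy
        assert limits[2] == pytest.approx(0.5 * limits[1])
        for k in range(3, len(limits)):
            assert limits[k] == pytest.approx(0.8 * limits[k - 1])

    def test_all_metrics_recorded_per_step(self, schedule):
        cfg, trace = schedule
        assert len(trace) == cfg.n_steps
        for col in METRIC_COLUMNS:
            assert np.isfinite(trace.data[col]).all()

    def test_short_schedule_rejected(self):
        with pytest.raises(ValueError):
            SensitivityConfig(n_steps=3)

    def test_analyze_trace_returns_valid_tuning_point(self, schedule):
        cfg, trace = schedule
        res = analyze_trace(trace, cfg)
        assert 1 <= res.jstar <= len(trace) - 1
        assert np.isfinite(res.ofv_at_jstar) and res.ofv_at_jstar >= 0


class TestDeriveTuningPoints:
    def test_single_phantom_mean_equals_its_value(self, small_phantom,
                                                  small_beamset):
        cfg = SensitivityConfig(n_steps=5)
        out = derive_tuning_points([small_phantom], [small_beamset], cfg)
        table = out["per_phantom"]
        assert len(table) == 2  # one class-2 and one class-1 run
        c2 = table[table["class"] == "class2"]["tuning_ofv"].iloc[0]
        assert out["class2_mean_ofv"] == pytest.approx(float(c2))
        assert np.isfinite(out["class1_mean_ofv"])

    def test_empty_phantom_list_rejected(self):
        with pytest.raises(ValueError):
            derive_tuning_points([], [], SensitivityConfig())


def test_smooth_then_difference_commutes_on_linear_series():
    """For a linear metric both operation orders give the exact slope inside."""
    tr = _trace({"oar_mean_gy": np.linspace(10, 4, 7)})
    smooth_then_diff = change_rates(smooth_trace(tr, 3))["oar_mean_gy"].to_numpy()
    diff_then_smooth = (pd.Series(change_rates(tr)["oar_mean_gy"].to_numpy())
                        .rolling(3, center=True, min_periods=1).mean()
                        .to_numpy())
    np.testing.assert_allclose(smooth_then_diff[1:-1], -1.0)
    np.testing.assert_allclose(diff_then_smooth[1:-1], -1.0)
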