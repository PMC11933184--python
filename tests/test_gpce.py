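import numpy as np
import pandas as pd
import pytest

from graftflow.distributions import ParameterDistribution
from graftflow.gpce import (
    UQ_PARAMETER_NAMES,
    apply_uq_sample,
    default_uq_distributions,
    filter_unphysical,
    fit_pce,
    required_sample_count,
    run_uq_stage,
    sample_inputs,
    select_order_by_cv,
    sobol_from_pce,
    sobol_main_pick_freeze,
)


def _unit_dists(k):
    return [ParameterDistribution.uniform(f"x{i}", -1.0, 1.0) for i in range(k)]


class TestSampleCounts:
    @pytest.mark.parametrize(
        "d,order,factor,expected",
        [(9, 2, 2, 110), (9, 1, 2, 20), (1, 0, 1, 1), (9, 2, 1, 55)],
    )
    def test_collocation_arithmetic(self, d, order, factor, expected):
        assert required_sample_count(d, order, factor) == expected


class TestSampling:
    def test_nine_default_marginals_with_uniform_stenosis(self):
        dists = default_uq_distributions()
        assert len(dists) == 9
        assert [d.name for d in dists] == list(UQ_PARAMETER_NAMES)
        assert dists[0].family == "uniform" and dists[0].upper == 75.0
        for d in dists[1:]:
            assert d.family == "truncnorm"
            assert d.upper == pytest.approx(d.mean + 1.96 * d.sd)

    def test_all_samples_inside_truncation_bounds(self):
        dists = default_uq_distributions()
        X = sample_inputs(dists, 500, seed=1)
        assert X.shape == (500, 9)
        for j, d in enumerate(dists):
            assert X[:, j].min() >= d.lower and X[:, j].max() <= d.upper

    def test_same_seed_same_matrix(self):
        dists = default_uq_distributions()
        assert np.array_equal(sample_inputs(dists, 50, seed=5), sample_inputs(dists, 50, seed=5))

    def test_area_scale_maps_to_inverse_square_resistance(self):
        base_R = apply_uq_sample({"graft_area_scale": 1.0}).R_graft
        halved = apply_uq_sample({"graft_area_scale": 0.5})
        assert halved.R_graft == pytest.approx(4.0 * base_R)
        assert halved.stenosis_D0 == pytest.approx(
            apply_uq_sample({"graft_area_scale": 1.0}).stenosis_D0 * np.sqrt(0.5)
        )


class _FakeRun:
    """Minimal stand-in (synthetic) for a simulation result in filter tests."""

    def __init__(self, peak_in_diastole: bool):
        T = 0.8
        self.t = np.linspace(0, 2 * T, 3201)
        opens = np.array([0.05, T + 0.05])
        closes = np.array([0.35, T + 0.35])
        self.events = {"aortic_valve_open": opens, "aortic_valve_close": closes}
        # last complete beat is [0.05, 0.85]; systole ends at 0.35
        t_peak = 0.6 if peak_in_diastole else 0.2
        p = 80 + 40 * np.exp(-((self.t - t_peak) ** 2) / 0.005)
        self.signals = {"aortic_pressure": p}


class TestFiltering:
    def test_systolic_peak_kept_diastolic_peak_removed(self):
        runs = [_FakeRun(False), _FakeRun(True), _FakeRun(False)]
        kept, report = filter_unphysical(runs)
        assert kept == [0, 2]
        assert report["removed_ids"] == [1]
        assert report["fraction_removed"] == pytest.approx(1 / 3)

    def test_planted_fraction_recovered(self, rng):
        flags = rng.random(40) < 0.25
        runs = [_FakeRun(bool(f)) for f in flags]
        kept, report = filter_unphysical(runs)
        assert report["fraction_removed"] == pytest.approx(flags.mean())

    def test_idempotent(self):
        runs = [_FakeRun(False), _FakeRun(True), _FakeRun(False), _FakeRun(False)]
        kept, _ = filter_unphysical(runs)
        kept2, report2 = filter_unphysical([runs[i] for i in kept])
        assert kept2 == list(range(len(kept)))
        assert report2["removed_ids"] == []


class TestFit:
    def test_recovers_generating_order2_polynomial(self, rng):
        dists = _unit_dists(3)
        X = sample_inputs(dists, 60, seed=2)
        y = 1.0 + 2.0 * X[:, 0] + 0.5 * X[:, 1] * X[:, 2] - X[:, 2] ** 2
        model = fit_pce(X, y, order=2, dists=dists)
        pred = model.predict(sample_inputs(dists, 200, seed=3))
        Xt = sample_inputs(dists, 200, seed=3)
        truth = 1.0 + 2.0 * Xt[:, 0] + 0.5 * Xt[:, 1] * Xt[:, 2] - Xt[:, 2] ** 2
        assert np.max(np.abs(pred[:, 0] - truth)) < 1e-8

    def test_constant_response_keeps_only_the_constant_term(self):
        dists = _unit_dists(2)
        X = sample_inputs(dists, 30, seed=4)
        model = fit_pce(X, np.full(30, 7.0), order=2, dists=dists)
        assert model.coeffs[0, 0] == pytest.approx(7.0)
        assert np.max(np.abs(model.coeffs[1:])) < 1e-10

    def test_duplicate_sample_rows_leave_fit_unchanged(self):
        dists = _unit_dists(2)
        X = sample_inputs(dists, 25, seed=5)
        y = 3.0 * X[:, 0] - X[:, 1]
        a = fit_pce(X, y, 1, dists)
        Xd = np.vstack([X, X])
        b = fit_pce(Xd, np.concatenate([y, y]), 1, dists)
        assert np.allclose(a.coeffs, b.coeffs, atol=1e-10)

    def test_underdetermined_system_rejected(self):
        dists = _unit_dists(4)
        X = sample_inputs(dists, 10, seed=6)
        with pytest.raises(ValueError, match="samples"):
            fit_pce(X, np.ones(10), order=2, dists=dists)


class TestOrderSelection:
    def test_planted_linear_truth_selects_order_1(self, rng):
        dists = _unit_dists(3)
        X = sample_inputs(dists, 80, seed=7)
        y = 2.0 * X[:, 0] - X[:, 1] + rng.normal(0, 0.02, 80)
        order, table = select_order_by_cv(X, y, dists, max_order=2, k=10, seed=0)
        assert order == 1
        assert set(table.index) == {1, 2}

    def test_planted_quadratic_truth_selects_order_2(self):
        dists = _unit_dists(3)
        X = sample_inputs(dists, 80, seed=8)
        y = 3.0 * X[:, 0] ** 2 + X[:, 1] * X[:, 2]
        order, _ = select_order_by_cv(X, y, dists, max_order=2, k=10, seed=0)
        assert order == 2

    def test_tie_breaks_to_the_lower_order(self):
        dists = _unit_dists(2)
        X = sample_inputs(dists, 40, seed=9)
        y = np.zeros(40)  # every order fits exactly: identical CV error
        order, _ = select_order_by_cv(X, y, dists, max_order=2, k=5, seed=0)
        assert order == 1

    def test_too_many_folds_rejected(self):
        dists = _unit_dists(2)
        X = sample_inputs(dists, 8, seed=10)
        with pytest.raises(ValueError):
            select_order_by_cv(X, np.ones(8), dists, k=10)


class TestSobol:
    def test_single_active_variable(self):
        dists = _unit_dists(3)
        X = sample_inputs(dists, 50, seed=11)
        model = fit_pce(X, X[:, 1], order=1, dists=dists)
        s = sobol_from_pce(model)
        assert s.main.iloc[1, 0] == pytest.approx(1.0, abs=1e-10)
        assert s.main.iloc[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert s.total.equals(s.main)  # order 1: identical by construction

    def test_additive_function_matches_analytic_variance_shares(self):
        a, b = 3.0, 1.0
        dists = _unit_dists(2)
        X = sample_inputs(dists, 60, seed=12)
        model = fit_pce(X, a * X[:, 0] + b * X[:, 1], order=1, dists=dists)
        s = sobol_from_pce(model)
        assert s.main.iloc[0, 0] == pytest.approx(a**2 / (a**2 + b**2), abs=1e-8)
        assert s.main.iloc[1, 0] == pytest.approx(b**2 / (a**2 + b**2), abs=1e-8)

    def test_interaction_counted_in_total_not_main(self):
        dists = _unit_dists(2)
        X = sample_inputs(dists, 60, seed=13)
        model = fit_pce(X, X[:, 0] * X[:, 1], order=2, dists=dists)
        s = sobol_from_pce(model)
        assert s.main.iloc[0, 0] == pytest.approx(0.0, abs=1e-8)
        assert s.total.iloc[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_pick_freeze_cross_check_agrees_with_spectral_indices(self):
        dists = _unit_dists(3)
        X = sample_inputs(dists, 100, seed=14)
        y = 2.0 * X[:, 0] + X[:, 1] + 0.3 * X[:, 2]
        model = fit_pce(X, y, order=1, dists=dists)
        spectral = sobol_from_pce(model).main
        mc = sobol_main_pick_freeze(model, n=40000, seed=0)
        assert np.max(np.abs(spectral.to_numpy() - mc.to_numpy())) < 0.02

    def test_zero_variance_rejected(self):
        dists = _unit_dists(2)
        X = sample_inputs(dists, 30, seed=15)
        model = fit_pce(X, np.full(30, 2.0), order=1, dists=dists)
        with pytest.raises(ValueError, match="variance"):
            sobol_from_pce(model)


class TestUqStage:
    def test_surrogate_runner_ranks_planted_dominant_parameter_first(self):
        """A synthetic response dominated by R0_SVB must top the ranking."""

        def runner(values):
            run = _FakeRun(False)
            x = values["R0_SVB"]
            run._metrics = {
                "q_mean": 50 + 40 * x, "pi": 2 + 0.1 * x,
                "ds_ratio": 3 + x, "df_pct": 75.0, "dri": 0.6 + 0.2 * x,
            }
            return run

        import graftflow.gpce as gpce

        orig = gpce.metrics_from_simulation
        gpce.metrics_from_simulation = lambda r: type(
            "M", (), {"median": r._metrics}
        )()
        try:
            rep = run_uq_stage(n=40, seed=3, max_order=1, runner=runner)
        finally:
            gpce.metrics_from_simulation = orig
        for metric in ("q_mean", "ds_ratio", "dri"):
            assert rep.most_influential(metric) == "R0_SVB"

    def test_same_seed_reproduces_report(self):
        rep1 = run_uq_stage(n=25, seed=4, max_order=1, n_beats=6)
        rep2 = run_uq_stage(n=25, seed=4, max_order=1, n_beats=6)
        pd.testing.assert_frame_equal(rep1.sobol.total, rep2.sobol.total)
        assert rep1.kept == rep2.kept
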