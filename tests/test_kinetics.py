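"""Induction-ODE closed form, numerical cross-check, and RMSD fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from galinduce.kinetics import (
    KineticFit,
    KineticParams,
    TimeCourse,
    fit_kinetics,
    half_steady_state_time,
    half_steady_state_time_numeric,
    predict_mrna,
    predict_mrna_numeric,
    rmsd_timecourse,
    steady_state_level,
)

params_strategy = st.builds(
    KineticParams,
    onset_time=st.floats(0.0, 10.0),
    production_rate=st.floats(0.01, 5.0),
    degradation_rate=st.floats(0.05, 3.0),
)


class TestClosedForm:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            (KineticParams(0, 2, 1), 0.0, 0.0),  # M(0)=0 by construction
            (KineticParams(5, 3, 0.5), 4.0, 0.0),  # pre-onset
            (KineticParams(0, 2, 1), math.log(2), 1.0),  # (alpha/delta)(1-e^-delta t)
        ],
    )
    def test_point_values(self, params, t, expected):
        assert predict_mrna(params, t) == pytest.approx(expected, abs=1e-12)

    def test_zero_degradation_is_linear_accumulation(self):
        p = KineticParams(2.0, 1.5, 0.0)
        assert predict_mrna(p, 6.0) == pytest.approx(1.5 * 4.0)
        assert predict_mrna(p, 1.0) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(params=params_strategy, t1=st.floats(0, 30), t2=st.floats(0, 30))
    def test_monotone_nondecreasing_and_bounded(self, params, t1, t2):
        lo, hi = sorted((t1, t2))
        m_lo, m_hi = predict_mrna(params, lo), predict_mrna(params, hi)
        assert m_lo <= m_hi + 1e-12
        assert m_hi <= steady_state_level(params) + 1e-12

    @settings(max_examples=25, deadline=None)
    @given(params=params_strategy)
    def test_converges_to_steady_state(self, params):
        t_far = params.onset_time + 20.0 / params.degradation_rate
        ss = steady_state_level(params)
        assert predict_mrna(params, t_far) == pytest.approx(ss, rel=1e-6)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-1.0, 1.0, 1.0)


class TestNumericSolution:
    def test_no_production_stays_zero(self):
        grid = np.linspace(0, 10, 11)
        assert np.all(predict_mrna_numeric(KineticParams(0, 0, 1), grid) == 0)

    def test_pre_onset_grid_points_zero(self):
        grid = np.arange(0.0, 14.1, 2.0)
        out = predict_mrna_numeric(KineticParams(3, 1, 0.2), grid)
        assert np.all(out[grid <= 3.0] == 0.0)

    @pytest.mark.parametrize(
        "params",
        [
            KineticParams(0, 2, 1),
            KineticParams(3, 1, 0.2),
            KineticParams(3.4, 0.3, 0.33),
            KineticParams(204.8, 0.02115, 0.0235),
        ],
    )
    def test_agrees_with_closed_form(self, params):
        grid = np.linspace(0.0, params.onset_time + 10.0 / max(params.degradation_rate, 0.1), 101)
        numeric = predict_mrna_numeric(params, grid)
        closed = predict_mrna(params, grid)
        assert np.max(np.abs(numeric - closed)) < 1e-8

    def test_rejects_nonincreasing_grid(self):
        with pytest.raises(ValueError):
            predict_mrna_numeric(KineticParams(0, 1, 1), np.array([0.0, 2.0, 1.0]))


class TestSteadyStateAndHalfTime:
    @pytest.mark.parametrize(
        "alpha, delta, expected",
        [(2.0, 1.0, 2.0), (0.0, 0.3, 0.0), (0.45, 0.5, 0.9)],
    )
    def test_steady_state_ratio(self, alpha, delta, expected):
        assert steady_state_level(KineticParams(0, alpha, delta)) == pytest.approx(expected)

    def test_steady_state_requires_degradation(self):
        with pytest.raises(ValueError):
            steady_state_level(KineticParams(0, 1, 0))

    @pytest.mark.parametrize(
        "params, expected",
        [
            (KineticParams(0, 1, 1), math.log(2)),
            (KineticParams(3, 1, math.log(2)), 4.0),
        ],
    )
    def test_half_time_analytic(self, params, expected):
        assert half_steady_state_time(params) == pytest.approx(expected, abs=1e-12)

    def test_half_time_root_finder_agrees(self):
        # bulk-fit scale: onset ~205 min, slow decay
        p = KineticParams(204.8, 0.9 * 0.0235, 0.0235)
        assert abs(half_steady_state_time_numeric(p) - half_steady_state_time(p)) < 1e-6

    @settings(max_examples=25, deadline=None)
    @given(params=params_strategy)
    def test_half_time_hits_half_steady_state(self, params):
        t_half = half_steady_state_time(params)
        target = 0.5 * steady_state_level(params)
        assert predict_mrna(params, t_half) == pytest.approx(target, rel=1e-6)

    def test_half_time_undefined_without_production(self):
        with pytest.raises(ValueError):
            half_steady_state_time(KineticParams(0, 0, 1))


class TestRmsd:
    def test_identical_series_zero(self):
        assert rmsd_timecourse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        a = np.array([0.0, 1.0, 2.0])
        assert rmsd_timecourse(a + 0.7, a) == pytest.approx(0.7)

    def test_hand_computed_value(self):
        assert rmsd_timecourse([0, 1, 2], [0, 0, 0]) == pytest.approx(math.sqrt(5 / 3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmsd_timecourse([1.0, 2.0], [1.0])


class TestFitKinetics:
    def test_noiseless_recovery_within_1pct(self, noiseless_timecourse, wt_kinetics):
        fit = fit_kinetics(noiseless_timecourse, n_starts=50, seed=1)
        for got, want in zip(fit.params.as_tuple(), wt_kinetics.as_tuple()):
            assert abs(got - want) / want < 0.01

    def test_all_zero_course_gives_zero_production(self, hourly_grid):
        tc = TimeCourse(hourly_grid, np.zeros((3, hourly_grid.size)))
        with pytest.warns(UserWarning):
            fit = fit_kinetics(tc, n_starts=5, seed=0)
        assert fit.params.production_rate <= 1e-6

    def test_fixed_onset_recovery(self, hourly_grid):
        truth = KineticParams(0.0, 1.0, 0.5)
        tc = TimeCourse(hourly_grid, predict_mrna(truth, hourly_grid)[None, :])
        fit = fit_kinetics(tc, fix_onset_zero=True, n_starts=50, seed=2)
        assert fit.params.onset_time == 0.0
        assert abs(fit.params.production_rate - 1.0) < 0.01
        assert abs(fit.params.degradation_rate - 0.5) < 0.005

    def test_deterministic_given_seed(self, noiseless_timecourse):
        f1 = fit_kinetics(noiseless_timecourse, n_starts=8, seed=11)
        f2 = fit_kinetics(noiseless_timecourse, n_starts=8, seed=11)
        assert f1.params.as_tuple() == f2.params.as_tuple()
        assert f1.rmsd == f2.rmsd

    def test_more_starts_never_worse(self, wt_kinetics, hourly_grid):
        rng = np.random.default_rng(3)
        vals = predict_mrna(wt_kinetics, hourly_grid)[None, :] * (
            1 + rng.normal(0, 0.05, size=(1, hourly_grid.size))
        )
        tc = TimeCourse(hourly_grid, np.clip(vals, 0, None))
        rmsds = [fit_kinetics(tc, n_starts=n, seed=5).rmsd for n in (2, 5, 10)]
        assert rmsds[0] >= rmsds[1] - 1e-12
        assert rmsds[1] >= rmsds[2] - 1e-12

    def test_noisy_recovery_median_under_10pct(self, hourly_grid):
        # 20 seeded parameter sets, 1% multiplicative noise
        rng = np.random.default_rng(42)
        errors = []
        for i in range(20):
            x = rng.uniform(1.0, 6.0)
            delta = rng.uniform(0.1, 1.0)
            alpha = rng.uniform(0.1, 1.0) * delta
            truth = KineticParams(x, alpha, delta)
            clean = predict_mrna(truth, hourly_grid)
            vals = np.clip(
                clean[None, :] * (1 + rng.normal(0, 0.01, size=(3, hourly_grid.size))), 0, None
            )
            fit = fit_kinetics(TimeCourse(hourly_grid, vals), n_starts=30, seed=100 + i)
            errors.append(
                [abs(g - w) / w for g, w in zip(fit.params.as_tuple(), truth.as_tuple())]
            )
        med = np.median(np.array(errors), axis=0)
        assert np.all(med < 0.10)

    def test_per_replicate_mode_returns_one_fit_each(self, noiseless_timecourse):
        fits = fit_kinetics(noiseless_timecourse, n_starts=5, seed=0, per_replicate=True)
        assert len(fits) == noiseless_timecourse.n_replicates
        assert all(isinstance(f, KineticFit) for f in fits)

    def test_too_few_points_rejected(self):
        tc = TimeCourse(np.array([0.0, 2.0, 4.0]), np.ones((1, 3)))
        with pytest.raises(ValueError):
            fit_kinetics(tc)


class TestTimeCourse:
    def test_unit_conversion_roundtrip(self, noiseless_timecourse):
        minutes = noiseless_timecourse.to_unit("minutes")
        assert minutes.times[1] == pytest.approx(120.0)
        back = minutes.to_unit("hours")
        assert np.allclose(back.times, noiseless_timecourse.times)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            TimeCourse(np.array([0.0, 0.0, 1.0]), np.ones((1, 3)))
        with pytest.raises(ValueError):
            TimeCourse(np.array([0.0, 1.0]), np.ones((1, 3)))
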