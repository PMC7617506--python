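"""Deterministic kinetics: closed form vs ODE oracle, derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teatk.kinetics import (
    SubjectDesign,
    TKParams,
    auc_inf,
    derive,
    observe,
    simulate_analytic,
    simulate_ode,
)
from conftest import random_params

GRID = np.linspace(0.0, 48.0, 97)


class TestDerive:
    def test_half_life_matches_clearance_volume_ratio(self, pop_params):
        d = derive(pop_params)
        # ln2 * 4.35 / 1.58 rounds to the reported 1.9 h
        assert round(d.t_half, 1) == 1.9
        assert d.t_half * d.k_el == pytest.approx(np.log(2.0))

    def test_mean_absorption_time(self, pop_params):
        assert round(derive(pop_params).mat, 3) == 0.042

    def test_unit_case(self):
        p = TKParams(cl_tot=1, vd=1, vd_met=1, cl_met=1, k_gutabs=2,
                     k_ufrac=0.5, f_gluc=0.5)
        d = derive(p)
        assert d.k_el == 1.0
        assert d.t_half == pytest.approx(np.log(2.0))
        assert d.k_u + d.k_met == pytest.approx(d.k_el)
        assert d.f_met == pytest.approx(0.25)

    def test_tmax_limit_at_coincident_rates(self):
        # k_gutabs == k_el is a removable singularity with limit 1/k_el
        p = TKParams(cl_tot=2.0, vd=1.0, vd_met=1.0, cl_met=1.0,
                     k_gutabs=2.0, k_ufrac=0.5, f_gluc=0.5)
        assert derive(p).t_max == pytest.approx(0.5)
        near = TKParams(cl_tot=2.0, vd=1.0, vd_met=1.0, cl_met=1.0,
                        k_gutabs=2.0 + 1e-6, k_ufrac=0.5, f_gluc=0.5)
        assert derive(near).t_max == pytest.approx(0.5, rel=1e-4)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TKParams(cl_tot=-1, vd=1, vd_met=1, cl_met=1, k_gutabs=1,
                     k_ufrac=0.5, f_gluc=0.5)
        with pytest.raises(ValueError):
            TKParams(cl_tot=1, vd=1, vd_met=1, cl_met=1, k_gutabs=1,
                     k_ufrac=1.5, f_gluc=0.5)


class TestTrajectories:
    def test_initial_condition(self, pop_params):
        traj = simulate_analytic(pop_params, 1500.0, np.array([0.0]))
        assert traj.a_gut[0] == pytest.approx(1500.0)
        for f in ("a_central", "a_met", "q_u", "q_umet"):
            assert getattr(traj, f)[0] == pytest.approx(0.0, abs=1e-9)

    def test_branching_fraction_conservation(self, pop_params):
        traj = simulate_analytic(pop_params, 1500.0, np.array([1e4]))
        assert traj.q_u[-1] == pytest.approx(
            pop_params.k_ufrac * 1500.0, rel=1e-6)
        assert traj.q_umet[-1] == pytest.approx(
            (1 - pop_params.k_ufrac) * 1500.0, rel=1e-6)

    @pytest.mark.parametrize("draw", range(20))
    def test_analytic_matches_ode_oracle(self, draw):
        rng = np.random.default_rng(1234 + draw)
        params = random_params(rng)
        dose = 1500.0
        ana = simulate_analytic(params, dose, GRID)
        ode = simulate_ode(params, dose, GRID)
        for f in ("a_gut", "a_central", "a_met", "q_u", "q_umet",
                  "c_free", "c_total"):
            np.testing.assert_allclose(
                getattr(ana, f), getattr(ode, f),
                rtol=1e-6, atol=1e-6 * dose, err_msg=f)

    @pytest.mark.parametrize("draw", range(10))
    def test_mass_balance(self, draw):
        rng = np.random.default_rng(99 + draw)
        params = random_params(rng)
        traj = simulate_analytic(params, 1500.0, GRID)
        assert traj.mass_balance_error().max() < 1e-9 * 1500.0

    def test_cumulative_urine_nondecreasing(self, pop_params):
        traj = simulate_analytic(pop_params, 1500.0, GRID)
        assert (np.diff(traj.q_u) >= -1e-12).all()
        assert (np.diff(traj.q_umet) >= -1e-12).all()

    def test_ode_zero_dose(self, pop_params):
        traj = simulate_ode(pop_params, 0.0, GRID)
        assert traj.a_central.max() == 0.0
        assert traj.q_u.max() == 0.0

    def test_ode_auc_identity(self, pop_params):
        # dense early grid to resolve the sharp absorption peak
        t = np.unique(np.concatenate([
            np.linspace(0.0, 5.0, 2001), np.linspace(5.0, 500.0, 2000)]))
        traj = simulate_ode(pop_params, 1500.0, t)
        auc = np.trapezoid(traj.c_free, t) * 1000.0  # ng/mL -> ng/L
        assert auc == pytest.approx(auc_inf(pop_params, 1500.0), rel=1e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ka=st.floats(0.5, 60.0))
    def test_cmax_monotone_in_absorption_rate(self, pop_params, ka):
        base = derive(pop_params)
        faster = derive(TKParams(
            cl_tot=pop_params.cl_tot, vd=pop_params.vd,
            vd_met=pop_params.vd_met, cl_met=pop_params.cl_met,
            k_gutabs=ka * 1.3, k_ufrac=pop_params.k_ufrac,
            f_gluc=pop_params.f_gluc))
        slower = derive(TKParams(
            cl_tot=pop_params.cl_tot, vd=pop_params.vd,
            vd_met=pop_params.vd_met, cl_met=pop_params.cl_met,
            k_gutabs=ka, k_ufrac=pop_params.k_ufrac,
            f_gluc=pop_params.f_gluc))
        assert faster.c_max >= slower.c_max * (1 - 1e-9)
        # half-life does not depend on the absorption rate
        assert slower.t_half == pytest.approx(base.t_half)

    def test_export_tidy_frame(self, pop_params):
        frame = simulate_analytic(pop_params, 1500.0, GRID[:5]).to_frame()
        assert set(frame.columns) == {"time_h", "compartment", "value", "unit"}
        assert set(frame["compartment"]) == {
            "a_gut", "a_central", "a_met", "q_u", "q_umet",
            "c_free", "c_total"}


class TestAUC:
    def test_reported_dose_case(self):
        p = TKParams(cl_tot=1.58, vd=4.35, vd_met=7.36, cl_met=33.7,
                     k_gutabs=23.9, k_ufrac=0.212, f_gluc=0.098)
        assert auc_inf(p, 1500.0) == pytest.approx(949.4, abs=0.05)

    def test_zero_dose_and_scaling(self, pop_params):
        assert auc_inf(pop_params, 0.0) == 0.0
        doubled = TKParams(
            cl_tot=2 * pop_params.cl_tot, vd=pop_params.vd,
            vd_met=pop_params.vd_met, cl_met=pop_params.cl_met,
            k_gutabs=pop_params.k_gutabs, k_ufrac=pop_params.k_ufrac,
            f_gluc=pop_params.f_gluc)
        assert auc_inf(doubled, 1500.0) == pytest.approx(
            auc_inf(pop_params, 1500.0) / 2)


class TestObserve:
    def _design(self, intervals, volumes=None):
        intervals = np.asarray(intervals, dtype=float)
        if volumes is None:
            volumes = np.full(len(intervals), 150.0)
        return SubjectDesign(
            subject="s", bw_kg=70.0, dose_ng_per_kg=1500.0,
            blood_times_h=np.array([0.5, 2.0, 8.0]),
            urine_intervals_h=intervals, urine_volumes_ml=volumes)

    def test_total_free_urine_recovery(self, pop_params):
        design = self._design([[0.0, 5000.0]])
        traj = simulate_analytic(pop_params, 1500.0, GRID)
        pred = observe(traj, design)
        assert pred.urine_free[0] == pytest.approx(
            pop_params.k_ufrac * 1500.0 * 70.0, rel=1e-6)

    def test_adjacent_intervals_are_additive(self, pop_params):
        traj = simulate_analytic(pop_params, 1500.0, GRID)
        split = observe(traj, self._design([[0, 6], [6, 24]]))
        spanning = observe(traj, self._design([[0, 24]]))
        assert split.urine_free.sum() == pytest.approx(
            spanning.urine_free[0])
        assert split.urine_total.sum() == pytest.approx(
            spanning.urine_total[0])

    def test_void_masses_match_ode_oracle(self, pop_params):
        design = self._design([[0, 3], [3, 9], [9, 24]])
        traj = simulate_analytic(pop_params, 1500.0, GRID)
        pred = observe(traj, design)
        edges = np.array([0.0, 3.0, 9.0, 24.0])
        ode = simulate_ode(pop_params, 1500.0, edges)
        qtot = ode.q_u + pop_params.f_gluc * ode.q_umet
        np.testing.assert_allclose(
            pred.urine_free, np.diff(ode.q_u) * 70.0, rtol=1e-6)
        np.testing.assert_allclose(
            pred.urine_total, np.diff(qtot) * 70.0, rtol=1e-6)

    def test_blood_predictions_are_concentrations(self, pop_params):
        design = self._design([[0, 24]])
        traj = simulate_analytic(pop_params, 1500.0, GRID)
        pred = observe(traj, design)
        direct = simulate_analytic(pop_params, 1500.0, design.blood_times_h)
        np.testing.assert_allclose(pred.blood_free, direct.c_free)
        np.testing.assert_allclose(pred.blood_total, direct.c_total)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            self._design([[5.0, 2.0]])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            self._design([[0.0, 5.0], [4.0, 8.0]])
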