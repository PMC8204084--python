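"""Cost, chi-square machinery, penalties, fitting, envelopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammainc

import glucoflux as gf
from glucoflux.errors import ConfigurationError, GlucofluxError
from glucoflux.estimation import (
    COST_SENTINEL,
    Dataset,
    PenaltyConfig,
    chi2_test,
    chi2_threshold,
    cost,
    cost_from_trajectory,
    fit,
    fraction_penalty,
    uncertainty_envelope,
)
from glucoflux.simulation import Trajectory, UptakeSummary


def make_traj(times, **cols):
    frame = pd.DataFrame({"time_min": times, **cols})
    return Trajectory(frame=frame)


class TestCost:
    def test_perfect_fit_costs_zero(self):
        t = np.arange(0.0, 10.0)
        traj = make_traj(t, Uidf=t * 0.1)
        ds = Dataset.from_arrays(t, "Uidf", t * 0.1, np.full_like(t, 0.05))
        assert cost_from_trajectory(ds, traj) == 0.0

    def test_unit_residuals(self):
        t = np.array([1.0, 2.0])
        traj = make_traj(t, Uidf=np.array([1.0, 1.0]))
        ds = Dataset.from_arrays(t, "Uidf", [1.2, 0.8], [0.2, 0.2])
        assert cost_from_trajectory(ds, traj) == pytest.approx(2.0)

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 20.0)
        traj = make_traj(t, Uidf=np.sin(t / 5.0))
        vals, sems = rng.normal(0, 1, t.size), rng.uniform(0.1, 0.5, t.size)
        ds = Dataset.from_arrays(t, "Uidf", vals, sems)
        perm = rng.permutation(t.size)
        ds2 = Dataset(ds.frame.iloc[perm].reset_index(drop=True))
        assert cost_from_trajectory(ds, traj) == pytest.approx(
            cost_from_trajectory(ds2, traj), rel=1e-12)

    def test_scales_inversely_with_sem_squared(self):
        t = np.arange(0.0, 10.0)
        traj = make_traj(t, Uidf=np.zeros_like(t))
        ds1 = Dataset.from_arrays(t, "Uidf", np.ones_like(t), np.full_like(t, 0.1))
        ds2 = Dataset.from_arrays(t, "Uidf", np.ones_like(t), np.full_like(t, 0.2))
        assert cost_from_trajectory(ds1, traj) == pytest.approx(
            4.0 * cost_from_trajectory(ds2, traj))

    def test_failed_simulation_returns_sentinel(self):
        ds = Dataset.from_arrays([0.0, 1.0], "Uidf", [0, 0], [1, 1])

        def boom(_):
            raise GlucofluxError("integrator blew up")

        assert cost(gf.ParameterSet(), ds, boom) == COST_SENTINEL

    def test_monte_carlo_cost_distribution_mean(self):
        # at the true parameters, residuals are unit normal, so the cost
        # is chi-square(N): its empirical mean over replicates is ~N
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 12.0)
        truth = np.sin(t / 3.0) + 2.0
        traj = make_traj(t, Uidf=truth)
        sems = np.full_like(t, 0.1)
        costs = [cost_from_trajectory(
            Dataset.from_arrays(t, "Uidf", truth + rng.normal(0, sems), sems), traj)
            for _ in range(200)]
        assert np.mean(costs) == pytest.approx(t.size, rel=0.15)


class TestChi2:
    @pytest.mark.parametrize("df,alpha,expected", [
        (9, 0.05, 16.9), (18, 0.05, 28.9), (15, 0.01, 30.6)])
    def test_printed_quantiles(self, df, alpha, expected):
        assert round(chi2_threshold(df, alpha), 1) == expected

    @pytest.mark.parametrize("df,alpha", [(9, 0.05), (18, 0.05), (15, 0.01), (2, 0.05)])
    def test_agrees_with_incomplete_gamma_bisection(self, df, alpha):
        # independent quantile: bisect P(df/2, x/2) = 1 - alpha
        lo, hi = 0.0, 200.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if gammainc(df / 2, mid / 2) < 1 - alpha:
                lo = mid
            else:
                hi = mid
        assert chi2_threshold(df, alpha) == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_model_rejection_verdicts(self):
        assert not chi2_test(77.7, 9, 0.05)       # rejected
        assert chi2_test(5.36, 9, 0.05)           # accepted
        assert chi2_test(24.5, 18, 0.05)
        assert chi2_test(29.8, 15, 0.01)

    def test_boundary_is_rejected(self):
        thr = chi2_threshold(9, 0.05)
        assert not chi2_test(thr, 9, 0.05)

    def test_estimated_parameter_correction(self):
        # df correction 4 - 2 = 2 changes the threshold used
        assert chi2_test(0.26, 4, 0.05, n_estimated=2)
        assert not chi2_test(chi2_threshold(2, 0.05) + 0.1, 4, 0.05, n_estimated=2)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            chi2_threshold(0, 0.05)
        with pytest.raises(ConfigurationError):
            chi2_threshold(9, 1.5)


class TestFractionPenalty:
    def summary(self, liver, other):
        rest = 1.0 - liver - other
        return UptakeSummary(auc={}, fraction={"liver": liver, "other": other,
                                               "muscle": rest * 0.8, "adipose": rest * 0.2})

    def test_zero_inside_bands(self):
        assert fraction_penalty(self.summary(0.45, 0.23)) == 0.0
        assert fraction_penalty(self.summary(0.40, 0.18)) == 0.0   # band edges
        assert fraction_penalty(self.summary(0.50, 0.30)) == 0.0

    def test_monotone_outside(self):
        p55 = fraction_penalty(self.summary(0.55, 0.23))
        p60 = fraction_penalty(self.summary(0.60, 0.23))
        assert 0 < p55 < p60

    def test_quadratic_hinge_form(self):
        # symbolic check: outside the band the penalty is weight*dist^2,
        # so its one-sided derivative vanishes at the band edge
        cfg = PenaltyConfig(weight=1.0)
        for eps in (1e-3, 1e-4):
            assert fraction_penalty(self.summary(0.50 + eps, 0.23), cfg) == \
                pytest.approx(eps**2, rel=1e-9)
        assert fraction_penalty(self.summary(0.50 + 1e-6, 0.23), cfg) / 1e-6 < 1e-5


class TestFit:
    def test_recovers_quadratic_minimum(self):
        # 1-parameter smoke test: the simulator emits a constant curve at
        # the parameter value; data sit at 0.7
        t = np.array([0.0, 1.0, 2.0, 3.0])
        ds = Dataset.from_arrays(t, "y", np.full(4, 0.7), np.full(4, 0.1))

        def simulator(p: gf.ParameterSet):
            return make_traj(t, y=np.full(4, p.V))

        r = fit(ds, simulator, ["V"], {"V": (0.2, 5.0)}, gf.ParameterSet(),
                restarts=1, seed=0, de_popsize=6, de_maxiter=20)
        assert r.params["V"] == pytest.approx(0.7, abs=1e-4)
        assert r.cost == pytest.approx(0.0, abs=1e-6)
        assert r.accepted

    def test_seeded_runs_reproducible(self):
        t = np.arange(0.0, 6.0)
        rng = np.random.default_rng(3)
        ds = Dataset.from_arrays(t, "y", rng.normal(1.0, 0.1, 6), np.full(6, 0.1))

        def simulator(p):
            return make_traj(t, y=np.full(6, p.V))

        r1 = fit(ds, simulator, ["V"], {"V": (0.2, 5.0)}, gf.ParameterSet(),
                 restarts=2, seed=11, de_popsize=5, de_maxiter=10)
        r2 = fit(ds, simulator, ["V"], {"V": (0.2, 5.0)}, gf.ParameterSet(),
                 restarts=2, seed=11, de_popsize=5, de_maxiter=10)
        assert r1.params == r2.params
        assert r1.cost == r2.cost

    def test_archive_members_all_below_threshold(self):
        t = np.arange(0.0, 6.0)
        ds = Dataset.from_arrays(t, "y", np.full(6, 1.0), np.full(6, 0.1))

        def simulator(p):
            return make_traj(t, y=np.full(6, p.V))

        r = fit(ds, simulator, ["V"], {"V": (0.2, 5.0)}, gf.ParameterSet(),
                restarts=1, seed=0, de_popsize=5, de_maxiter=10)
        assert len(r.acceptable_set) > 0
        assert (r.acceptable_set["cost"] < r.threshold).all()
        assert r.cost <= r.acceptable_set["cost"].min() + 1e-12

    def test_refit_from_optimum_is_idempotent(self):
        t = np.arange(0.0, 6.0)
        ds = Dataset.from_arrays(t, "y", np.full(6, 0.7), np.full(6, 0.1))

        def simulator(p):
            return make_traj(t, y=np.full(6, p.V))

        r1 = fit(ds, simulator, ["V"], {"V": (0.2, 5.0)}, gf.ParameterSet(),
                 restarts=1, seed=0, de_popsize=6, de_maxiter=20)
        base2 = gf.ParameterSet().replace(V=r1.params["V"])
        r2 = fit(ds, simulator, ["V"], {"V": (0.2, 5.0)}, base2,
                 restarts=1, seed=1, de_popsize=6, de_maxiter=20)
        assert abs(r2.cost - r1.cost) < 1e-6

    def test_missing_bounds_rejected(self):
        ds = Dataset.from_arrays([0.0, 1.0], "y", [0, 0], [1, 1])
        with pytest.raises(ConfigurationError):
            fit(ds, lambda p: None, ["V"], {}, gf.ParameterSet())


class TestEnvelope:
    def simulator(self, p):
        t = np.linspace(0.0, 10.0, 21)
        return make_traj(t, y=p.V * np.sin(t / 3.0) + p.Uii)

    def test_singleton_collapses(self):
        arch = pd.DataFrame({"V": [1.3], "cost": [0.5]})
        bands = uncertainty_envelope(arch, self.simulator, ["y"], gf.ParameterSet())
        assert np.allclose(bands["y_min"], bands["y_max"])

    def test_adding_member_only_widens(self):
        arch1 = pd.DataFrame({"V": [1.0, 1.2], "cost": [0.1, 0.2]})
        arch2 = pd.DataFrame({"V": [1.0, 1.2, 0.8], "cost": [0.1, 0.2, 0.3]})
        b1 = uncertainty_envelope(arch1, self.simulator, ["y"], gf.ParameterSet())
        b2 = uncertainty_envelope(arch2, self.simulator, ["y"], gf.ParameterSet())
        assert (b2["y_min"] <= b1["y_min"] + 1e-12).all()
        assert (b2["y_max"] >= b1["y_max"] - 1e-12).all()

    def test_empty_set_advises_wider_starts(self):
        with pytest.raises(ConfigurationError, match="wider"):
            uncertainty_envelope(pd.DataFrame(columns=["V", "cost"]),
                                 self.simulator, ["y"], gf.ParameterSet())

    def test_band_contains_best_fit(self, params, adipose_sim):
        arch = pd.DataFrame({
            "p3": [params.p3, params.p3 * 1.2, params.p3 * 0.8],
            "cost": [0.0, 1.0, 2.0]})
        bands = uncertainty_envelope(arch, adipose_sim, ["Uidf"], params)
        best = adipose_sim(params).column("Uidf")
        assert (bands["Uidf_min"] <= best + 1e-12).all()
        assert (bands["Uidf_max"] >= best - 1e-12).all()

    def test_coverage_of_truth_from_accepted_perturbations(self, params, adipose_sim):
        # reduced Monte-Carlo check: acceptable sets built from perturbed
        # parameters bracket the true-parameter trajectory
        truth_curve = adipose_sim(params).column("Uidf")
        t = np.array([0., 30., 60., 90., 120., 160., 200., 260., 320., 360.])
        truth_at = adipose_sim(params).interpolate("Uidf", t)
        sems = np.maximum(0.05 * np.abs(truth_at), 0.05 * np.abs(truth_at).max())
        contained = 0
        n_rep = 3
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            ds = Dataset.from_arrays(t, "Uidf", truth_at + rng.normal(0, sems), sems)
            thr = chi2_threshold(ds.N, 0.05)
            rows = []
            while len(rows) < 12:
                cand = {k: getattr(params, k) * rng.uniform(0.85, 1.15)
                        for k in ("p3", "p4", "VG6Pmax")}
                c = cost_from_trajectory(ds, adipose_sim(params.replace(**cand)))
                if c < thr:
                    rows.append({**cand, "cost": c})
            bands = uncertainty_envelope(pd.DataFrame(rows), adipose_sim, ["Uidf"], params)
            inside = ((bands["Uidf_min"] - 1e-9 <= truth_curve)
                      & (truth_curve <= bands["Uidf_max"] + 1e-9))
            contained += inside.mean() > 0.9
        assert contained >= 2
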