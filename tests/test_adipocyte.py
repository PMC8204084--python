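"""Adipocyte transport, metabolism with product inhibition, insulin effect."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import glucoflux as gf
from glucoflux.adipocyte import (
    AdipocyteParams,
    AdipocyteState,
    HillGlut4Driver,
    InsulinEffectParams,
    adipocyte_steady_state,
)
from glucoflux.errors import ConfigurationError

ADIP = AdipocyteParams(part_f=0.5, p1=1.0, p2=0.03, p3=0.05, p4=0.1,
                       kgluin=100.0, kG6P=2.0, VG6Pmax=10.0)


class TestTransportFluxes:
    def test_no_insulin_effect_no_transport(self):
        assert gf.transport_fluxes(130.0, 50.0, 0.0, ADIP) == (0.0, 0.0)

    def test_gradient_equilibrium(self):
        gluin = (ADIP.p4 / ADIP.p3) * 130.0
        vin, vout = gf.transport_fluxes(130.0, gluin, 2.0, ADIP)
        assert vin == pytest.approx(vout)

    def test_hand_arithmetic(self):
        p = AdipocyteParams(part_f=0.5, p1=1.0, p2=0.03, p3=0.05, p4=0.1,
                            kgluin=100.0, kG6P=2.0, VG6Pmax=10.0)
        vin, vout = gf.transport_fluxes(130.0, 100.0, 2.0, p)
        assert vin == pytest.approx(26.0)
        assert vout == pytest.approx(10.0)

    @given(st.floats(0, 500), st.floats(0, 500), st.floats(0, 10))
    def test_linear_in_insulin_effect(self, gt, gluin, insfe):
        vin1, vout1 = gf.transport_fluxes(gt, gluin, insfe, ADIP)
        vin2, vout2 = gf.transport_fluxes(gt, gluin, 2 * insfe, ADIP)
        assert vin2 == pytest.approx(2 * vin1)
        assert vout2 == pytest.approx(2 * vout1)


class TestNetUptake:
    def test_examples(self):
        assert gf.net_adipose_uptake(5.0, 5.0, 3.0) == 0.0
        assert gf.net_adipose_uptake(7.0, 2.0, 0.0) == 0.0
        assert gf.net_adipose_uptake(26.0, 10.0, 0.5) == pytest.approx(8.0)

    def test_sign_follows_gradient(self):
        assert gf.net_adipose_uptake(1.0, 4.0, 1.0) < 0


class TestPhosphorylation:
    def test_zero_substrate(self):
        assert gf.phosphorylation_rate(0.0, 5.0, ADIP) == 0.0

    def test_hand_arithmetic(self):
        # VG6Pmax=10, Gluin=kgluin -> 0.5, G6P=0 with kG6P=2 -> 0.5; 10*0.5*0.5=2.5
        assert gf.phosphorylation_rate(ADIP.kgluin, 0.0, ADIP) == pytest.approx(2.5)

    @given(st.floats(0.1, 1e3), st.floats(0, 1e3))
    def test_monotonicity(self, gluin, g6p):
        r = gf.phosphorylation_rate(gluin, g6p, ADIP)
        assert gf.phosphorylation_rate(gluin * 1.1, g6p, ADIP) > r
        assert gf.phosphorylation_rate(gluin, g6p + 1.0, ADIP) < r

    def test_inhibition_shuts_rate_down(self):
        rates = [gf.phosphorylation_rate(100.0, g, ADIP) for g in (0, 10, 100, 1e4, 1e8)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert rates[-1] < 1e-6


class TestAdipocyteRhs:
    def test_empty_cell_fixed_point(self):
        d = gf.adipocyte_rhs(AdipocyteState(0.0, 0.0), 0.0, 0.0, ADIP)
        assert d == (0.0, 0.0)

    def test_steady_state_identities(self):
        # at the fixed point: p2*G6P = VG6P and Vin = Vout + VG6P/p1
        ss = adipocyte_steady_state(130.0, 2.0, ADIP)
        vg6p = gf.phosphorylation_rate(ss.Gluin, ss.G6P, ADIP)
        vin, vout = gf.transport_fluxes(130.0, ss.Gluin, 2.0, ADIP)
        assert ADIP.p2 * ss.G6P == pytest.approx(vg6p, rel=1e-9)
        assert vin == pytest.approx(vout + vg6p / ADIP.p1, rel=1e-9)
        d = gf.adipocyte_rhs(ss, 130.0, 2.0, ADIP)
        assert d == pytest.approx((0.0, 0.0), abs=1e-10)

    def test_steady_state_agrees_with_independent_bisection(self):
        # independent oracle: eliminate G6P and bisect the scalar residual
        p, gt, insfe = ADIP, 130.0, 2.0

        def resid(gluin):
            g6p = p.p1 * insfe * (p.p4 * gt - p.p3 * gluin) / p.p2
            return p.VG6Pmax * gluin / (p.kgluin + gluin) / (p.kG6P + g6p) - p.p2 * g6p

        ref = brentq(resid, 1e-9, p.p4 * gt / p.p3, xtol=1e-12)
        assert adipocyte_steady_state(gt, insfe, p).Gluin == pytest.approx(ref, rel=1e-8)

    def test_product_inhibition_chain_of_events(self):
        # step increase of Gt at constant INSfe: Gluin and G6P rise, the
        # phosphorylation rate peaks and then declines while Gluin is
        # still elevated (G6P inhibition throttles it)
        ss = adipocyte_steady_state(130.0, 2.0, ADIP)

        def rhs(t, y):
            return gf.adipocyte_rhs(AdipocyteState(*y), 260.0, 2.0, ADIP)

        sol = solve_ivp(rhs, (0, 600), [ss.Gluin, ss.G6P], rtol=1e-9, atol=1e-11,
                        t_eval=np.linspace(0, 600, 1201))
        gluin, g6p = sol.y
        vg6p = np.array([gf.phosphorylation_rate(g, s, ADIP) for g, s in zip(gluin, g6p)])
        ipk = vg6p.argmax()
        assert 0 < ipk < len(vg6p) - 1          # interior peak, then decline
        assert gluin[-1] > ss.Gluin              # Gluin still elevated at the end
        assert vg6p[-1] < vg6p[ipk]              # rate has declined from its peak

    def test_intracellular_mass_balance_in_meal(self, meal_traj):
        fr, t = meal_traj.frame, meal_traj.times
        p = gf.ParameterSet()
        dgluin = np.trapezoid(p.p1 * (fr["Vin"] - fr["Vout"]) - fr["VG6P"], t)
        dg6p = np.trapezoid(fr["VG6P"] - p.p2 * fr["G6P"], t)
        assert dgluin == pytest.approx(fr["Gluin"].iloc[-1] - fr["Gluin"].iloc[0], abs=0.5)
        assert dg6p == pytest.approx(fr["G6P"].iloc[-1] - fr["G6P"].iloc[0], abs=0.5)

    def test_no_efflux_means_nonnegative_uptake(self, params, meal_forcings):
        # without efflux there is no finite intracellular steady state
        # (glucose accumulates), so start from the literal initial values
        from glucoflux.simulation import Model, steady_state_initialize
        m = Model(params.replace(p3=0.0))
        y0 = steady_state_initialize(m, literal=True)
        traj = gf.simulate(m, meal_forcings, y0=y0)
        assert traj.column("Uidf").min() >= 0


class TestInsulinEffect:
    EFF = InsulinEffectParams(nC=1.0, k8=2.0, pf=1.0, GLUT1=1.0)

    def test_zero_scaling(self):
        assert gf.insulin_effect(3.0, 0.5, InsulinEffectParams(nC=0.0, k8=2.0, pf=1.0, GLUT1=1.0)) == 0.0

    def test_constitutive_glut1_only(self):
        p = InsulinEffectParams(nC=2.0, k8=1.0, pf=1.3, GLUT1=1.5)
        assert gf.insulin_effect(0.0, 0.0, p) == pytest.approx(2.0 * 1.5**1.3)

    def test_hand_arithmetic(self):
        assert gf.insulin_effect(3.0, 0.5, self.EFF) == pytest.approx(7.5)


class TestGlut4Surrogate:
    DRIVER = HillGlut4Driver(basal_level=0.1, amp=5.0, ec50=60.0, hill=2.0, rate=0.03)

    def test_basal_insulin_gives_basal_glut4(self):
        assert self.DRIVER.steady_state(0.0) == self.DRIVER.basal()
        assert self.DRIVER.rhs(self.DRIVER.basal(), 0.0) == 0.0

    def test_step_response_matches_closed_form(self):
        # after an insulin step the driver is linear:
        # GLUT4m(t) = target + (basal - target)*exp(-rate*t)
        d = self.DRIVER
        target = d.steady_state(100.0)
        sol = solve_ivp(lambda t, y: [d.rhs(y[0], 100.0)], (0, 80.0), [d.basal()],
                        rtol=1e-10, atol=1e-12)
        expected = target + (d.basal() - target) * np.exp(-d.rate * 80.0)
        assert sol.y[0, -1] == pytest.approx(expected, abs=1e-7)

    @given(st.floats(0, 1e4))
    def test_doubling_insulin_never_decreases_steady_state(self, ins):
        d = self.DRIVER
        assert d.steady_state(2 * ins) >= d.steady_state(ins)
        assert d.steady_state(ins) <= d.basal_level + d.amp


class TestValidation:
    def test_kg6p_singularity_guarded(self):
        with pytest.raises(ConfigurationError):
            AdipocyteParams(part_f=1, p1=1, p2=0.03, p3=0.05, p4=0.1,
                            kgluin=100.0, kG6P=0.0, VG6Pmax=10.0)
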