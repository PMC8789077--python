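import math

import numpy as np
import pytest

from rnacat.model import (
    ConservationError,
    EquilibriumParams,
    KineticParams,
    available_substrate,
    simulate_reaction,
    solve_speciation,
    velocity_profile,
)
from rnacat.presets import inactivation_demo, standard_conditions
from rnacat.quantify import ReactionConditions

from _oracles import bisect_speciation, mm_ode_product

T5 = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
OFF = 1e12  # dissociation constant large enough to switch a step off


def _eq(**kw):
    base = dict(Kcs=1.0, Kss=2.0, Kds=5.0, Kp=2.0, Ks=1.0, Kc=OFF,
                substrate_mode="hairpin", conjugate_mode="duplex",
                k_inact=0.0)
    base.update(kw)
    return EquilibriumParams(**base)


class TestAvailableSubstrate:
    def test_no_folding_limit(self):
        assert available_substrate(7.0, math.inf, "hairpin") == (7.0, 0.0)

    def test_symmetric_hairpin_equilibrium(self):
        avail, folded = available_substrate(10.0, 1.0, "hairpin")
        assert avail == pytest.approx(5.0) and folded == pytest.approx(5.0)

    def test_duplex_root_against_bisection(self):
        from scipy.optimize import brentq

        avail, dimers = available_substrate(10.0, 1.0, "duplex")
        root = brentq(lambda s: s + 2 * s * s / 1.0 - 10.0, 0, 10,
                      xtol=1e-14)
        assert avail == pytest.approx(root, abs=1e-9)
        assert avail == pytest.approx(2.0, abs=1e-12)
        assert avail + dimers == pytest.approx(10.0)


class TestSpeciation:
    def test_pure_substrate_reduces_to_available_substrate(self):
        eq = _eq()
        sp = solve_speciation(10.0, 0.0, 0.0, eq)
        avail, folded = available_substrate(10.0, eq.Ks, eq.substrate_mode)
        assert sp.s_free == pytest.approx(avail, rel=1e-10)
        assert sp.s_self == pytest.approx(folded, rel=1e-10)
        assert sp.c_free == 0.0

    def test_tight_full_binding_activates_all_conjugate(self):
        """Kcs -> 0 with excess substrate pulls the conjugate entirely
        into the full complex, even against self-association."""
        eq = _eq(Kcs=1e-9, Kss=1.0, Kc=0.01)
        sp = solve_speciation(100.0, 1.0, 0.0, eq)
        of, _, _, _ = sp.occupancies()
        assert of == pytest.approx(1.0, abs=1e-4)
        assert sp.c_self == pytest.approx(0.0, abs=1e-4)

    def test_single_site_langmuir_isotherm(self):
        """One binding mode only: occupancy is S/(Kcs+S) exactly."""
        eq = EquilibriumParams(Kcs=3.0, Kss=OFF, Kds=OFF, Kp=OFF,
                               Ks=OFF, Kc=OFF)
        c_tot = 1e-6  # catalytic trace: negligible substrate depletion
        for s_tot in (0.5, 3.0, 30.0):
            sp = solve_speciation(s_tot, c_tot, 0.0, eq)
            of, *_ = sp.occupancies()
            assert of == pytest.approx(
                sp.s_free / (3.0 + sp.s_free), abs=1e-9
            )
            assert of == pytest.approx(s_tot / (3.0 + s_tot), abs=1e-6)

    def test_agrees_with_bisection_oracle_on_random_systems(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            kw = dict(
                Kcs=10 ** rng.uniform(-1, 2),
                Kds=10 ** rng.uniform(-1, 2),
                Kp=10 ** rng.uniform(-1, 2),
                Ks=10 ** rng.uniform(-1, 2),
                Kc=10 ** rng.uniform(-2, 2),
            )
            kw["Kss"] = kw["Kcs"] * 10 ** rng.uniform(0, 1.5)
            totals = (10 ** rng.uniform(-1, 2.2), 10 ** rng.uniform(-1, 1),
                      10 ** rng.uniform(-2, 1.5))
            eq = EquilibriumParams(**kw)
            sp = solve_speciation(*totals, eq)
            s, c, p = bisect_speciation(*totals, **kw)
            assert sp.s_free == pytest.approx(s, rel=1e-6)
            assert sp.c_free == pytest.approx(c, rel=1e-6)
            assert sp.p_free == pytest.approx(p, rel=1e-6)

    def test_premise_kcs_not_tighter_than_kss_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumParams(Kcs=10.0, Kss=5.0, Kds=1.0)


class TestSimulate:
    def test_zero_kcat_is_inert(self):
        states = simulate_reaction(_eq(), KineticParams(k_cat=0.0),
                                   ReactionConditions(10.0, 5.0), T5)
        assert all(st.P == 0.0 for st in states)
        assert states[0].S_avail == pytest.approx(states[-1].S_avail)

    def test_reduces_to_michaelis_menten_when_availability_off(self):
        """With self-association, partial/double binding and product
        binding switched off and trace catalyst, the trajectory matches
        the classical MM ODE with Km = Kcs to 0.5% of S_total."""
        eq = EquilibriumParams(Kcs=22.0, Kss=OFF, Kds=OFF, Kp=OFF,
                               Ks=OFF, Kc=OFF)
        kin = KineticParams(k_cat=0.8)
        cond = ReactionConditions(50.0, 0.5)
        states = simulate_reaction(eq, kin, cond, T5, max_step=0.1)
        p_sim = np.array([st.P for st in states])
        p_ode = mm_ode_product(0.8, 22.0, 50.0, 0.5, T5)
        assert np.max(np.abs(p_sim - p_ode)) < 0.005 * 50.0

    def test_mass_conservation_and_monotonicity(self):
        eq, kin = inactivation_demo()
        states = simulate_reaction(eq, kin, ReactionConditions(150.0, 5.0),
                                   T5, max_step=0.2)
        p = np.array([st.P for st in states])
        ci = np.array([st.C_inactivated for st in states])
        assert np.all(np.diff(p) >= 0) and p[-1] <= 150.0
        assert np.all(np.diff(ci) >= -1e-12)
        for st in states:
            s_sum = st.S_avail + st.S_complexed + st.S_bound + st.P
            assert s_sum == pytest.approx(150.0, rel=1e-6)
            c_sum = st.C_active + st.C_selfcomplexed + st.C_inactivated
            assert c_sum == pytest.approx(5.0, rel=1e-6)

    def test_step_halving_changes_endpoint_under_0p1pct(self):
        eq, kin = inactivation_demo()
        cond = ReactionConditions(50.0, 5.0)
        p_a = simulate_reaction(eq, kin, cond, T5, max_step=0.2)[-1].P
        p_b = simulate_reaction(eq, kin, cond, T5, max_step=0.1)[-1].P
        assert abs(p_a - p_b) / p_b < 1e-3

    def test_occupancies_are_fractions(self):
        eq, kin = inactivation_demo()
        for st in simulate_reaction(eq, kin, ReactionConditions(100.0, 5.0),
                                    T5, max_step=0.2):
            occ = (st.occ_full, st.occ_partial, st.occ_double,
                   st.occ_product)
            assert all(0.0 <= o <= 1.0 for o in occ)
            assert sum(occ) <= 1.0 + 1e-9


class TestVelocityProfile:
    def test_single_site_reduction_formula(self):
        eq = EquilibriumParams(Kcs=5.0, Kss=OFF, Kds=OFF, Kp=OFF,
                               Ks=OFF, Kc=OFF)
        kin = KineticParams(k_cat=0.7)
        c, s = 1e-6, 10.0
        vp = velocity_profile(eq, kin, [ReactionConditions(s, c)])
        assert vp["v0_model"][0] == pytest.approx(
            0.7 * c * s / (5.0 + s), rel=1e-6
        )

    def test_v0_proportional_to_catalyst_in_linear_regime(self):
        eq = EquilibriumParams(Kcs=5.0, Kss=OFF, Kds=OFF, Kp=OFF,
                               Ks=OFF, Kc=OFF)
        kin = KineticParams(k_cat=0.7)
        v = [velocity_profile(eq, kin, [ReactionConditions(10.0, c)])
             ["v0_model"][0] for c in (1e-7, 2e-7)]
        assert v[1] / v[0] == pytest.approx(2.0, rel=1e-6)

    def test_initial_velocity_rises_then_falls_across_excesses(self):
        """The parabolic signature: v0 is non-monotone in total
        substrate on the inactivation-enabled fixture."""
        eq, kin = inactivation_demo()
        v0 = velocity_profile(eq, kin, standard_conditions())["v0_model"]
        peak = int(np.argmax(v0))
        assert 0 < peak < len(v0) - 1
        assert v0[peak] > v0.iloc[0] and v0[peak] > v0.iloc[-1]

    def test_mm_form_reproduces_model_velocity_exactly(self):
        """v0 = k_cat * C_active0 * S_avail0 / (Kcs + S_avail0) holds
        for the reported productive-pool definitions."""
        eq, kin = inactivation_demo()
        vp = velocity_profile(eq, kin, standard_conditions())
        pred = kin.k_cat * vp["C_active0"] * vp["S_avail0"] / (
            eq.Kcs + vp["S_avail0"]
        )
        assert np.allclose(pred, vp["v0_model"], rtol=1e-9)
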