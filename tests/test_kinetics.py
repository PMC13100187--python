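"""Unit and property tests of the quenching ODE core."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from npqtau import (
    SpeciesState,
    derivatives,
    initial_state,
    simulate,
)
from npqtau._integrate import NSTATE, pack_params, rhs
from npqtau.kinetics import binding_equilibrium
from npqtau.parameters import GenotypeSpec, KineticParameters, apply_genotype

conc = st.floats(min_value=0.0, max_value=50.0)


def random_state(draw_vals):
    v, a, z, pv, pa, pz, pl, qv, qa, qz, ql, alpha = draw_vals
    return SpeciesState(V=v, A=a, Z=z, PV=pv, PA=pa, PZ=pz, PL=pl,
                        QV=qv, QA=qa, QZ=qz, QL=ql, alpha_qI=alpha)


@settings(derandomize=True, max_examples=50)
@given(st.tuples(*([conc] * 11),
                 st.floats(min_value=0.0, max_value=1.0)),
       st.integers(0, 1), st.integers(0, 1))
def test_vaz_and_lutein_pools_have_zero_net_flux(truth_vals, u, laser):
    """Mass action moves material between VAZ-cycle species but never
    creates or destroys it; same for the lutein pool."""
    from npqtau import default_truth

    kin, _, _ = default_truth()
    s = random_state(truth_vals)
    d = derivatives(s, u, laser, kin)
    vaz_flux = d.V + d.A + d.Z + d.PV + d.PA + d.PZ + d.QV + d.QA + d.QZ
    assert abs(vaz_flux) < 1e-12 * max(1.0, s.vaz_total)
    assert abs(d.PL + d.QL) < 1e-12 * max(1.0, s.lut_total)


@settings(derandomize=True, max_examples=30)
@given(st.tuples(*([conc] * 11), st.floats(min_value=0.0, max_value=1.0)),
       st.integers(0, 1), st.integers(0, 1))
def test_compiled_rhs_matches_reference_derivatives(vals, u, laser):
    """The numba RHS and the pure-Python mass-action reference agree."""
    from npqtau import default_truth

    kin, _, _ = default_truth()
    s = random_state(vals)
    d = derivatives(s, u, laser, kin)
    out = np.empty(NSTATE)
    rhs(s.to_vector(), pack_params(kin), float(u), float(laser), out)
    ref = np.array([d.V, d.A, d.Z, d.PV, d.PA, d.PZ, d.PL,
                    d.QV, d.QA, d.QZ, d.QL, d.alpha_qI])
    np.testing.assert_allclose(out, ref, rtol=1e-12, atol=1e-14)


def test_dark_limit_kills_light_gated_fluxes(truth):
    kin, _, reg = truth
    s = initial_state(reg["zep2"], apply_genotype(kin, reg["zep2"]))
    s = dataclasses.replace(s, QV=1.0, QZ=2.0)
    d = derivatives(s, u=0, laser=0, params=apply_genotype(kin, reg["zep2"]))
    # quenchers only decay in darkness
    assert d.QV == pytest.approx(-kin.k_qvb * 1.0)
    assert d.QZ == pytest.approx(-apply_genotype(kin, reg["zep2"]).k_qzb * 2.0)
    assert d.alpha_qI == 0.0


def test_zero_rates_give_zero_derivatives():
    kin = KineticParameters()
    s = SpeciesState(V=10.0, A=5.0, Z=1.0, PL=100.0)
    d = derivatives(s, u=1, laser=1, params=kin)
    assert all(getattr(d, f) == 0.0 for f in
               ("V", "A", "Z", "PV", "PA", "PZ", "PL", "QV", "QA", "QZ",
                "QL", "alpha_qI"))


class TestInitialState:
    def test_npq1_has_no_ant_or_zea(self, truth):
        kin, _, reg = truth
        s = initial_state(reg["npq1"], apply_genotype(kin, reg["npq1"]))
        assert s.A == s.Z == s.PA == s.PZ == 0.0
        assert s.QV == s.QA == s.QZ == s.QL == 0.0
        assert s.alpha_qI == 0.0

    def test_no_binding_rates_leaves_pools_free(self):
        kin = KineticParameters(P_tot=5.0, L_tot=10.0)
        g = GenotypeSpec(name="x", initial_pigments=(
            ("V_0", 7.0), ("A_0", 2.0), ("Z_0", 1.0), ("L_0", 10.0)))
        s = initial_state(g, kin)
        assert (s.V, s.A, s.Z) == (7.0, 2.0, 1.0)
        assert s.PV == s.PA == s.PZ == 0.0
        assert s.PL == 10.0

    def test_single_pigment_equilibrium_matches_bisection(self):
        """PV from the shared-site solver equals the one-pigment root of
        k_pvf*(V0-PV)*(P_tot-PV) = k_pvb*PV found independently."""
        kin = KineticParameters(k_pvf=0.08, k_pvb=0.3, P_tot=4.0)
        V0 = 10.0

        def f(pv):
            return kin.k_pvf * (V0 - pv) * (kin.P_tot - pv) - kin.k_pvb * pv

        pv_oracle = bisect(f, 0.0, min(V0, kin.P_tot), xtol=1e-12)
        eq = binding_equilibrium({"V": V0, "A": 0.0, "Z": 0.0}, kin)
        assert eq["PV"] == pytest.approx(pv_oracle, abs=1e-9)
        assert eq["V"] == pytest.approx(V0 - pv_oracle, abs=1e-9)

    def test_dark_state_is_stationary_without_zep_flux(self, truth):
        """With no Ant/Zea the dark-acclimated state is a fixed point."""
        kin, _, reg = truth
        p = apply_genotype(kin, reg["WT"])
        s = initial_state(reg["WT"], p)
        d = derivatives(s, u=0, laser=0, params=p)
        vec = np.array([d.V, d.A, d.Z, d.PV, d.PA, d.PZ, d.PL,
                        d.QV, d.QA, d.QZ, d.QL, d.alpha_qI])
        assert np.linalg.norm(vec) < 1e-9


class TestSimulate:
    def test_zero_rate_parameters_hold_state_constant(self, seq_5hl):
        kin = KineticParameters(P_tot=3.0, L_tot=10.0)
        g = GenotypeSpec(name="x", initial_pigments=(
            ("V_0", 7.0), ("A_0", 0.0), ("Z_0", 0.0), ("L_0", 10.0)))
        traj = simulate(g, kin, seq_5hl, grid=np.linspace(0, 1200, 25))
        assert np.max(np.abs(traj.states - traj.states[0:1])) < 1e-12

    def test_conservation_drift_below_1e6(self, truth, seq_5hl):
        kin, _, reg = truth
        for name in ("WT", "zep2", "lut2"):
            g = reg[name]
            traj = simulate(g, apply_genotype(kin, g), seq_5hl)
            assert traj.conservation_drift < 1e-6

    def test_alpha_qI_bounded_and_monotone_under_light(self, truth,
                                                       seq_20hl):
        kin, _, reg = truth
        g = reg["npq4npq1"]
        traj = simulate(g, apply_genotype(kin, g), seq_20hl)
        alpha = traj.species("alpha_qI")
        assert np.all(alpha >= 0.0) and np.all(alpha <= 1.0)
        assert np.all(np.diff(alpha) >= -1e-15)

    def test_zep2_activates_zea_quenching_faster_than_wt(self, truth,
                                                         seq_20hl):
        """Pre-existing dark Zea in the ZEP-reduced mutant drives early
        QZ well above wild type."""
        kin, _, reg = truth
        qz = {}
        for name in ("WT", "zep2"):
            g = reg[name]
            traj = simulate(g, apply_genotype(kin, g), seq_20hl,
                            grid=np.arange(0.0, 61.0, 1.0))
            qz[name] = traj.species("QZ")[-1]
        assert qz["zep2"] > 5 * qz["WT"]

    def test_zeroing_activation_never_increases_quenchers(self, truth,
                                                          seq_20hl):
        kin, _, reg = truth
        g = reg["WT"]
        base = apply_genotype(kin, g)
        knocked = dataclasses.replace(base, k_qzf=0.0)
        t_base = simulate(g, base, seq_20hl)
        t_ko = simulate(g, knocked, seq_20hl)
        assert np.all(t_ko.species("QZ") <= t_base.species("QZ") + 1e-12)
        assert np.all(t_ko.species("QZ") == 0.0)

    def test_adaptive_matches_lsoda_backend(self, truth, seq_5hl):
        """The compiled RK45 and scipy LSODA agree to integration
        tolerance on a full wild-type trajectory."""
        kin, _, reg = truth
        g = reg["WT"]
        p = apply_genotype(kin, g)
        grid = np.arange(0.0, 1201.0, 15.0)
        a = simulate(g, p, seq_5hl, grid=grid, rtol=1e-9, atol=1e-12)
        b = simulate(g, p, seq_5hl, grid=grid, rtol=1e-9, atol=1e-12,
                     method="lsoda")
        np.testing.assert_allclose(a.states, b.states, rtol=2e-6, atol=1e-9)

    def test_grid_outside_duration_rejected(self, truth, seq_5hl):
        kin, _, reg = truth
        g = reg["WT"]
        with pytest.raises(ValueError):
            simulate(g, apply_genotype(kin, g), seq_5hl,
                     grid=np.array([0.0, 1300.0]))
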