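"""Aggregation cascade: conservation, limits, schemes, mode agreement."""

import numpy as np
import pytest

from amykin.equilibria import EquilibriumModel, Totals, \
    solve_prenucleation_equilibrium
from amykin.kinetics import (KineticModel, compare_inhibition_schemes,
                             simulate_aggregation)

T_GRID = np.linspace(0.0, 20 * 3600.0, 41)


class TestCascade:
    def test_no_nucleation_stays_at_equilibrium(self, q35_equilibrium):
        """k_conv = 0 and P0 = 0: no fibrils ever, trajectories equal the
        static pre-nucleation equilibrium."""
        model = KineticModel(equilibrium=q35_equilibrium, k_conv=0.0,
                             k_e=500.0, k_2=0.25, p0=0.0)
        totals = Totals(0.38e-3)
        tc = simulate_aggregation(model, totals, T_GRID)
        eq = solve_prenucleation_equilibrium(
            EquilibriumModel(70e-3, 200e-3, 11e-6), totals)
        assert np.all(tc.trajectories["M"] == 0.0)
        assert np.all(tc.trajectories["P"] == 0.0)
        np.testing.assert_allclose(tc.trajectories["m"], eq.m, rtol=1e-6)
        np.testing.assert_allclose(tc.trajectories["T"], eq.T, rtol=1e-5)

    @pytest.mark.parametrize("scheme,i_tot", [
        ("none", 0.0), ("monomer_binding", 0.4e-3),
        ("nucleus_binding", 0.4e-3), ("dual", 0.4e-3)])
    def test_monomer_unit_conservation(self, q35_equilibrium, scheme, i_tot):
        """m + mI + 2D + 2D* + 4T + M = P_tot to <= 1e-8 relative, all
        four schemes, explicit dynamic integration."""
        model = KineticModel(equilibrium=q35_equilibrium, k_conv=2e-5,
                             k_e=500.0, k_2=0.25, p0=1e-9, scheme=scheme)
        totals = Totals(0.38e-3, i_tot)
        tc = simulate_aggregation(model, totals, T_GRID)
        np.testing.assert_allclose(tc.monomer_units(), totals.p_tot,
                                   rtol=1e-8)

    def test_pure_elongation_closed_form(self, q35_equilibrium):
        """With pre-nucleation off and only elongation active,
        m(t) = m0 exp(-2 k_e P0 t) (two growing ends)."""
        p0, k_e = 5e-8, 1e4
        model = KineticModel(equilibrium=q35_equilibrium, k_conv=0.0,
                             k_e=k_e, k_2=0.0, p0=p0, prenucleation=False)
        totals = Totals(0.38e-3)
        t = np.linspace(0.0, 4 * 3600.0, 21)
        tc = simulate_aggregation(model, totals, t, rtol=1e-10)
        expected = totals.p_tot * np.exp(-2.0 * k_e * p0 * t)
        np.testing.assert_allclose(tc.trajectories["m"], expected, rtol=1e-3)
        assert np.all(tc.trajectories["P"] == pytest.approx(p0, rel=1e-6))

    def test_nucleus_binding_leaves_initial_pool_untouched(self, q35_equilibrium):
        """The nucleus binder acts downstream: at t = 0 the pre-nucleation
        species match the inhibitor-free run exactly."""
        base = KineticModel(equilibrium=q35_equilibrium, k_conv=2e-5,
                            k_e=500.0, k_2=0.25, p0=1e-9)
        bound = base.with_scheme("nucleus_binding")
        tc0 = simulate_aggregation(base, Totals(0.38e-3), T_GRID)
        tc1 = simulate_aggregation(bound, Totals(0.38e-3, 0.8e-3), T_GRID)
        for sp in ("m", "D", "D_star", "T"):
            assert tc1.trajectories[sp][0] == pytest.approx(
                tc0.trajectories[sp][0], rel=1e-9)

    def test_dynamic_and_quasi_equilibrium_agree(self, q35_kinetics):
        totals = Totals(0.38e-3)
        tc_d = simulate_aggregation(q35_kinetics, totals, T_GRID)
        tc_q = simulate_aggregation(q35_kinetics, totals, T_GRID,
                                    mode="quasi_equilibrium")
        m_d, m_q = tc_d.trajectories["M"], tc_q.trajectories["M"]
        assert np.max(np.abs(m_d - m_q)) / totals.p_tot < 0.01

    def test_monomer_inhibition_slows_fibril_growth(self, q35_equilibrium):
        """M(t; I1) >= M(t; I2) pointwise for I1 <= I2 under monomer binding."""
        prev = None
        for i_tot in (0.0, 0.2e-3, 0.4e-3, 0.8e-3):
            scheme = "monomer_binding" if i_tot else "none"
            model = KineticModel(equilibrium=q35_equilibrium, k_conv=2e-5,
                                 k_e=500.0, k_2=0.25, p0=1e-9, scheme=scheme)
            tc = simulate_aggregation(model, Totals(0.38e-3, i_tot), T_GRID,
                                      mode="quasi_equilibrium")
            M = tc.trajectories["M"]
            if prev is not None:
                assert np.all(M <= prev + 1e-9 * 0.38e-3)
            prev = M

    def test_secondary_needs_fibril_mass_primary_needs_tetramer(
            self, q35_equilibrium):
        """k_conv = 0 with M(0) = 0: the secondary term alone never starts
        aggregation."""
        model = KineticModel(equilibrium=q35_equilibrium, k_conv=0.0,
                             k_e=500.0, k_2=10.0, p0=0.0)
        tc = simulate_aggregation(model, Totals(0.38e-3), T_GRID)
        assert np.all(tc.trajectories["M"] == 0.0)

    def test_t_grid_validation(self, q35_kinetics):
        with pytest.raises(ValueError):
            simulate_aggregation(q35_kinetics, Totals(1e-3),
                                 np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate_aggregation(q35_kinetics, Totals(1e-3),
                                 np.array([0.0, 2.0, 1.0]))

    def test_scheme_requires_matching_kd(self):
        eq = EquilibriumModel(70e-3, 200e-3, 11e-6)  # no inhibitor constants
        with pytest.raises(ValueError):
            KineticModel(equilibrium=eq, scheme="monomer_binding")


class TestSchemeComparison:
    def test_identical_schemes_never_diverge(self, q35_equilibrium):
        model = KineticModel(equilibrium=q35_equilibrium, k_conv=2e-5,
                             k_e=500.0, k_2=0.25, p0=1e-9,
                             scheme="monomer_binding")
        rep = compare_inhibition_schemes(model, model, Totals(0.38e-3, 0.4e-3),
                                         T_GRID, mode="quasi_equilibrium")
        assert rep.divergence_time is None
        np.testing.assert_allclose(rep.signal_monomer, rep.signal_nucleus)

    def test_monomer_binding_suppresses_de_novo_nuclei(self, q35_equilibrium):
        """At matched KD = 50 uM, I = 0.8 mM, P = 0.38 mM, the monomer
        binder produces fewer new nuclei than the nucleus binder, and the
        early-time fibril signals coincide (shared pre-existing P0)."""
        kwargs = dict(equilibrium=q35_equilibrium, k_conv=2e-5, k_e=500.0,
                      k_2=0.25, p0=1e-9)
        model_m = KineticModel(scheme="monomer_binding", **kwargs)
        model_p = KineticModel(scheme="nucleus_binding", **kwargs)
        rep = compare_inhibition_schemes(model_m, model_p,
                                         Totals(0.38e-3, 0.8e-3), T_GRID,
                                         mode="quasi_equilibrium")
        # de-novo production: total P + PI created beyond P0
        made_m = (rep.monomer_course.trajectories["P"][-1]
                  + rep.monomer_course.trajectories["PI"][-1] - 1e-9)
        made_p = (rep.nucleus_course.trajectories["P"][-1]
                  + rep.nucleus_course.trajectories["PI"][-1] - 1e-9)
        assert made_m < made_p
        assert abs(rep.signal_monomer[0] - rep.signal_nucleus[0]) < 1e-12
        assert rep.divergence_time is not None

    def test_divergence_time_decreases_with_k_conv(self, q35_equilibrium):
        """Faster primary nucleation separates the mechanisms earlier."""
        times = []
        for k_conv in (1e-5, 4e-5, 1.6e-4):
            kwargs = dict(equilibrium=q35_equilibrium, k_conv=k_conv,
                          k_e=500.0, k_2=0.25, p0=1e-9)
            rep = compare_inhibition_schemes(
                KineticModel(scheme="monomer_binding", **kwargs),
                KineticModel(scheme="nucleus_binding", **kwargs),
                Totals(0.38e-3, 0.8e-3),
                np.linspace(0.0, 20 * 3600.0, 241),
                threshold=0.01, mode="quasi_equilibrium")
            assert rep.divergence_time is not None
            times.append(rep.divergence_time)
        assert times[0] > times[1] > times[2]

    def test_mismatched_shared_parameters_rejected(self, q35_equilibrium):
        a = KineticModel(equilibrium=q35_equilibrium, k_conv=1e-5,
                         scheme="monomer_binding")
        b = KineticModel(equilibrium=q35_equilibrium, k_conv=2e-5,
                         scheme="nucleus_binding")
        with pytest.raises(ValueError):
            compare_inhibition_schemes(a, b, Totals(1e-3, 1e-4), T_GRID)
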