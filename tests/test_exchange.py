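"""Exchange observables: system construction, delta_ex, CPMG, R1rho."""

import numpy as np
import pytest

from amykin.equilibria import SpeciesState, Totals, solve_prenucleation_equilibrium
from amykin.exchange import (DispersionGrid, ExchangeFixture, ExchangeSystem,
                             SpectrometerContext, build_exchange_system,
                             delta_ex_fast, observed_lineshape_parameters,
                             simulate_cpmg, simulate_r1rho)

from conftest import carver_richards, fast_exchange_rex, two_site_system


def random_state(rng) -> SpeciesState:
    m = 10 ** rng.uniform(-4.5, -3)
    return SpeciesState(m=m, D=m * 10 ** rng.uniform(-3, -1.2),
                        D_star=m * 10 ** rng.uniform(-3, -1.2),
                        T=m * 10 ** rng.uniform(-3.5, -1.5))


class TestConstruction:
    def test_two_site_rate_split(self):
        """p_minor = 1%, tau = 750 us: k_ex = 1333.3 s^-1 splits as
        13.3 s^-1 forward and 1320 s^-1 back."""
        state = SpeciesState(m=0.99e-3, D=0.0, D_star=0.005e-3, T=0.0)
        fixture = ExchangeFixture(shifts={"D_star": 1.0}, tau_m_dstar=750e-6)
        system = build_exchange_system(state, Totals(1e-3), fixture)
        i, j = system.labels.index("m"), system.labels.index("D_star")
        assert system.K[j, i] == pytest.approx(13.333, rel=1e-3)   # m -> D*
        assert system.K[i, j] == pytest.approx(1320.0, rel=1e-3)   # D* -> m
        assert -system.K[i, i] == pytest.approx(13.333, rel=1e-3)

    def test_single_site_has_no_exchange(self):
        state = SpeciesState(m=1e-3, D=0.0, D_star=0.0, T=0.0)
        system = build_exchange_system(state, Totals(1e-3),
                                       ExchangeFixture(shifts={}))
        assert system.labels == ("m",)
        assert np.all(system.K == 0.0)

    def test_stationary_vector_matches_populations(self):
        """Null space of each constructed K equals the supplied populations
        (eigen-decomposition oracle, 20 random systems)."""
        rng = np.random.default_rng(11)
        fixture = ExchangeFixture(shifts={"D": 1.0, "D_star": -0.5, "T": 3.0})
        for _ in range(20):
            system = build_exchange_system(random_state(rng), Totals(1e-3),
                                           fixture)
            lam, vec = np.linalg.eig(system.K)
            k = np.argmin(np.abs(lam))
            assert lam[k] == pytest.approx(0.0, abs=1e-8)
            stat = np.real(vec[:, k])
            stat /= stat.sum()
            np.testing.assert_allclose(stat, system.p, atol=1e-10)

    def test_detailed_balance_enforced(self):
        K = np.array([[-10.0, 5.0], [10.0, -5.0]])  # wrong for 0.9/0.1
        with pytest.raises(ValueError):
            ExchangeSystem(labels=("m", "T"), p=np.array([0.9, 0.1]),
                           delta=np.array([0.0, 2.0]), K=K)

    def test_star_topology_drops_dimer(self):
        rng = np.random.default_rng(0)
        state = random_state(rng)
        star = ExchangeFixture(shifts={"D": 1.0, "D_star": -0.5, "T": 3.0},
                               topology="star")
        system = build_exchange_system(state, Totals(1e-3), star)
        assert "D" not in system.labels
        assert {"m", "D_star", "T"} <= set(system.labels)


class TestDeltaEx:
    def test_zero_shifts_give_zero(self):
        system = two_site_system(0.05, 0.0, 1000.0)
        assert delta_ex_fast(system) == 0.0

    def test_weighted_mean(self):
        system = two_site_system(0.05, 2.0, 1000.0)
        assert delta_ex_fast(system) == pytest.approx(0.10)

    def test_fast_limit_matches_eigenvalue_shift(self, context):
        """In deep fast exchange (k_ex >= 50 |d_omega|) the dominant-mode
        observed shift converges on the population-weighted average."""
        d_omega = 2 * np.pi * 2.0 * context.frequency_mhz
        system = two_site_system(0.05, 2.0, k_ex=60 * d_omega)
        shift, _ = observed_lineshape_parameters(system, context)
        assert shift == pytest.approx(delta_ex_fast(system), rel=0.01)

    def test_concentration_dependence_strictly_increasing(self, q7_model,
                                                          exchange_fixture):
        dex = []
        for p_tot in (0.2e-3, 0.4e-3, 0.8e-3, 1.2e-3):
            totals = Totals(p_tot)
            state = solve_prenucleation_equilibrium(q7_model, totals)
            dex.append(delta_ex_fast(
                build_exchange_system(state, totals, exchange_fixture)))
        assert np.all(np.diff(dex) > 0)


class TestLineshape:
    def test_no_exchange_returns_majority_site(self, context):
        system = ExchangeSystem(labels=("m", "T"), p=np.array([0.9, 0.1]),
                                delta=np.array([0.0, 2.0]), r2_0=5.0)
        shift, rex = observed_lineshape_parameters(system, context)
        assert shift == pytest.approx(0.0, abs=1e-9)
        assert rex == pytest.approx(0.0, abs=1e-9)

    def test_two_site_fast_exchange_rex(self, context):
        d_omega = 2 * np.pi * 1.0 * context.frequency_mhz
        k_ex = 30 * d_omega
        system = two_site_system(0.03, 1.0, k_ex)
        _, rex = observed_lineshape_parameters(system, context)
        assert rex == pytest.approx(fast_exchange_rex(0.97, 0.03, d_omega, k_ex),
                                    rel=0.01)

    def test_inhibitor_suppresses_shift_and_broadening(self, q7_model,
                                                       exchange_fixture,
                                                       context):
        model = q7_model.with_inhibitor(kd_mi=50e-6)
        dex, rex = [], []
        for i_tot in (0.0, 0.2e-3, 0.4e-3, 0.8e-3):
            totals = Totals(1.2e-3, i_tot)
            state = solve_prenucleation_equilibrium(model, totals)
            system = build_exchange_system(state, totals, exchange_fixture)
            dex.append(delta_ex_fast(system))
            rex.append(observed_lineshape_parameters(system, context)[1])
        assert np.all(np.diff(dex) < 0)
        assert np.all(np.diff(rex) < 0)

    def test_eigenvalue_agrees_with_time_domain_fid(self, context):
        """Dominant-eigenvalue Rex/shift match a direct FID simulation
        (long-time log-magnitude slope and phase drift) on random systems."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            p_b = rng.uniform(0.01, 0.1)
            delta = rng.uniform(0.5, 3.0)
            d_omega = context.ppm_to_rad(delta)
            k_ex = rng.uniform(5, 50) * d_omega  # fast side: single line
            system = two_site_system(p_b, delta, k_ex, r2_0=5.0)
            shift, rex = observed_lineshape_parameters(system, context)
            L = (system.K - system.r2_0 * np.eye(2)
                 + 1j * np.diag(context.ppm_to_rad(system.delta)))
            from scipy.linalg import expm
            # t1 past the fast transient; t2-t1 short enough that the
            # accumulated phase stays below pi (no wrapping)
            t1, t2 = 0.010, 0.012
            s = [expm(L * t) @ system.p for t in (t1, t2)]
            s1, s2 = np.sum(s[0]), np.sum(s[1])
            decay = -np.log(abs(s2) / abs(s1)) / (t2 - t1)
            freq = np.angle(s2 / s1) / (t2 - t1)
            assert decay - system.r2_0 == pytest.approx(rex, rel=0.02, abs=1e-3)
            assert context.rad_to_ppm(freq) == pytest.approx(shift, rel=0.02,
                                                             abs=1e-4)


class TestCPMG:
    def test_no_exchange_flat_profile(self, context):
        system = ExchangeSystem(labels=("m", "T"), p=np.array([0.9, 0.1]),
                                delta=np.array([0.0, 2.0]), r2_0=12.0)
        grid = DispersionGrid(nu_cpmg=(50.0, 200.0, 1000.0), t_relax=0.04)
        df = simulate_cpmg(system, context, grid)
        np.testing.assert_allclose(df["r2_eff_s"], 12.0, atol=1e-8)

    def test_equal_shifts_flat_profile(self, context):
        system = two_site_system(0.05, 0.0, 1333.0, r2_0=9.0)
        grid = DispersionGrid(nu_cpmg=(50.0, 500.0, 2000.0), t_relax=0.04)
        df = simulate_cpmg(system, context, grid)
        np.testing.assert_allclose(df["r2_eff_s"], 9.0, atol=1e-8)

    def test_matches_carver_richards(self, context):
        """Matrix propagation vs the closed form, within 2% over the
        50-2000 Hz window (p_b = 5%, 2 ppm, k_ex = 1333 s^-1)."""
        p_b, delta, k_ex, r2_0 = 0.05, 2.0, 1333.3, 10.0
        system = two_site_system(p_b, delta, k_ex, r2_0=r2_0)
        nus = tuple(np.linspace(50.0, 2000.0, 12))
        df = simulate_cpmg(system, context, DispersionGrid(nu_cpmg=nus,
                                                           t_relax=0.04))
        d_omega = context.ppm_to_rad(delta)
        oracle = [carver_richards(nu, 1 - p_b, p_b, d_omega, k_ex, r2_0)
                  for nu in nus]
        np.testing.assert_allclose(df["r2_eff_s"], oracle, rtol=0.02)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            DispersionGrid(nu_cpmg=(0.0,))

    def test_dispersion_amplitude_suppressed_by_inhibitor(
            self, q7_model, exchange_fixture, context):
        model = q7_model.with_inhibitor(kd_mi=50e-6)
        amp = []
        grid = DispersionGrid(nu_cpmg=(25.0, 4000.0), t_relax=0.04)
        for i_tot in (0.0, 0.2e-3, 0.4e-3, 0.8e-3):
            totals = Totals(1.2e-3, i_tot)
            state = solve_prenucleation_equilibrium(model, totals)
            system = build_exchange_system(state, totals, exchange_fixture)
            r2 = simulate_cpmg(system, context, grid)["r2_eff_s"]
            amp.append(r2.iloc[0] - r2.iloc[-1])
        assert all(a >= 0 for a in amp)
        assert np.all(np.diff(amp) < 0)


class TestR1rho:
    def test_strong_spinlock_quenches_dispersion(self, context):
        system = two_site_system(0.05, 2.0, 1333.0, r2_0=10.0)
        grid = DispersionGrid(omega1=(100e3,), t_relax=0.04)
        df = simulate_r1rho(system, context, grid)
        assert df["r1rho_s"].iloc[0] == pytest.approx(10.0, abs=0.05)

    def test_field_ordering(self, q7_model, exchange_fixture, context):
        """750 >= 1500 >= 3000 Hz spin locks, any valid system."""
        totals = Totals(1.2e-3)
        state = solve_prenucleation_equilibrium(q7_model, totals)
        system = build_exchange_system(state, totals, exchange_fixture)
        grid = DispersionGrid(omega1=(750.0, 1500.0, 3000.0), t_relax=0.04)
        df = simulate_r1rho(system, context, grid)
        r = df["r1rho_s"].to_numpy()
        assert r[0] >= r[1] >= r[2]

    def test_matches_analytic_fast_exchange(self, context):
        """Within 3% of Rex = pa pb dw^2 kex / (kex^2 + we^2)."""
        delta = 1.0
        d_omega = float(context.ppm_to_rad(delta))
        k_ex = 20 * d_omega
        p_b = 0.04
        system = two_site_system(p_b, delta, k_ex, r2_0=8.0)
        omega1 = (750.0, 1500.0, 3000.0)
        df = simulate_r1rho(system, context,
                            DispersionGrid(omega1=omega1, t_relax=0.04))
        for w1, r1rho in zip(omega1, df["r1rho_s"]):
            rex = fast_exchange_rex(1 - p_b, p_b, d_omega, k_ex,
                                    omega_e=2 * np.pi * w1)
            assert r1rho == pytest.approx(8.0 + rex, rel=0.03)
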