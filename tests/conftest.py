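import numpy as np
import pytest

from amykin.equilibria import EquilibriumModel, Totals
from amykin.exchange import ExchangeFixture, ExchangeSystem, SpectrometerContext
from amykin.kinetics import KineticModel


@pytest.fixture
def q7_model() -> EquilibriumModel:
    """Printed dissociation constants of the non-pathogenic construct."""
    return EquilibriumModel(kd1=70e-3, kd1_star=200e-3, kd2=30e-6)


@pytest.fixture
def q7_totals() -> Totals:
    return Totals(p_tot=1.2e-3)


@pytest.fixture
def q35_equilibrium() -> EquilibriumModel:
    """Pathogenic-construct constants (tighter tetramer) with both
    inhibitor dissociation constants at 50 uM."""
    return EquilibriumModel(kd1=70e-3, kd1_star=200e-3, kd2=11e-6,
                            kd_mi=50e-6, kd_pi=50e-6)


@pytest.fixture
def q35_kinetics(q35_equilibrium) -> KineticModel:
    """Aggregation fixture: hours-scale fibrillation at 0.38 mM."""
    return KineticModel(equilibrium=q35_equilibrium, k_conv=2e-5, k_e=500.0,
                        k_2=0.25, p0=1e-9, scheme="none")


@pytest.fixture
def exchange_fixture() -> ExchangeFixture:
    return ExchangeFixture(shifts={"D": 1.0, "D_star": -0.4, "T": 6.0},
                           r2_0=8.0)


@pytest.fixture
def context() -> SpectrometerContext:
    return SpectrometerContext(frequency_mhz=60.8)


def two_site_system(p_b: float, delta_ppm: float, k_ex: float,
                    r2_0: float = 10.0,
                    labels=("m", "D_star")) -> ExchangeSystem:
    """Hand-built two-site exchange system with detailed balance."""
    p = np.array([1.0 - p_b, p_b])
    kf, kr = k_ex * p_b, k_ex * (1.0 - p_b)
    K = np.array([[-kf, kr], [kf, -kr]])
    return ExchangeSystem(labels=labels, p=p,
                          delta=np.array([0.0, delta_ppm]), r2_0=r2_0, K=K)


def carver_richards(nu_cpmg: float, p_a: float, p_b: float, d_omega: float,
                    k_ex: float, r2_0: float) -> float:
    """Closed-form two-site CPMG R2_eff (independent oracle)."""
    tcp = 1.0 / (2.0 * nu_cpmg)  # time between 180 pulses
    psi = k_ex ** 2 - d_omega ** 2
    zeta = -2.0 * d_omega * k_ex * (p_a - p_b)
    root = np.sqrt(psi ** 2 + zeta ** 2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * d_omega ** 2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * d_omega ** 2) / root)
    eta_plus = tcp / np.sqrt(2.0) * np.sqrt(psi + root)
    eta_minus = tcp / np.sqrt(2.0) * np.sqrt(-psi + root)
    cosh_arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
    return r2_0 + 0.5 * (k_ex - np.arccosh(cosh_arg) / tcp)


def fast_exchange_rex(p_a: float, p_b: float, d_omega: float, k_ex: float,
                      omega_e: float = 0.0) -> float:
    """Analytic fast-exchange Rex with optional effective field (rad/s)."""
    return p_a * p_b * d_omega ** 2 * k_ex / (k_ex ** 2 + omega_e ** 2)
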