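"""Forward models of solution-NMR chemical-exchange observables.

The pre-nucleation oligomers are too sparsely populated and too short-lived
to observe directly; they are read out through their exchange footprint on
the monomer resonance.  This module builds an N-site exchange system from
equilibrium populations and simulates three observables:

* exchange-induced chemical shift (delta_ex) — displacement of the observed
  line from the pure-monomer position in the fast-exchange regime;
* CPMG relaxation dispersion — R2_eff as a function of refocusing-pulse
  frequency, from matrix-exponential propagation of in-phase magnetization
  (Bloch-McConnell) through tau-180-tau echo blocks with ideal pulses;
* on-resonance R1rho dispersion — rotating-frame relaxation versus spin-lock
  field strength, from the dominant eigenvalue of the 3N rotating-frame
  evolution matrix.

Site populations are monomer-unit weights (each NH in an oligomer counts),
renormalized over the exchange-visible sites; rate matrices satisfy detailed
balance with those populations, with pairwise exchange rates set from the
experimental exchange timescales (tau = 1/k_ex for the pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .equilibria import STOICHIOMETRY, SpeciesState, Totals

__all__ = [
    "ExchangeSystem",
    "SpectrometerContext",
    "DispersionGrid",
    "ExchangeFixture",
    "build_exchange_system",
    "delta_ex_fast",
    "observed_lineshape_parameters",
    "simulate_cpmg",
    "simulate_r1rho",
]


@dataclass(frozen=True)
class SpectrometerContext:
    """Larmor frequency of the observed nucleus, for ppm <-> rad/s."""

    frequency_mhz: float = 60.8  # 15N at 14.1 T
    nucleus: str = "15N"

    def __post_init__(self) -> None:
        if self.frequency_mhz <= 0:
            raise ValueError("frequency_mhz must be positive")

    def ppm_to_rad(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return 2.0 * np.pi * np.asarray(ppm) * self.frequency_mhz

    def rad_to_ppm(self, rad: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(rad) / (2.0 * np.pi * self.frequency_mhz)


@dataclass(frozen=True)
class DispersionGrid:
    """Acquisition grid: CPMG pulsing frequencies and/or spin-lock strengths."""

    nu_cpmg: tuple[float, ...] = ()
    omega1: tuple[float, ...] = ()
    t_relax: float = 0.04

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.nu_cpmg) or any(v <= 0 for v in self.omega1):
            raise ValueError("CPMG and spin-lock frequencies must be positive")
        if self.t_relax <= 0:
            raise ValueError("t_relax must be positive")


class ExchangeConstructionError(ValueError):
    """Populations and rates cannot be reconciled with detailed balance."""


@dataclass
class ExchangeSystem:
    """N-site exchange description.

    Attributes
    ----------
    labels : site names, subset of {m, D, D_star, T, mI}
    p : stationary populations (monomer-unit weights, sum to 1)
    delta : chemical-shift offsets relative to m, ppm
    r2_0 : intrinsic transverse relaxation baseline, s^-1 (scalar applied
        to all sites; exchange broadening is reported on top of it)
    r1 : longitudinal relaxation rate, s^-1 (0 by default)
    K : first-order exchange rate matrix, s^-1; K[i, j] is the j -> i rate
        for i != j, columns sum to zero, K @ p = 0
    """

    labels: tuple[str, ...]
    p: np.ndarray
    delta: np.ndarray
    r2_0: float = 0.0
    r1: float = 0.0
    K: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        n = len(self.labels)
        if self.K is None:
            self.K = np.zeros((n, n))
        self.K = np.asarray(self.K, dtype=float)
        if self.p.shape != (n,) or self.delta.shape != (n,) or self.K.shape != (n, n):
            raise ExchangeConstructionError("inconsistent system dimensions")
        if np.any(self.p < -1e-12) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ExchangeConstructionError("populations must be non-negative and sum to 1")
        if np.max(np.abs(self.K.sum(axis=0))) > 1e-8 * max(1.0, np.max(np.abs(self.K))):
            raise ExchangeConstructionError("rate-matrix columns must sum to zero")
        stat = self.K @ self.p
        if np.max(np.abs(stat)) > 1e-8 * max(1.0, np.max(np.abs(self.K))):
            raise ExchangeConstructionError("K @ p != 0: populations not stationary")
        for i in range(n):
            for j in range(i + 1, n):
                flux = self.K[i, j] * self.p[j] - self.K[j, i] * self.p[i]
                if abs(flux) > 1e-8 * max(1.0, np.max(np.abs(self.K))):
                    raise ExchangeConstructionError(
                        f"detailed balance violated for pair ({self.labels[i]}, {self.labels[j]})")

    @property
    def n_sites(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ExchangeFixture:
    """Bundle of exchange parameters that the printed record does not fix.

    Oligomer chemical shifts and intrinsic relaxation rates are free
    parameters of the forward model; experiments constrain them only through
    fitting.  ``topology`` selects the productive-branch description: the
    full linear chain m <-> D <-> T (default) or a lumped two-site m <-> T
    approximation.
    """

    shifts: dict[str, float]           # ppm offsets relative to m
    tau_m_dstar: float = 750e-6        # s, m <-> D* exchange timescale
    tau_m_t: float = 50e-6             # s, productive-branch timescale
    r2_0: float = 8.0                  # s^-1
    r1: float = 0.0
    topology: str = "chain"            # "chain" | "star"
    include_mi: bool = False           # mI visible in the exchange network
    tau_m_mi: float = 0.1              # s, only if include_mi (slow binding)

    def __post_init__(self) -> None:
        if self.tau_m_dstar <= 0 or self.tau_m_t <= 0 or self.tau_m_mi <= 0:
            raise ValueError("exchange timescales must be positive")
        if self.topology not in ("chain", "star"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _add_pair(K: np.ndarray, p: np.ndarray, i: int, j: int, k_ex: float) -> None:
    """Connect sites i, j with total exchange rate k_ex and detailed balance.

    Within the pair, k(i->j) = k_ex * p_j / (p_i + p_j), so the minor site's
    forward rate is the minor population times k_ex.
    """
    tot = p[i] + p[j]
    if tot <= 0:
        return
    kij = k_ex * p[i] / tot  # j -> i
    kji = k_ex * p[j] / tot  # i -> j
    K[i, j] += kij
    K[j, j] -= kij
    K[j, i] += kji
    K[i, i] -= kji


def build_exchange_system(state: SpeciesState,
                          totals: Totals,
                          fixture: ExchangeFixture) -> ExchangeSystem:
    """Construct the exchange network from an equilibrium species state.

    The network is anchored on the monomer: m <-> D* on the slower timescale
    (tau_m_dstar ~ 750 us, CPMG window) and the productive branch on the
    faster one (tau_m_t ~ 50 us, delta_ex / R1rho window).  In "chain"
    topology the productive branch is the linear m <-> D <-> T sequence with
    both steps at k_ex = 1/tau_m_t; in "star" topology D is dropped and a
    lumped m <-> T pair carries the branch.  mI (slow, ms-to-s binding) is
    excluded from the microsecond network unless ``include_mi`` is set.
    """
    weights: dict[str, float] = {"m": state.m}
    if state.D_star > 0:
        weights["D_star"] = STOICHIOMETRY["D_star"] * state.D_star
    if fixture.topology == "chain" and state.D > 0:
        weights["D"] = STOICHIOMETRY["D"] * state.D
    if state.T > 0:
        weights["T"] = STOICHIOMETRY["T"] * state.T
    if fixture.include_mi and state.mI > 0:
        weights["mI"] = state.mI

    labels = tuple(weights)
    w = np.array([weights[s] for s in labels])
    if w.sum() <= 0:
        raise ExchangeConstructionError("no exchange-visible population")
    p = w / w.sum()
    delta = np.array([0.0 if s == "m" else fixture.shifts.get(s, 0.0) for s in labels])

    idx = {s: i for i, s in enumerate(labels)}
    K = np.zeros((len(labels), len(labels)))
    if "D_star" in idx:
        _add_pair(K, p, idx["m"], idx["D_star"], 1.0 / fixture.tau_m_dstar)
    if fixture.topology == "chain":
        if "D" in idx:
            _add_pair(K, p, idx["m"], idx["D"], 1.0 / fixture.tau_m_t)
            if "T" in idx:
                _add_pair(K, p, idx["D"], idx["T"], 1.0 / fixture.tau_m_t)
        elif "T" in idx:
            _add_pair(K, p, idx["m"], idx["T"], 1.0 / fixture.tau_m_t)
    else:
        if "T" in idx:
            _add_pair(K, p, idx["m"], idx["T"], 1.0 / fixture.tau_m_t)
    if "mI" in idx:
        _add_pair(K, p, idx["m"], idx["mI"], 1.0 / fixture.tau_m_mi)

    return ExchangeSystem(labels=labels, p=p, delta=delta,
                          r2_0=fixture.r2_0, r1=fixture.r1, K=K)


def delta_ex_fast(system: ExchangeSystem) -> float:
    """Fast-exchange-limit exchange-induced shift, ppm.

    delta_ex = sum_i p_i * delta_i: the population-weighted displacement of
    the coalesced line from the pure-monomer position.
    """
    return float(system.p @ system.delta)


def _evolution_matrix(system: ExchangeSystem, context: SpectrometerContext) -> np.ndarray:
    omega = context.ppm_to_rad(system.delta)
    return system.K - system.r2_0 * np.eye(system.n_sites) + 1j * np.diag(omega)


def observed_lineshape_parameters(system: ExchangeSystem,
                                  context: SpectrometerContext
                                  ) -> tuple[float, float]:
    """Observed-line position (ppm) and exchange broadening Rex (s^-1).

    Eigendecomposition of the free-evolution matrix L = K - R2 + i*Omega;
    the observed line is the eigenmode carrying the largest detected
    amplitude for the equilibrium starting magnetization (weight
    c_k * 1^T v_k with L v_k = lambda_k v_k and p = sum c_k v_k).
    Shift = Im(lambda)/(2 pi nu0); Rex = -Re(lambda) - R2_0.
    """
    L = _evolution_matrix(system, context)
    lam, V = np.linalg.eig(L)
    try:
        coef = np.linalg.solve(V, system.p.astype(complex))
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(V, system.p.astype(complex), rcond=None)[0]
    amp = np.abs(coef * V.sum(axis=0))
    order = np.argsort(-amp)
    if len(order) > 1 and np.isclose(amp[order[0]], amp[order[1]], rtol=1e-6):
        warnings.warn("degenerate dominant exchange eigenmodes; "
                      "tie broken by detected amplitude", stacklevel=2)
    k = order[0]
    shift_ppm = float(context.rad_to_ppm(lam[k].imag))
    rex = float(-lam[k].real - system.r2_0)
    return shift_ppm, rex


def simulate_cpmg(system: ExchangeSystem,
                  context: SpectrometerContext,
                  grid: DispersionGrid) -> "pd.DataFrame":
    """CPMG relaxation dispersion R2_eff(nu_cpmg).

    In-phase magnetization is propagated through repeating tau-180-tau
    blocks (tau = 1/(4 nu)); the ideal 180 pulse is complex conjugation.
    The echo-block count is rounded to fill t_relax, and
    R2_eff = -ln(S(T)/S(0)) / T with T the actual propagated duration.
    """
    import pandas as pd

    rows = []
    for nu in grid.nu_cpmg:
        tau = 1.0 / (4.0 * nu)
        n_blocks = max(1, round(grid.t_relax / (2.0 * tau)))
        t_total = n_blocks * 2.0 * tau
        U = expm(_evolution_matrix(system, context) * tau)
        M = system.p.astype(complex)
        s0 = abs(M.sum())
        for _ in range(n_blocks):
            M = U @ np.conj(U @ M)
        r2_eff = -np.log(abs(M.sum()) / s0) / t_total
        rows.append((nu, float(r2_eff)))
    return pd.DataFrame(rows, columns=["nu_cpmg_hz", "r2_eff_s"])


def _rotating_frame_matrix(system: ExchangeSystem,
                           context: SpectrometerContext,
                           omega1_hz: float) -> np.ndarray:
    """3N x 3N Bloch-McConnell matrix with an x spin-lock, on resonance with
    the population-averaged line (offset convention: Omega_i - Omega_bar)."""
    n = system.n_sites
    omega = np.asarray(context.ppm_to_rad(system.delta), dtype=float)
    d_omega = omega - float(system.p @ omega)
    w1 = 2.0 * np.pi * omega1_hz
    A = np.zeros((3 * n, 3 * n))
    for i in range(n):
        b = 3 * i
        A[b, b] = -system.r2_0
        A[b, b + 1] = -d_omega[i]
        A[b + 1, b] = d_omega[i]
        A[b + 1, b + 1] = -system.r2_0
        A[b + 1, b + 2] = -w1
        A[b + 2, b + 1] = w1
        A[b + 2, b + 2] = -system.r1
    A += np.kron(system.K, np.eye(3))
    return A


def simulate_r1rho(system: ExchangeSystem,
                   context: SpectrometerContext,
                   grid: DispersionGrid) -> "pd.DataFrame":
    """On-resonance R1rho dispersion versus spin-lock field strength.

    R1rho is minus the real part of the eigenvalue of the rotating-frame
    evolution matrix whose eigenvector has maximal overlap with the
    spin-locked equilibrium magnetization (all sites along x).
    """
    import pandas as pd

    n = system.n_sites
    m0 = np.zeros(3 * n)
    m0[0::3] = system.p
    m0 /= np.linalg.norm(m0)
    rows = []
    for w1 in grid.omega1:
        A = _rotating_frame_matrix(system, context, w1)
        lam, V = np.linalg.eig(A)
        overlap = np.abs(m0 @ V) / np.linalg.norm(V, axis=0)
        k = int(np.argmax(overlap))
        rows.append((w1, float(-lam[k].real)))
    return pd.DataFrame(rows, columns=["omega1_hz", "r1rho_s"])
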