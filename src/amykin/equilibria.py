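"""Branched pre-nucleation mass-action equilibrium.

Monomeric huntingtin exon 1 (m) self-associates along two competing routes:
a productive pathway m <-> D <-> T (coiled-coil dimer to tetrameric helical
bundle, the species feeding nucleation) and a non-productive off-pathway
dimer D*.  A small-molecule inhibitor I may bind free monomer to form an
inert complex mI.  Dissociation-constant conventions:

    KD1  = [m]^2 / [D]      (m <-> D)
    KD1* = [m]^2 / [D*]     (m <-> D*)
    KD2  = [D]^2 / [T]      (D <-> T)
    KD_mI = [m][I] / [mI]   (m + I <-> mI)

With these conventions the tetramer concentration scales as [m]^4
(so its monomer-unit mass fraction scales as [m]^3), which is the origin
of the strong concentration dependence of the exchange observables.

The mI complex is inert: it neither dimerizes nor tetramerizes, and mixed
species (m2I, mI2, (mI)2, (mI)4) are excluded from the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

GAS_CONSTANT_KCAL = 1.987204258640832e-3  # kcal / (mol K)

__all__ = [
    "EquilibriumModel",
    "Totals",
    "SpeciesState",
    "EquilibriumError",
    "solve_prenucleation_equilibrium",
    "population_fractions",
    "free_energy_difference",
    "STOICHIOMETRY",
]

#: monomer units carried by each protein species
STOICHIOMETRY = {"m": 1, "mI": 1, "D": 2, "D_star": 2, "T": 4}


class EquilibriumError(RuntimeError):
    """Raised when the mass-balance root-finder fails to converge."""


@dataclass(frozen=True)
class EquilibriumModel:
    """Dissociation constants of the branched pre-nucleation scheme (molar).

    ``kd_mi`` / ``kd_pi`` are optional; ``None`` means the corresponding
    binding step is absent.  ``kd_pi`` (nucleus-inhibitor binding) is not
    used here but travels with the model for the aggregation cascade.
    """

    kd1: float
    kd1_star: float
    kd2: float
    kd_mi: float | None = None
    kd_pi: float | None = None

    def __post_init__(self) -> None:
        for name in ("kd1", "kd1_star", "kd2"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("kd_mi", "kd_pi"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive or None, got {v!r}")

    def with_inhibitor(self, kd_mi: float | None = None,
                       kd_pi: float | None = None) -> "EquilibriumModel":
        return EquilibriumModel(self.kd1, self.kd1_star, self.kd2,
                                kd_mi if kd_mi is not None else self.kd_mi,
                                kd_pi if kd_pi is not None else self.kd_pi)


@dataclass(frozen=True)
class Totals:
    """Total protein (monomer-equivalent) and total inhibitor, molar."""

    p_tot: float
    i_tot: float = 0.0

    def __post_init__(self) -> None:
        if not (self.p_tot >= 0 and math.isfinite(self.p_tot)):
            raise ValueError(f"p_tot must be >= 0 and finite, got {self.p_tot!r}")
        if not (self.i_tot >= 0 and math.isfinite(self.i_tot)):
            raise ValueError(f"i_tot must be >= 0 and finite, got {self.i_tot!r}")


@dataclass(frozen=True)
class SpeciesState:
    """Molar concentrations of all species at equilibrium (or a time point)."""

    m: float
    D: float
    D_star: float
    T: float
    mI: float = 0.0
    I_free: float = 0.0

    def concentrations(self) -> dict[str, float]:
        return {"m": self.m, "D": self.D, "D_star": self.D_star,
                "T": self.T, "mI": self.mI}

    def protein_total(self) -> float:
        """Monomer units held in protein species."""
        return sum(STOICHIOMETRY[k] * v for k, v in self.concentrations().items())


def _species_given_m(m: float, model: EquilibriumModel, i_tot: float) -> SpeciesState:
    D = m * m / model.kd1
    D_star = m * m / model.kd1_star
    T = D * D / model.kd2
    if model.kd_mi is not None and i_tot > 0:
        I_free = i_tot * model.kd_mi / (model.kd_mi + m)
        mI = m * I_free / model.kd_mi
    else:
        I_free, mI = i_tot, 0.0
    return SpeciesState(m=m, D=D, D_star=D_star, T=T, mI=mI, I_free=I_free)


def solve_prenucleation_equilibrium(model: EquilibriumModel,
                                    totals: Totals,
                                    tol: float = 1e-15,
                                    max_iter: int = 200) -> SpeciesState:
    """Solve the coupled mass balances for all species concentrations.

    Free inhibitor is eliminated analytically, I_free = I_tot/(1 + m/KD_mI),
    leaving a single strictly increasing protein-balance function of the
    free-monomer concentration, f(m) = m + mI + 2D + 2D* + 4T - P_tot,
    bracketed on [0, P_tot].  The bracketed root is located with Brent's
    method and polished with Newton steps on the analytic derivative.

    Raises
    ------
    EquilibriumError
        If the root-finder does not converge (residual reported).
    """
    p_tot, i_tot = totals.p_tot, totals.i_tot
    if p_tot == 0.0:
        return SpeciesState(0.0, 0.0, 0.0, 0.0, 0.0, i_tot)

    def balance(m: float) -> float:
        return _species_given_m(m, model, i_tot).protein_total() - p_tot

    def dbalance(m: float) -> float:
        d = 1.0 + 4.0 * m / model.kd1 + 4.0 * m / model.kd1_star \
            + 16.0 * m ** 3 / (model.kd1 ** 2 * model.kd2)
        if model.kd_mi is not None and i_tot > 0:
            d += i_tot * model.kd_mi / (model.kd_mi + m) ** 2
        return d

    # f(0) = -P_tot < 0 and f(P_tot) >= 0: the root is bracketed.
    m = brentq(balance, 0.0, p_tot, xtol=1e-18, rtol=1e-15, maxiter=max_iter)
    for _ in range(5):
        f = balance(m)
        step = f / dbalance(m)
        m_new = m - step
        if not (0.0 <= m_new <= p_tot):
            break
        m = m_new
        if abs(step) < tol:
            break
    state = _species_given_m(m, model, i_tot)
    residual = abs(state.protein_total() - p_tot)
    if residual > 1e-9 * max(p_tot, 1e-30):
        raise EquilibriumError(
            f"mass-balance residual {residual:.3e} M exceeds tolerance "
            f"(m={m:.6e} M, P_tot={p_tot:.6e} M)")
    return state


def population_fractions(state: SpeciesState, totals: Totals) -> dict[str, float]:
    """Monomer-unit mass fraction of each protein species.

    fraction_X = stoichiometry_X * [X] / P_tot; fractions sum to 1 over the
    protein species when the state satisfies the protein mass balance.
    Returns an empty mapping for an empty system (P_tot = 0).
    """
    if totals.p_tot == 0:
        return {}
    return {name: STOICHIOMETRY[name] * conc / totals.p_tot
            for name, conc in state.concentrations().items()}


def free_energy_difference(kd_a: float, kd_b: float, temperature: float) -> float:
    """Free-energy difference R*T*ln(KD_a/KD_b) in kcal/mol.

    Positive when KD_a > KD_b, i.e. the b-state complex is the more stable.
    """
    if not (kd_a > 0 and kd_b > 0 and temperature > 0):
        raise ValueError("dissociation constants and temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd_a / kd_b)
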