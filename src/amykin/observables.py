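"""Time-resolved NMR observables computed from aggregation trajectories.

Three readouts distinguish the stages of the cascade:

* PRD intensity decay — the proline-rich-domain resonances are free of
  fast-exchange broadening, so their intensity simply tracks the soluble
  (NMR-visible) monomer-unit pool and decays only on fibril incorporation;
* NT cross-peak volume and intensity (V/I) — the N-terminal resonances sit
  in fast exchange with the oligomers: volume tracks the visible pool while
  peak height is additionally damped by exchange broadening,
  I ~ V * R2_ref / (R2_ref + Rex), so the two diverge early (intensity can
  transiently rise as monomer depletion shrinks the tetramer population and
  hence Rex, before overall signal loss wins);
* time-dependent delta_ex — the fast-exchange shift evaluated from the
  instantaneous free-species populations.

All exchange quantities are computed adiabatically: the microsecond exchange
network re-equilibrates instantly on the hours-scale aggregation clock, so
at each output time the static exchange model is rebuilt from the
instantaneous species concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import STOICHIOMETRY, Totals
from .exchange import (ExchangeFixture, SpectrometerContext,
                       build_exchange_system, delta_ex_fast,
                       observed_lineshape_parameters)
from .kinetics import TimeCourse

__all__ = ["ObservableSettings", "prd_decay", "nt_volume_intensity",
           "delta_ex_timecourse"]

_DEFAULT_VISIBILITY = {"m": True, "mI": True, "D": True, "D_star": True,
                       "T": True, "P": False, "PI": False, "M": False}


@dataclass(frozen=True)
class ObservableSettings:
    """Settings shared by the time-resolved observables.

    ``r2_ref`` is the linewidth-equivalent relaxation rate of the NT
    resonance absent exchange (sets how strongly Rex suppresses peak
    height).  ``visibility`` flags which species contribute observable
    signal; fibril-phase species (P, PI, M) are solid-like and invisible,
    while the rapidly exchanging oligomers share the monomer's single
    observed resonance.  Signals are normalized to 1 at t = 0.
    """

    r2_ref: float = 8.0
    visibility: dict[str, bool] = field(default_factory=lambda: dict(_DEFAULT_VISIBILITY))

    def __post_init__(self) -> None:
        if self.r2_ref <= 0:
            raise ValueError("r2_ref must be positive")


def _visible_signal(tc: TimeCourse, settings: ObservableSettings) -> np.ndarray:
    """Visible monomer-unit fraction at each output time."""
    p_tot = tc.totals.p_tot
    sig = np.zeros_like(tc.t, dtype=float)
    for name, stoich in STOICHIOMETRY.items():
        if settings.visibility.get(name, False):
            sig += stoich * tc.trajectories[name]
    return sig / p_tot


def prd_decay(tc: TimeCourse, settings: ObservableSettings | None = None) -> pd.DataFrame:
    """Normalized PRD intensity versus time.

    signal(t) = sum over visible species of stoichiometry * [X](t) / P_tot;
    equal to 1 at t = 0 when no fibril mass is present and monotone
    non-increasing while aggregation is irreversible.
    """
    settings = settings or ObservableSettings()
    return pd.DataFrame({"t_s": tc.t, "intensity": _visible_signal(tc, settings)})


def _rex_series(tc: TimeCourse, fixture: ExchangeFixture,
                context: SpectrometerContext) -> np.ndarray:
    rex = np.empty_like(tc.t, dtype=float)
    for i in range(len(tc.t)):
        state = tc.state_at(i)
        if state.m <= 0:
            rex[i] = 0.0
            continue
        system = build_exchange_system(state, tc.totals, fixture)
        _, rex[i] = observed_lineshape_parameters(system, context)
    return np.clip(rex, 0.0, None)


def nt_volume_intensity(tc: TimeCourse,
                        fixture: ExchangeFixture,
                        context: SpectrometerContext | None = None,
                        settings: ObservableSettings | None = None) -> pd.DataFrame:
    """NT cross-peak volume, intensity and V/I ratio versus time.

    V(t) tracks the visible pool; I(t) = V(t) * R2_ref / (R2_ref + Rex(t))
    with Rex rebuilt from the instantaneous species state (Lorentzian peak
    height = area / linewidth).  Both are normalized to their t = 0 values,
    so V/I starts at 1 and reports the change in exchange broadening.
    """
    context = context or SpectrometerContext()
    settings = settings or ObservableSettings()
    volume = _visible_signal(tc, settings)
    rex = _rex_series(tc, fixture, context)
    height = volume * settings.r2_ref / (settings.r2_ref + rex)
    v = volume / volume[0]
    i = height / height[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i > 0, v / i, np.nan)
    return pd.DataFrame({"t_s": tc.t, "volume": v, "intensity": i,
                         "v_over_i": ratio, "rex_s": rex})


def delta_ex_timecourse(tc: TimeCourse,
                        fixture: ExchangeFixture) -> pd.DataFrame:
    """Fast-exchange delta_ex evaluated from the instantaneous populations.

    Decays toward zero as free monomer (and with it the oligomer pool)
    is consumed by fibril formation.
    """
    dex = np.empty_like(tc.t, dtype=float)
    for i in range(len(tc.t)):
        state = tc.state_at(i)
        if state.m <= 0:
            dex[i] = 0.0
            continue
        system = build_exchange_system(state, tc.totals, fixture)
        dex[i] = delta_ex_fast(system)
    return pd.DataFrame({"t_s": tc.t, "delta_ex_ppm": dex})
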