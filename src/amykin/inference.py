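"""Global fitting and inhibitor-mechanism classification.

A heterogeneous :class:`ExperimentSet` — concentration-dependent delta_ex,
R1rho and CPMG dispersions, V/I ratios and PRD decay time courses — is fit
simultaneously to the forward models of the other modules by weighted
nonlinear least squares (inverse-variance weighting across observables,
parameters optimized on a log scale where they are strictly positive).

Mechanism classification fits the four candidate inhibitor schemes and ranks
them by small-sample-corrected Akaike information criterion (AICc).  The
ranking operationalizes the experimental signatures: a monomer-sequestering
inhibitor changes the equilibrium observables (delta_ex, V/I) *and* slows
PRD decay; a nucleus-sequestering inhibitor slows PRD decay while leaving
the equilibrium observables untouched (nuclei form downstream of the
m <-> D <-> T pool); an inert compound changes nothing.

The public surface follows the Model/Results convention:
``GlobalFitModel(experiments, params, free=...).fit()`` returns a
:class:`GlobalFitResult` carrying estimates, standard errors, per-dataset
residual statistics and a ``summary()`` table; ``MechanismClassifier.fit()``
returns a :class:`MechanismVerdict`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .equilibria import (EquilibriumModel, Totals,
                         solve_prenucleation_equilibrium)
from .exchange import (DispersionGrid, ExchangeFixture, SpectrometerContext,
                       build_exchange_system, delta_ex_fast,
                       observed_lineshape_parameters, simulate_cpmg,
                       simulate_r1rho)
from .kinetics import KineticModel, simulate_aggregation
from .observables import ObservableSettings, prd_decay

__all__ = ["Dataset", "ExperimentSet", "GlobalFitModel", "GlobalFitResult",
           "MechanismClassifier", "MechanismVerdict", "InsufficientDataError",
           "DEFAULT_PARAMS", "DATASET_KINDS"]

DATASET_KINDS = ("delta_ex", "r1rho", "cpmg", "vi", "prd_decay")

#: full parameter vocabulary with defaults; every forward model draws from
#: one flat mapping so that any subset can be declared free in a fit.
DEFAULT_PARAMS: dict[str, float | str | bool] = {
    "kd1": 70e-3, "kd1_star": 200e-3, "kd2": 30e-6,
    "kd_mi": 50e-6, "kd_pi": 50e-6,
    "tau_m_dstar": 750e-6, "tau_m_t": 50e-6,
    "delta_d": 1.0, "delta_dstar": -0.4, "delta_t": 6.0,   # ppm
    "r2_0": 8.0, "r2_ref": 3.0, "r1": 0.0,                 # s^-1
    "k_conv": 2e-5, "k_e": 500.0, "k_2": 0.25,
    "n_2": 2.0, "n_c": 4, "p0": 1e-9,
    "frequency_mhz": 60.8, "topology": "chain", "t_relax": 0.04,
}

_LOG_SCALE = {"kd1", "kd1_star", "kd2", "kd_mi", "kd_pi", "tau_m_dstar",
              "tau_m_t", "r2_0", "r2_ref", "k_conv", "k_e", "k_2", "p0"}

_REQUIRED_COLUMNS = {
    "delta_ex": ("p_tot_M", "i_tot_M", "value", "sigma"),
    "vi": ("p_tot_M", "i_tot_M", "value", "sigma"),
    "r1rho": ("omega1_hz", "value", "sigma"),
    "cpmg": ("nu_cpmg_hz", "value", "sigma"),
    "prd_decay": ("t_s", "value", "sigma"),
}


class InsufficientDataError(ValueError):
    """The dataset collection cannot support the requested analysis."""


@dataclass
class Dataset:
    """One observed table tagged with its type and conditions.

    ``conditions`` must provide ``p_tot`` and ``i_tot`` (molar) for the
    per-condition kinds (r1rho, cpmg, prd_decay); for delta_ex and vi the
    conditions are per-row columns.
    """

    kind: str
    table: pd.DataFrame
    conditions: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DATASET_KINDS:
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        missing = [c for c in _REQUIRED_COLUMNS[self.kind]
                   if c not in self.table.columns]
        if missing:
            raise ValueError(f"{self.kind} table missing columns {missing}")
        if not (self.table["sigma"] > 0).all():
            raise ValueError("per-point uncertainties must be positive")
        if self.kind in ("r1rho", "cpmg", "prd_decay"):
            for key in ("p_tot", "i_tot"):
                if key not in self.conditions:
                    raise ValueError(f"{self.kind} dataset requires condition {key!r}")

    @property
    def nobs(self) -> int:
        return len(self.table)


@dataclass
class ExperimentSet:
    """Heterogeneous collection of datasets for global fitting."""

    datasets: list[Dataset]

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def nobs(self) -> int:
        return sum(d.nobs for d in self.datasets)

    def kinds(self) -> set[str]:
        return {d.kind for d in self.datasets}

    def inhibitor_levels(self, kind: str) -> set[float]:
        levels: set[float] = set()
        for d in self.datasets:
            if d.kind != kind:
                continue
            if "i_tot_M" in d.table.columns:
                levels.update(d.table["i_tot_M"].unique())
            elif "i_tot" in d.conditions:
                levels.add(d.conditions["i_tot"])
        return levels


# ---------------------------------------------------------------------------
# forward evaluation from a flat parameter mapping

def _equilibrium_from(params: dict, scheme: str) -> EquilibriumModel:
    binds_m = scheme in ("monomer_binding", "dual")
    return EquilibriumModel(
        kd1=params["kd1"], kd1_star=params["kd1_star"], kd2=params["kd2"],
        kd_mi=params["kd_mi"] if binds_m else None,
        kd_pi=params["kd_pi"] if scheme in ("nucleus_binding", "dual") else None)


def _fixture_from(params: dict) -> ExchangeFixture:
    return ExchangeFixture(
        shifts={"D": params["delta_d"], "D_star": params["delta_dstar"],
                "T": params["delta_t"]},
        tau_m_dstar=params["tau_m_dstar"], tau_m_t=params["tau_m_t"],
        r2_0=params["r2_0"], r1=params["r1"], topology=params["topology"])


def _kinetic_from(params: dict, scheme: str) -> KineticModel:
    return KineticModel(
        equilibrium=_equilibrium_from(params, scheme),
        k_conv=params["k_conv"], k_e=params["k_e"], k_2=params["k_2"],
        n_2=params["n_2"], n_c=int(params["n_c"]), p0=params["p0"],
        scheme=scheme)


def predict_dataset(dataset: Dataset, params: dict, scheme: str) -> np.ndarray:
    """Forward-model prediction for one dataset under one inhibitor scheme."""
    eq = _equilibrium_from(params, scheme)
    fixture = _fixture_from(params)
    ctx = SpectrometerContext(params["frequency_mhz"])
    tab = dataset.table

    if dataset.kind in ("delta_ex", "vi"):
        out = np.empty(len(tab))
        for i, (p_tot, i_tot) in enumerate(zip(tab["p_tot_M"], tab["i_tot_M"])):
            state = solve_prenucleation_equilibrium(eq, Totals(p_tot, i_tot))
            system = build_exchange_system(state, Totals(p_tot, i_tot), fixture)
            if dataset.kind == "delta_ex":
                out[i] = delta_ex_fast(system)
            else:
                _, rex = observed_lineshape_parameters(system, ctx)
                out[i] = (params["r2_ref"] + max(rex, 0.0)) / params["r2_ref"]
        return out

    totals = Totals(dataset.conditions["p_tot"], dataset.conditions["i_tot"])
    if dataset.kind in ("r1rho", "cpmg"):
        state = solve_prenucleation_equilibrium(eq, totals)
        system = build_exchange_system(state, totals, fixture)
        if dataset.kind == "r1rho":
            grid = DispersionGrid(omega1=tuple(tab["omega1_hz"]),
                                  t_relax=params["t_relax"])
            return simulate_r1rho(system, ctx, grid)["r1rho_s"].to_numpy()
        grid = DispersionGrid(nu_cpmg=tuple(tab["nu_cpmg_hz"]),
                              t_relax=params["t_relax"])
        return simulate_cpmg(system, ctx, grid)["r2_eff_s"].to_numpy()

    # prd_decay: integrate the cascade and sample the visible-pool signal
    t_data = tab["t_s"].to_numpy(dtype=float)
    t_grid = np.unique(np.concatenate(([0.0], t_data)))
    model = _kinetic_from(params, scheme)
    tc = simulate_aggregation(model, totals, t_grid,
                              mode="quasi_equilibrium", rtol=1e-7)
    signal = prd_decay(tc, ObservableSettings(r2_ref=params["r2_ref"]))
    return np.interp(t_data, signal["t_s"], signal["intensity"])


# ---------------------------------------------------------------------------
# Model / Results

class GlobalFitModel:
    """Weighted global nonlinear least squares over an :class:`ExperimentSet`.

    Parameters
    ----------
    experiments : the datasets to fit simultaneously.
    params : full parameter mapping (missing keys take ``DEFAULT_PARAMS``).
    free : names of the parameters to optimize; strictly positive ones are
        handled in log10 space.
    bounds : optional ``{name: (lo, hi)}`` on the natural scale.
    scheme : inhibitor scheme used by the forward models.
    """

    _DEFAULT_BOUNDS = (1e-12, 1e3)

    def __init__(self, experiments: ExperimentSet, params: dict | None = None,
                 free: list[str] | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 scheme: str = "none") -> None:
        if len(experiments) == 0:
            raise InsufficientDataError("at least one dataset is required")
        self.experiments = experiments
        self.params = dict(DEFAULT_PARAMS)
        self.params.update(params or {})
        self.free = list(free or [])
        unknown = [f for f in self.free if f not in self.params]
        if unknown:
            raise ValueError(f"unknown free parameters {unknown}")
        self.bounds = dict(bounds or {})
        self.scheme = scheme
        if set(experiments.kinds()) == {"prd_decay"} and \
                any(f in ("kd1", "kd1_star", "kd2") for f in self.free):
            warnings.warn("equilibrium constants are weakly identifiable from "
                          "PRD decay alone; add delta_ex or V/I data",
                          stacklevel=2)

    # -- parameter transforms -------------------------------------------------
    def _to_theta(self, values: dict) -> np.ndarray:
        return np.array([math.log10(values[f]) if f in _LOG_SCALE else values[f]
                         for f in self.free])

    def _from_theta(self, theta: np.ndarray) -> dict:
        p = dict(self.params)
        for f, v in zip(self.free, theta):
            p[f] = 10.0 ** v if f in _LOG_SCALE else v
        return p

    def _theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for f in self.free:
            b = self.bounds.get(f, self._DEFAULT_BOUNDS if f in _LOG_SCALE
                                else (-np.inf, np.inf))
            if f in _LOG_SCALE:
                lo.append(math.log10(b[0]))
                hi.append(math.log10(b[1]))
            else:
                lo.append(b[0])
                hi.append(b[1])
        return np.array(lo), np.array(hi)

    # -- objective ------------------------------------------------------------
    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        p = self._from_theta(theta)
        res = []
        for d in self.experiments:
            try:
                pred = predict_dataset(d, p, self.scheme)
                r = (pred - d.table["value"].to_numpy()) / d.table["sigma"].to_numpy()
            except Exception:
                r = np.full(d.nobs, 1e3)
            res.append(r)
        return np.concatenate(res)

    def fit(self, start: dict | None = None, n_starts: int = 8,
            seed: int = 0, **ls_kwargs) -> "GlobalFitResult":
        """Multi-start trust-region least squares; deterministic given seed."""
        values = dict(self.params)
        values.update(start or {})
        theta0 = self._to_theta(values)
        lo, hi = self._theta_bounds()
        theta0 = np.clip(theta0, lo, hi)
        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(max(0, n_starts - 1)):
            jitter = rng.uniform(-0.5, 0.5, size=len(theta0))
            starts.append(np.clip(theta0 + jitter, lo, hi))

        best = None
        if len(self.free) == 0:
            r = self._residuals(np.array([]))
            return GlobalFitResult(self, np.array([]), r, converged=True)
        for th in starts:
            sol = least_squares(self._residuals, th, bounds=(lo, hi),
                                method="trf", **ls_kwargs)
            if best is None or sol.cost < best.cost:
                best = sol
        return GlobalFitResult(self, best.x, best.fun,
                               converged=bool(best.status > 0), jac=best.jac)


class GlobalFitResult:
    """Estimates, uncertainties and diagnostics from :class:`GlobalFitModel`.

    Standard errors come from the Jacobian-based covariance approximation
    (J^T J)^-1 scaled to the natural parameter scale; ``aicc`` is the
    small-sample-corrected Akaike criterion computed from the weighted
    residual sum of squares (known-sigma Gaussian likelihood).
    """

    def __init__(self, model: GlobalFitModel, theta: np.ndarray,
                 residuals: np.ndarray, converged: bool,
                 jac: np.ndarray | None = None) -> None:
        self.model = model
        self.theta = theta
        self.params = model._from_theta(theta)
        self.residuals = residuals
        self.converged = converged
        self.nobs = model.experiments.nobs
        self.k = len(model.free)
        self.chi2 = float(residuals @ residuals)
        self.dof = max(self.nobs - self.k, 1)
        self._cov_theta = self._covariance(jac)

    def _covariance(self, jac: np.ndarray | None) -> np.ndarray | None:
        if jac is None or self.k == 0:
            return None
        jtj = jac.T @ jac
        try:
            return np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(jtj)

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k
        aic = self.chi2 + 2 * k
        if n - k - 1 > 0:
            return aic + 2 * k * (k + 1) / (n - k - 1)
        return math.inf

    def stderr(self) -> dict[str, float]:
        """Approximate standard errors on the natural parameter scale."""
        if self._cov_theta is None:
            return {f: math.nan for f in self.model.free}
        out = {}
        for i, f in enumerate(self.model.free):
            se_theta = math.sqrt(max(self._cov_theta[i, i], 0.0))
            if f in _LOG_SCALE:  # delta-method back from log10
                out[f] = self.params[f] * math.log(10.0) * se_theta
            else:
                out[f] = se_theta
        return out

    def per_dataset_chi2(self) -> dict[str, float]:
        out, i = {}, 0
        for j, d in enumerate(self.model.experiments):
            r = self.residuals[i:i + d.nobs]
            out[d.name or f"{d.kind}[{j}]"] = float(r @ r)
            i += d.nobs
        return out

    def predict(self, dataset: Dataset) -> np.ndarray:
        return predict_dataset(dataset, self.params, self.model.scheme)

    def summary(self) -> str:
        lines = [
            "Global fit summary",
            "==================",
            f"scheme:      {self.model.scheme}",
            f"n obs:       {self.nobs}   free params: {self.k}   dof: {self.dof}",
            f"chi2:        {self.chi2:.6g}   reduced: {self.chi2 / self.dof:.4g}",
            f"AICc:        {self.aicc:.6g}",
            f"converged:   {self.converged}",
            "",
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
        ]
        se = self.stderr()
        for f in self.model.free:
            lines.append(f"{f:<12}{self.params[f]:>14.6g}{se[f]:>14.3g}")
        lines.append("")
        lines.append("per-dataset chi2:")
        for name, c2 in self.per_dataset_chi2().items():
            lines.append(f"  {name:<24}{c2:>12.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# mechanism classification

_SCHEME_LABEL = {"none": "none",
                 "monomer_binding": "monomer_sequestration",
                 "nucleus_binding": "nucleus_sequestration",
                 "dual": "dual"}
_SCHEME_FREE = {"none": [], "monomer_binding": ["kd_mi"],
                "nucleus_binding": ["kd_pi"], "dual": ["kd_mi", "kd_pi"]}


@dataclass
class MechanismVerdict:
    """Outcome of model selection over the four inhibitor schemes."""

    label: str
    criteria: dict[str, float]          # scheme -> AICc
    fits: dict[str, GlobalFitResult]
    evidence: dict[str, dict[str, float]]  # scheme -> per-dataset chi2

    def summary(self) -> str:
        lines = ["Mechanism classification", "========================",
                 f"verdict: {self.label}", "",
                 f"{'scheme':<18}{'AICc':>12}{'chi2':>12}{'k':>4}"]
        for s in sorted(self.criteria, key=self.criteria.get):
            fit = self.fits[s]
            lines.append(f"{s:<18}{self.criteria[s]:>12.4g}{fit.chi2:>12.4g}"
                         f"{fit.k:>4d}")
        return "\n".join(lines)


class MechanismClassifier:
    """Assign an inhibitor to a sequestration class by AICc model selection.

    Requires at least one equilibrium-sensitive observable (delta_ex or vi)
    and one fibrillation observable (prd_decay), each recorded at two or
    more inhibitor concentrations — without both, the monomer- and
    nucleus-binding mechanisms are not distinguishable.
    """

    def __init__(self, experiments: ExperimentSet,
                 params: dict | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None) -> None:
        kinds = experiments.kinds()
        if not kinds & {"delta_ex", "vi"}:
            raise InsufficientDataError(
                "classification needs an equilibrium-sensitive observable "
                "(delta_ex or vi): only these separate monomer binding from "
                "downstream mechanisms")
        if "prd_decay" not in kinds:
            raise InsufficientDataError(
                "classification needs a fibrillation observable (prd_decay) "
                "to detect any inhibition at all")
        for kind in (kinds & {"delta_ex", "vi"}) | {"prd_decay"}:
            if len(experiments.inhibitor_levels(kind)) < 2:
                raise InsufficientDataError(
                    f"{kind} data must span >= 2 inhibitor concentrations")
        self.experiments = experiments
        self.params = dict(DEFAULT_PARAMS)
        self.params.update(params or {})
        # wide bounds: the upper end must let a binding step become
        # negligible (KD >> I_tot) so that dual nests the single schemes
        self.bounds = bounds or {"kd_mi": (1e-9, 1.0), "kd_pi": (1e-9, 1.0)}

    def fit(self, n_starts: int = 4, seed: int = 0) -> MechanismVerdict:
        criteria: dict[str, float] = {}
        fits: dict[str, GlobalFitResult] = {}
        for scheme, free in _SCHEME_FREE.items():
            model = GlobalFitModel(self.experiments, self.params, free=free,
                                   bounds=self.bounds, scheme=scheme)
            start = {f: 1e-4 for f in free}  # generic 0.1 mM guess
            res = model.fit(start=start, n_starts=n_starts, seed=seed,
                            xtol=1e-10, ftol=1e-10)
            fits[scheme] = res
            criteria[scheme] = res.aicc
        best = min(criteria, key=criteria.get)
        evidence = {s: fits[s].per_dataset_chi2() for s in fits}
        return MechanismVerdict(label=_SCHEME_LABEL[best], criteria=criteria,
                                fits=fits, evidence=evidence)
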