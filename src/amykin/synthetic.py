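"""Synthetic dataset generation from known ground truth.

Every observable the framework fits can be generated here from a fully
specified scenario, with seeded Gaussian noise, so parameter-recovery and
classification studies need no external data.  The named scenarios carry
the study conditions: dissociation constants 70 mM / 200 mM / 30 uM for the
non-pathogenic Q7 construct (11 uM tetramer constant for pathogenic Q35),
exchange timescales 750 us (m-D*) and 50 us (productive branch), inhibitor
dissociation constants of 50 uM, protein series 0.20-0.75 mM (up to 1.2 mM
for Q7) and inhibitor series 0.2 / 0.4 / 0.8 mM.  Quantities the printed
record does not fix — oligomer chemical shifts, intrinsic relaxation rates,
and the aggregation rate constants k_conv, k_e, k_2 and P0 — are fixture
constants chosen for realism (hours-scale fibrillation, exchange broadening
of a few s^-1) and documented in the package methods note; they are not
literature-derived values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibria import Totals
from .inference import DEFAULT_PARAMS, Dataset, ExperimentSet, predict_dataset

__all__ = ["ScenarioSpec", "make_scenario", "simulate_experiments",
           "generate", "load_experiments", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("q7_prenucleation", "q7_inhibited", "q35_aggregation",
                  "q35_monomer_inhibition", "q35_nucleus_inhibition")

_Q7_CONC = (0.2e-3, 0.4e-3, 0.6e-3, 0.8e-3, 1.0e-3, 1.2e-3)
_Q35_CONC = (0.2e-3, 0.38e-3, 0.55e-3, 0.75e-3)
_INHIBITOR_SERIES = (0.0, 0.2e-3, 0.4e-3, 0.8e-3)
_SPIN_LOCKS = (750.0, 1500.0, 3000.0)
_CPMG_GRID = tuple(np.geomspace(50.0, 2000.0, 10))
_PRD_TIMES = tuple(np.linspace(0.0, 20 * 3600.0, 13))


@dataclass
class ScenarioSpec:
    """Ground truth plus acquisition layout for one synthetic study."""

    name: str
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    scheme: str = "none"
    conc_series: tuple[float, ...] = _Q35_CONC
    inhibitor_series: tuple[float, ...] = (0.0,)
    kinds: tuple[str, ...] = ("delta_ex",)
    noise: float = 0.02
    seed: int = 0
    reference_conc: float = 0.38e-3

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def make_scenario(name: str, noise: float = 0.02, seed: int = 0) -> ScenarioSpec:
    """Return a fully specified scenario by name (see SCENARIO_NAMES)."""
    params = dict(DEFAULT_PARAMS)
    if name == "q7_prenucleation":
        params["kd2"] = 30e-6
        return ScenarioSpec(name, params, scheme="none", conc_series=_Q7_CONC,
                            inhibitor_series=(0.0,),
                            kinds=("delta_ex", "r1rho", "cpmg"),
                            noise=noise, seed=seed, reference_conc=1.2e-3)
    if name == "q7_inhibited":
        params["kd2"] = 30e-6
        return ScenarioSpec(name, params, scheme="monomer_binding",
                            conc_series=_Q7_CONC,
                            inhibitor_series=_INHIBITOR_SERIES,
                            kinds=("delta_ex", "r1rho", "cpmg"),
                            noise=noise, seed=seed, reference_conc=1.2e-3)
    if name == "q35_aggregation":
        params["kd2"] = 11e-6
        return ScenarioSpec(name, params, scheme="none", conc_series=_Q35_CONC,
                            inhibitor_series=(0.0,),
                            kinds=("delta_ex", "vi", "prd_decay"),
                            noise=noise, seed=seed, reference_conc=0.5e-3)
    if name == "q35_monomer_inhibition":
        params["kd2"] = 11e-6
        return ScenarioSpec(name, params, scheme="monomer_binding",
                            conc_series=_Q35_CONC,
                            inhibitor_series=_INHIBITOR_SERIES,
                            kinds=("delta_ex", "vi", "prd_decay"),
                            noise=noise, seed=seed, reference_conc=0.38e-3)
    if name == "q35_nucleus_inhibition":
        params["kd2"] = 11e-6
        params["p0"] = 1e-9
        return ScenarioSpec(name, params, scheme="nucleus_binding",
                            conc_series=_Q35_CONC,
                            inhibitor_series=_INHIBITOR_SERIES,
                            kinds=("delta_ex", "vi", "prd_decay"),
                            noise=noise, seed=seed, reference_conc=0.38e-3)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def _noiseless_datasets(spec: ScenarioSpec) -> list[Dataset]:
    datasets: list[Dataset] = []
    p = spec.params
    for kind in spec.kinds:
        if kind in ("delta_ex", "vi"):
            rows = [(pt, it) for it in spec.inhibitor_series
                    for pt in spec.conc_series]
            tab = pd.DataFrame(rows, columns=["p_tot_M", "i_tot_M"])
            tab["value"] = 0.0
            tab["sigma"] = 1.0
            ds = Dataset(kind, tab, name=f"{spec.name}:{kind}")
            ds.table["value"] = predict_dataset(ds, p, spec.scheme)
            datasets.append(ds)
        elif kind in ("r1rho", "cpmg"):
            col, grid = (("omega1_hz", _SPIN_LOCKS) if kind == "r1rho"
                         else ("nu_cpmg_hz", _CPMG_GRID))
            for i_tot in spec.inhibitor_series:
                tab = pd.DataFrame({col: grid})
                tab["value"] = 0.0
                tab["sigma"] = 1.0
                ds = Dataset(kind, tab,
                             conditions={"p_tot": spec.reference_conc,
                                         "i_tot": i_tot},
                             name=f"{spec.name}:{kind}:I={i_tot * 1e3:g}mM")
                ds.table["value"] = predict_dataset(ds, p, spec.scheme)
                datasets.append(ds)
        elif kind == "prd_decay":
            for i_tot in spec.inhibitor_series:
                tab = pd.DataFrame({"t_s": _PRD_TIMES})
                tab["value"] = 0.0
                tab["sigma"] = 1.0
                ds = Dataset(kind, tab,
                             conditions={"p_tot": spec.reference_conc,
                                         "i_tot": i_tot},
                             name=f"{spec.name}:prd:I={i_tot * 1e3:g}mM")
                ds.table["value"] = predict_dataset(ds, p, spec.scheme)
                datasets.append(ds)
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
    return datasets


def simulate_experiments(spec: ScenarioSpec) -> ExperimentSet:
    """Forward-simulate all tables of the scenario and add seeded noise.

    The per-point uncertainty column holds the true noise sigma:
    sigma_i = noise * max(|y_i|, 0.05 * max|y|) (a floor keeps weights
    finite where the observable itself crosses zero).  With noise = 0 the
    tables equal the forward-model output exactly and sigmas fall back to
    1% of the dataset scale.
    """
    rng = np.random.default_rng(spec.seed)
    datasets = _noiseless_datasets(spec)
    for ds in datasets:
        y = ds.table["value"].to_numpy()
        scale = np.max(np.abs(y)) if len(y) else 1.0
        floor = 0.05 * scale if scale > 0 else 1.0
        sigma = max(spec.noise, 1e-2) * np.maximum(np.abs(y), floor)
        ds.table["sigma"] = sigma
        if spec.noise > 0:
            true_sigma = spec.noise * np.maximum(np.abs(y), floor)
            ds.table["value"] = y + rng.normal(size=len(y)) * true_sigma
    return ExperimentSet(datasets)


def generate(spec: ScenarioSpec, out_dir: str | Path) -> ExperimentSet:
    """Write the scenario's tables and a ground-truth manifest to disk.

    Tables are tab-delimited text with a header row; the manifest records
    the full ground truth (parameters, scheme, noise, seed) so recovery
    tests can compare against it.  Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    experiments = simulate_experiments(spec)
    files = []
    for i, ds in enumerate(experiments):
        fname = f"{spec.name}_{i:02d}_{ds.kind}.tsv"
        ds.table.to_csv(out / fname, sep="\t", index=False, float_format="%.10g")
        files.append({"file": fname, "kind": ds.kind, "name": ds.name,
                      "conditions": ds.conditions})
    manifest = {"scenario": spec.name, "scheme": spec.scheme,
                "noise": spec.noise, "seed": spec.seed,
                "conc_series_M": list(spec.conc_series),
                "inhibitor_series_M": list(spec.inhibitor_series),
                "reference_conc_M": spec.reference_conc,
                "ground_truth": {k: v for k, v in spec.params.items()},
                "datasets": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return experiments


def load_experiments(directory: str | Path) -> tuple[ExperimentSet, dict]:
    """Read back a generated directory; returns (experiments, manifest)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    datasets = []
    for entry in manifest["datasets"]:
        tab = pd.read_csv(directory / entry["file"], sep="\t")
        datasets.append(Dataset(entry["kind"], tab,
                                conditions=entry.get("conditions") or {},
                                name=entry.get("name", "")))
    return ExperimentSet(datasets), manifest
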