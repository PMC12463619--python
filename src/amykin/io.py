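"""Configuration parsing, unit handling and experiment-table IO.

Configs are YAML documents with up to five sections — ``equilibrium``,
``kinetics``, ``exchange``, ``observables``, ``fitting`` — plus a
``conditions`` section for totals.  Scalar values may carry units
("70 mM", "750 us", "60.8 MHz"); everything is converted to base
SI-molar units on parse.  Unknown sections or keys are rejected so that a
typo cannot silently fall back to a default.

Experiment tables are tab- or comma-delimited text with a header row; one
schema per dataset type (see ``TABLE_SCHEMAS``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .inference import DEFAULT_PARAMS, Dataset
from .units import UnitError, parse_quantity

__all__ = ["Config", "ConfigError", "parse_config", "read_experiment_table",
           "write_experiment_table", "TABLE_SCHEMAS"]


class ConfigError(ValueError):
    """Malformed configuration: the message names the offending key."""


# section -> key -> (dimension or None, flat parameter name or None)
_SCHEMA: dict[str, dict[str, tuple[str | None, str | None]]] = {
    "equilibrium": {
        "kd1": ("concentration", "kd1"),
        "kd1_star": ("concentration", "kd1_star"),
        "kd2": ("concentration", "kd2"),
        "kd_mi": ("concentration", "kd_mi"),
        "kd_pi": ("concentration", "kd_pi"),
    },
    "conditions": {
        "p_tot": ("concentration", None),
        "i_tot": ("concentration", None),
        "temperature": ("temperature", None),
    },
    "exchange": {
        "tau_m_dstar": ("time", "tau_m_dstar"),
        "tau_m_t": ("time", "tau_m_t"),
        "delta_d": ("shift", "delta_d"),
        "delta_dstar": ("shift", "delta_dstar"),
        "delta_t": ("shift", "delta_t"),
        "r2_0": (None, "r2_0"),
        "r1": (None, "r1"),
        "frequency_mhz": (None, "frequency_mhz"),
        "topology": (None, "topology"),
        "t_relax": ("time", "t_relax"),
    },
    "kinetics": {
        "k_conv": (None, "k_conv"),
        "k_e": (None, "k_e"),
        "k_2": (None, "k_2"),
        "n_2": (None, "n_2"),
        "n_c": (None, "n_c"),
        "p0": ("concentration", "p0"),
        "scheme": (None, None),
        "koff_mi": (None, None),
        "koff_pi": (None, None),
        "fast_relax": (None, None),
    },
    "observables": {
        "r2_ref": (None, "r2_ref"),
    },
    "fitting": {
        "free": (None, None),
        "n_starts": (None, None),
        "seed": (None, None),
        "noise": (None, None),
    },
}

_STRING_KEYS = {"topology", "scheme"}
_PASSTHROUGH_KEYS = {"free", "n_starts", "seed", "noise", "n_c"}


@dataclass
class Config:
    """Parsed configuration with all scalars in base units."""

    sections: dict[str, dict] = field(default_factory=dict)
    source: Path | None = None

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    def params(self) -> dict:
        """Flatten into the shared forward-model parameter mapping."""
        out = dict(DEFAULT_PARAMS)
        for section, keys in _SCHEMA.items():
            present = self.sections.get(section, {})
            for key, (_, param) in keys.items():
                if param is not None and key in present:
                    out[param] = present[key]
        return out

    def totals(self) -> tuple[float, float]:
        cond = self.sections.get("conditions", {})
        return cond.get("p_tot", 0.0), cond.get("i_tot", 0.0)

    @property
    def scheme(self) -> str:
        return self.get("kinetics", "scheme", "none")

    def to_yaml(self, path: str | Path) -> None:
        """Serialize with values in base units; parse(to_yaml(c)) == c."""
        Path(path).write_text(yaml.safe_dump(self.sections, sort_keys=True))

    def sha256(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.sections, sort_keys=True).encode()).hexdigest()


def parse_config(path: str | Path) -> Config:
    """Parse and validate a YAML config file.

    Raises :class:`ConfigError` naming the offending section/key for
    unknown keys, unknown units, or malformed values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    sections: dict[str, dict] = {}
    for section, content in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown section {section!r} "
                              f"(expected one of {sorted(_SCHEMA)})")
        if content is None:
            sections[section] = {}
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        parsed = {}
        for key, value in content.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key {section}.{key!r}")
            dim, _ = _SCHEMA[section][key]
            if key in _STRING_KEYS or key in _PASSTHROUGH_KEYS \
                    or isinstance(value, (list, dict, bool)):
                parsed[key] = value
                continue
            try:
                parsed[key] = parse_quantity(value, expect=dim)
            except UnitError as exc:
                raise ConfigError(f"{section}.{key}: {exc}") from exc
        sections[section] = parsed
    return Config(sections=sections, source=path)


# ---------------------------------------------------------------------------
# experiment tables

#: independent-variable column per dataset type (all types also require
#: value and sigma columns; delta_ex and vi carry conditions per row)
TABLE_SCHEMAS = {
    "delta_ex": ("p_tot_M", ["p_tot_M", "i_tot_M", "value", "sigma"]),
    "vi": ("p_tot_M", ["p_tot_M", "i_tot_M", "value", "sigma"]),
    "r1rho": ("omega1_hz", ["omega1_hz", "value", "sigma"]),
    "cpmg": ("nu_cpmg_hz", ["nu_cpmg_hz", "value", "sigma"]),
    "prd_decay": ("t_s", ["t_s", "value", "sigma"]),
}


def read_experiment_table(path: str | Path, kind: str,
                          conditions: dict | None = None) -> Dataset:
    """Read a delimited table, validate its schema and sort the abscissa.

    Duplicate abscissa values (replicates) are allowed and preserved.
    Schema violations raise ``ValueError`` listing the offending columns or
    rows.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown dataset kind {kind!r}")
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    x_col, required = TABLE_SCHEMAS[kind]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    bad = table.index[~(table["sigma"] > 0)].tolist()
    if bad:
        raise ValueError(f"{path.name}: non-positive sigma in rows {bad}")
    table = table.sort_values(x_col, kind="stable").reset_index(drop=True)
    return Dataset(kind, table, conditions=conditions or {}, name=path.stem)


def write_experiment_table(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    dataset.table.to_csv(path, sep=sep, index=False, float_format="%.10g")
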