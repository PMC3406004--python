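"""Scenario configuration: TOML blocks with strict key validation.

A scenario file has blocks ``[enzyme]``, ``[pk_parameters]`` and
``[simulation]``, plus optional ``[evaluation]`` and ``[thresholds]`` blocks
for the reporting commands.  Units follow the package conventions throughout:
concentrations in µM, volumes in L, rate constants in min^-1, times in min,
doses in µg.  Unknown keys are rejected so silent typos cannot change a run.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .enzyme_eval import get_enzyme
from .pk_core import (
    REFERENCE_PK_PARAMS,
    EnzymeKinetics,
    PKParameters,
    SimulationSpec,
)

__all__ = ["ConfigError", "RunConfig", "load_config"]

_SCHEMA = {
    "enzyme": {"name", "k_cat", "K_M", "E_conc"},
    "pk_parameters": {"V_p", "V_b", "K_pb", "K_bp"},
    "simulation": {"C1_0", "dose_ug", "t_end", "dt", "n_points", "rtol", "atol"},
    "evaluation": {"enzymes", "doses", "E_conc", "criterion"},
    "thresholds": {"peak", "auc"},
}


class ConfigError(ValueError):
    """Invalid configuration (unknown key, missing field, bad value)."""


@dataclass
class RunConfig:
    """Validated scenario configuration."""

    enzyme: EnzymeKinetics
    params: PKParameters
    spec: SimulationSpec
    evaluation: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


def _check_keys(table: dict, block: str) -> None:
    unknown = set(table) - _SCHEMA[block]
    if unknown:
        raise ConfigError(
            f"[{block}]: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(_SCHEMA[block])}"
        )


def load_config(path) -> RunConfig:
    """Parse and validate a scenario TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown_blocks = set(raw) - set(_SCHEMA)
    if unknown_blocks:
        raise ConfigError(f"unknown block(s) {sorted(unknown_blocks)}")
    for block in raw:
        if not isinstance(raw[block], dict):
            raise ConfigError(f"[{block}] must be a table")
        _check_keys(raw[block], block)

    enz_tbl = raw.get("enzyme", {})
    try:
        if {"k_cat", "K_M"} <= set(enz_tbl):
            enzyme = EnzymeKinetics(
                name=enz_tbl.get("name", "custom"),
                k_cat=float(enz_tbl["k_cat"]),
                K_M=float(enz_tbl["K_M"]),
                E_conc=float(enz_tbl.get("E_conc", 0.035)),
            )
        elif "name" in enz_tbl:
            enzyme = get_enzyme(enz_tbl["name"], enz_tbl.get("E_conc"))
        else:
            raise ConfigError(
                "[enzyme] needs either a panel 'name' or explicit k_cat/K_M"
            )
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"[enzyme]: {exc}") from exc

    pk_tbl = raw.get("pk_parameters")
    if pk_tbl is None:
        params = REFERENCE_PK_PARAMS
    else:
        missing = _SCHEMA["pk_parameters"] - set(pk_tbl)
        if missing:
            raise ConfigError(f"[pk_parameters]: missing {sorted(missing)}")
        try:
            params = PKParameters(**{k: float(v) for k, v in pk_tbl.items()})
        except ValueError as exc:
            raise ConfigError(f"[pk_parameters]: {exc}") from exc

    sim_tbl = dict(raw.get("simulation", {}))
    dose = sim_tbl.pop("dose_ug", None)
    try:
        if dose is not None:
            if "C1_0" in sim_tbl:
                raise ConfigError(
                    "[simulation]: give either C1_0 or dose_ug, not both"
                )
            spec = SimulationSpec.from_dose(float(dose), params, **sim_tbl)
        else:
            spec = SimulationSpec(**sim_tbl)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[simulation]: {exc}") from exc

    return RunConfig(
        enzyme=enzyme,
        params=params,
        spec=spec,
        evaluation=dict(raw.get("evaluation", {})),
        thresholds=dict(raw.get("thresholds", {})),
    )
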