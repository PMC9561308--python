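"""Configuration loading, dot-path overrides and model-object assembly.

The packaged ``data/base_case.yaml`` mirrors the base-case parameter
table field for field; every analysis (base case, one-way DSA, PSA, CLI
runs) starts from a configuration dictionary of that shape, so a single
override mechanism serves them all.  Parameters that carry a sensitivity
range are stored as ``{base, low, high, dist}`` mappings; scalars are
stored plain.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any, Mapping

import yaml

from .model import (
    AdverseEvent,
    AEProfile,
    CostSet,
    DrugComponent,
    EconParams,
    Strategy,
    UtilitySet,
)
from .survival import ParametricSurvival

__all__ = [
    "load_config",
    "default_config",
    "apply_overrides",
    "get_path",
    "set_path",
    "base_value",
    "build_econ",
    "build_strategy",
    "build_costs",
    "build_utilities",
    "run_base_case",
]


class ConfigError(ValueError):
    """Malformed configuration or unresolvable override path."""


def default_config() -> dict:
    """The packaged base-case configuration as a fresh dict."""
    text = resources.files("psmcea").joinpath("data/base_case.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | None = None) -> dict:
    """Load a YAML/JSON configuration file, or the packaged base case."""
    if path is None:
        return default_config()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration root must be a mapping")
    return cfg


def base_value(node: Any) -> Any:
    """The working value of a config leaf (its ``base`` if it has a range)."""
    if isinstance(node, Mapping) and "base" in node:
        return node["base"]
    return node


def get_path(cfg: Mapping, path: str) -> Any:
    node: Any = cfg
    for part in path.split("."):
        if not isinstance(node, Mapping) or part not in node:
            raise ConfigError(f"config path not found: {path!r} (at {part!r})")
        node = node[part]
    return node


def set_path(cfg: dict, path: str, value: Any) -> None:
    """Set a dot-path leaf in place; for ranged leaves, sets the ``base``."""
    parts = path.split(".")
    node: Any = cfg
    for part in parts[:-1]:
        if not isinstance(node, Mapping) or part not in node:
            raise ConfigError(f"config path not found: {path!r} (at {part!r})")
        node = node[part]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigError(f"config path not found: {path!r} (at {leaf!r})")
    if isinstance(node[leaf], dict) and "base" in node[leaf]:
        node[leaf]["base"] = value
    else:
        node[leaf] = value


def apply_overrides(cfg: Mapping, overrides: Mapping[str, Any] | None) -> dict:
    """Return a deep copy of ``cfg`` with dot-path overrides applied."""
    out = copy.deepcopy(dict(cfg))
    for path, value in (overrides or {}).items():
        set_path(out, path, value)
    return out


# ---------------------------------------------------------------------------
# Object assembly


def build_econ(cfg: Mapping) -> EconParams:
    e = cfg["econ"]
    return EconParams(
        cycle_length_days=float(e["cycle_length_days"]),
        horizon_years=float(e["horizon_years"]),
        annual_discount_rate=float(base_value(e["annual_discount_rate"])),
        wtp_per_qaly=float(e["wtp_per_qaly"]),
        bsa_m2=float(base_value(e["bsa_m2"])),
        month_days=float(e["month_days"]),
        half_cycle_correction=bool(e.get("half_cycle_correction", False)),
        occupancy=str(e.get("occupancy", "partitioned")),
    )


def _build_survival(node: Mapping) -> ParametricSurvival:
    return ParametricSurvival(
        family=str(node["family"]),
        shape=float(node["shape"]),
        scale=float(node["scale"]),
    )


def build_strategy(cfg: Mapping, arm: str) -> Strategy:
    try:
        s = cfg["strategies"][arm]
        surv = cfg["survival"][arm]
    except KeyError as exc:
        raise ConfigError(f"unknown strategy {arm!r}") from exc
    components = []
    for name, spec in s["components"].items():
        try:
            price = float(base_value(cfg["drug_prices"][name]))
        except KeyError as exc:
            raise ConfigError(f"no price listed for drug {name!r}") from exc
        components.append(
            DrugComponent(
                name=name,
                price_per_mg=price,
                dose_rule=str(spec["dose_rule"]),
                dose=float(spec["dose"]),
                administrations_per_cycle=float(spec.get("administrations_per_cycle", 1.0)),
                weight=float(base_value(spec.get("weight", 1.0))),
            )
        )
    events = []
    for name, inc in s.get("ae_incidence", {}).items():
        events.append(
            AdverseEvent(
                name=name,
                incidence=float(base_value(inc)),
                cost_per_cycle=float(base_value(cfg["ae_costs"][name])),
                disutility=float(base_value(cfg["ae_disutilities"][name])),
            )
        )
    return Strategy(
        name=str(s.get("label", arm)),
        components=tuple(components),
        treatment_duration_cycles=int(round(base_value(s["treatment_duration_cycles"]))),
        ae_profile=AEProfile(tuple(events)),
        os_model=_build_survival(surv["os"]),
        pfs_model=_build_survival(surv["pfs"]),
    )


def build_costs(cfg: Mapping) -> CostSet:
    oc = cfg["other_costs"]
    return CostSet(
        followup_per_cycle=float(base_value(oc["followup_per_cycle"])),
        bsc_per_cycle=float(base_value(oc["bsc_per_cycle"])),
    )


def build_utilities(cfg: Mapping) -> UtilitySet:
    u = cfg["utilities"]
    return UtilitySet(u_pfd=float(base_value(u["pfd"])), u_pd=float(base_value(u["pd"])))


def run_base_case(cfg: Mapping | None = None, overrides: Mapping[str, Any] | None = None):
    """Run both arms and the incremental analysis for a configuration.

    Returns the :class:`~psmcea.cea.CEResult` for LP versus chemotherapy.
    """
    from .cea import incremental_analysis
    from .model import run_arm

    cfg = apply_overrides(cfg if cfg is not None else default_config(), overrides)
    econ = build_econ(cfg)
    costs = build_costs(cfg)
    utils = build_utilities(cfg)
    lp = run_arm(build_strategy(cfg, "lp"), costs, utils, econ)
    chemo = run_arm(build_strategy(cfg, "chemo"), costs, utils, econ)
    return incremental_analysis(lp, chemo, econ)
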