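"""Analysis configuration: loading, validation and serialization.

An :class:`AnalysisConfig` bundles everything one model run needs — global
settings, utilities, costs, the three strategy arms and the sensitivity
specification (deterministic ranges and probabilistic distributions per
parameter).  The shipped fixture ``data/taiwan_icc_2022.yaml`` carries the
published model inputs for second-line pemigatinib versus mFOLFOX and 5-FU
in advanced intrahepatic cholangiocarcinoma, priced in 2022 NT$ from the
single-payer (NHIA) perspective.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .engine import (
    ArmOutcomes,
    CostInputs,
    ModelSettings,
    StrategyArm,
    UtilityInputs,
    run_arm,
)
from .survival import SurvivalDist

__all__ = [
    "ParamSpec",
    "AnalysisConfig",
    "ConfigError",
    "load_config",
    "load_default_config",
    "save_config",
    "config_to_dict",
    "config_checksum",
    "evaluate_arms",
]

PSA_DISTRIBUTIONS = ("normal", "gamma_ms", "beta", "uniform", "fixed")


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration."""


@dataclass(frozen=True)
class ParamSpec:
    """Sensitivity specification for one model parameter.

    ``paths`` lists the config locations the parameter writes to (several
    arms can share one cost parameter).  ``dist`` names the probabilistic
    sampling law: ``normal(mean, sd)``, ``gamma_ms(mean, sd)`` moment-matched
    to shape/scale, ``beta(alpha, beta)``, ``uniform(lo, hi)`` or ``fixed``
    (excluded from probabilistic sampling).  ``positive`` marks normal draws
    that must be resampled when non-positive.
    """

    name: str
    paths: tuple
    dsa_low: float | None = None
    dsa_high: float | None = None
    dist: str = "fixed"
    args: tuple = ()
    positive: bool = False

    def __post_init__(self):
        if self.dist not in PSA_DISTRIBUTIONS:
            raise ConfigError(
                f"sensitivity.{self.name}: unknown distribution {self.dist!r}"
            )
        if self.dsa_low is not None and self.dsa_high is not None:
            if self.dsa_low > self.dsa_high:
                raise ConfigError(f"sensitivity.{self.name}: dsa_low > dsa_high")
        if not self.paths:
            raise ConfigError(f"sensitivity.{self.name}: empty paths")


@dataclass(frozen=True)
class AnalysisConfig:
    """Complete, validated input set for one cost-effectiveness analysis."""

    settings: ModelSettings
    utilities: UtilityInputs
    costs: CostInputs
    arms: dict
    intervention: str
    comparators: tuple
    param_specs: tuple = ()
    seed: int = 2022

    def __post_init__(self):
        if self.intervention not in self.arms:
            raise ConfigError(f"intervention {self.intervention!r} not among arms")
        for c in self.comparators:
            if c not in self.arms:
                raise ConfigError(f"comparator {c!r} not among arms")
        for spec in self.param_specs:
            for path in spec.paths:
                try:
                    get_path(self, path)
                except Exception as exc:
                    raise ConfigError(
                        f"sensitivity.{spec.name}: bad path {list(path)}: {exc}"
                    ) from exc

    def arm(self, name: str) -> StrategyArm:
        return self.arms[name]

    def base_value(self, spec: ParamSpec) -> float:
        return get_path(self, spec.paths[0])

    def spec(self, name: str) -> ParamSpec:
        for s in self.param_specs:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# immutable path access (dataclasses / dicts / tuples)
# ---------------------------------------------------------------------------

def get_path(obj, path):
    """Read a nested value addressed by a path of field names / keys / indices."""
    for step in path:
        if dataclasses.is_dataclass(obj) and isinstance(step, str):
            obj = getattr(obj, step)
        elif isinstance(obj, dict):
            obj = obj[step]
        elif isinstance(obj, (tuple, list)):
            obj = obj[int(step)]
        else:
            raise KeyError(f"cannot descend into {type(obj).__name__} via {step!r}")
    return obj


def set_path(obj, path, value):
    """Return a copy of ``obj`` with the value at ``path`` replaced."""
    if not path:
        return value
    step, rest = path[0], path[1:]
    if dataclasses.is_dataclass(obj) and isinstance(step, str):
        new_child = set_path(getattr(obj, step), rest, value)
        return replace(obj, **{step: new_child})
    if isinstance(obj, dict):
        new = dict(obj)
        new[step] = set_path(obj[step], rest, value)
        return new
    if isinstance(obj, (tuple, list)):
        idx = int(step)
        items = list(obj)
        items[idx] = set_path(items[idx], rest, value)
        return tuple(items) if isinstance(obj, tuple) else items
    raise KeyError(f"cannot descend into {type(obj).__name__} via {step!r}")


def apply_value(config: AnalysisConfig, spec: ParamSpec, value) -> AnalysisConfig:
    """Write ``value`` into every config location ``spec`` addresses."""
    for path in spec.paths:
        config = set_path(config, path, value)
    return config


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

_REQUIRED_TOP = ("settings", "utilities", "costs", "arms", "intervention", "comparators")
_ARM_FIELDS = (
    "os",
    "pfs",
    "medication_cost_per_year",
    "nonmedication_cost_per_year",
    "ae_grade3_proportion",
)


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        import warnings

        warnings.warn(f"{section}: ignoring unknown keys {sorted(unknown)}")
    try:
        return cls(**{k: v for k, v in data.items() if k in allowed})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def _parse_dist(data: dict, where: str) -> SurvivalDist:
    for key in ("family", "params"):
        if key not in data:
            raise ConfigError(f"{where}: missing key {key!r}")
    try:
        return SurvivalDist(
            family=data["family"],
            params=tuple(data["params"]),
            label=data.get("label", ""),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_arm(name: str, data: dict) -> StrategyArm:
    missing = [k for k in _ARM_FIELDS if k not in data]
    if missing:
        raise ConfigError(f"arms.{name}: missing keys {missing}")
    try:
        return StrategyArm(
            name=name,
            os=_parse_dist(data["os"], f"arms.{name}.os"),
            pfs=_parse_dist(data["pfs"], f"arms.{name}.pfs"),
            medication_cost_per_year=float(data["medication_cost_per_year"]),
            nonmedication_cost_per_year=float(data["nonmedication_cost_per_year"]),
            ae_grade3_proportion=float(data["ae_grade3_proportion"]),
            iv_administered=bool(data.get("iv_administered", False)),
            requires_genetic_testing=bool(data.get("requires_genetic_testing", False)),
        )
    except ValueError as exc:
        raise ConfigError(f"arms.{name}: {exc}") from exc


def _parse_param_spec(name: str, data: dict) -> ParamSpec:
    if "paths" not in data:
        raise ConfigError(f"sensitivity.{name}: missing key 'paths'")
    paths = tuple(tuple(p) for p in data["paths"])
    psa = data.get("psa", {}) or {}
    dsa = data.get("dsa", None)
    return ParamSpec(
        name=name,
        paths=paths,
        dsa_low=None if dsa is None else float(dsa[0]),
        dsa_high=None if dsa is None else float(dsa[1]),
        dist=psa.get("dist", "fixed"),
        args=tuple(float(a) for a in psa.get("args", ())),
        positive=bool(psa.get("positive", False)),
    )


def config_from_dict(raw: dict) -> AnalysisConfig:
    if not raw:
        raise ConfigError(
            "empty configuration; required sections: " + ", ".join(_REQUIRED_TOP)
        )
    missing = [k for k in _REQUIRED_TOP if k not in raw]
    if missing:
        raise ConfigError(f"missing required sections: {missing}")
    arms = {name: _parse_arm(name, d) for name, d in raw["arms"].items()}
    specs = tuple(
        _parse_param_spec(name, d) for name, d in (raw.get("sensitivity") or {}).items()
    )
    return AnalysisConfig(
        settings=_build_section(ModelSettings, raw["settings"], "settings"),
        utilities=_build_section(UtilityInputs, raw["utilities"], "utilities"),
        costs=_build_section(CostInputs, raw["costs"], "costs"),
        arms=arms,
        intervention=raw["intervention"],
        comparators=tuple(raw["comparators"]),
        param_specs=specs,
        seed=int(raw.get("seed", 2022)),
    )


def config_to_dict(config: AnalysisConfig) -> dict:
    def dist_d(d: SurvivalDist):
        out = {"family": d.family, "params": list(d.params)}
        if d.label:
            out["label"] = d.label
        return out

    raw = {
        "settings": dataclasses.asdict(config.settings),
        "utilities": dataclasses.asdict(config.utilities),
        "costs": dataclasses.asdict(config.costs),
        "arms": {
            name: {
                "os": dist_d(a.os),
                "pfs": dist_d(a.pfs),
                "medication_cost_per_year": a.medication_cost_per_year,
                "nonmedication_cost_per_year": a.nonmedication_cost_per_year,
                "ae_grade3_proportion": a.ae_grade3_proportion,
                "iv_administered": a.iv_administered,
                "requires_genetic_testing": a.requires_genetic_testing,
            }
            for name, a in config.arms.items()
        },
        "intervention": config.intervention,
        "comparators": list(config.comparators),
        "seed": config.seed,
    }
    if config.param_specs:
        raw["sensitivity"] = {
            s.name: {
                "paths": [list(p) for p in s.paths],
                **(
                    {"dsa": [s.dsa_low, s.dsa_high]}
                    if s.dsa_low is not None
                    else {}
                ),
                "psa": {
                    "dist": s.dist,
                    "args": list(s.args),
                    **({"positive": True} if s.positive else {}),
                },
            }
            for s in config.param_specs
        }
    return raw


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration."""
    with open(path, "r") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


def load_default_config() -> AnalysisConfig:
    """The shipped fixture: published Taiwan 2022 model inputs."""
    ref = resources.files("psmcea").joinpath("data/taiwan_icc_2022.yaml")
    raw = yaml.safe_load(ref.read_text())
    return config_from_dict(raw)


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_checksum(config: AnalysisConfig) -> str:
    """SHA-256 of the canonical JSON form, for run logs."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def evaluate_arms(config: AnalysisConfig) -> dict[str, ArmOutcomes]:
    """Run the partitioned-survival model for every configured arm."""
    return {
        name: run_arm(arm, config.costs, config.utilities, config.settings)
        for name, arm in config.arms.items()
    }
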