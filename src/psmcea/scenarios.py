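"""Scenario analyses: price-reduction grid and structural variants.

The scenario battery mirrors the published analysis plan: a gradual 10%
price reduction of the intervention drug, measuring effectiveness in
life-years instead of QALYs, applying a conversion factor to
non-medication costs, spreading the adverse-event disutility over the
first six months or the whole horizon, and swapping in alternative
survival laws (supported structurally; alternative fits must be supplied).

A price multiplier scales the intervention's annual medication cost *and*
the bounds of its uniform sampling distribution, so probabilistic results
under a price cut remain centred on the reduced price.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cea
from .config import AnalysisConfig, ConfigError, apply_value, evaluate_arms, set_path
from .survival import SurvivalDist
from .uncertainty import PsaResult, run_psa

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "apply_scenario",
    "run_scenario",
    "price_reduction_grid",
    "default_battery",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Named bundle of config overrides defining one scenario."""

    name: str
    price_multiplier: float = 1.0
    effect_measure: str = "qaly"
    ae_duration_mode: str | None = None
    conversion_factor: float | None = None
    horizon_years: float | None = None
    discount_rate: float | None = None
    # {(arm, "os"|"pfs"): SurvivalDist} replacements, e.g. second-best fits
    survival_overrides: tuple = ()

    def __post_init__(self):
        if not 0 <= self.price_multiplier <= 1:
            raise ConfigError("price_multiplier must be in [0, 1]")
        if self.effect_measure not in ("qaly", "ly"):
            raise ConfigError(f"unknown effect_measure {self.effect_measure!r}")


def _scale_price_spec(config: AnalysisConfig, multiplier: float) -> AnalysisConfig:
    """Scale the intervention medication-cost sensitivity spec with the price."""
    new_specs = []
    target_path = ("arms", config.intervention, "medication_cost_per_year")
    for s in config.param_specs:
        if target_path in tuple(s.paths):
            s = replace(
                s,
                args=tuple(a * multiplier for a in s.args),
                dsa_low=None if s.dsa_low is None else s.dsa_low * multiplier,
                dsa_high=None if s.dsa_high is None else s.dsa_high * multiplier,
            )
        new_specs.append(s)
    return replace(config, param_specs=tuple(new_specs))


def apply_scenario(config: AnalysisConfig, spec: ScenarioSpec) -> AnalysisConfig:
    """Return the config with all scenario overrides applied."""
    cfg = config
    if spec.price_multiplier != 1.0:
        arm = cfg.arms[cfg.intervention]
        cfg = set_path(
            cfg,
            ("arms", cfg.intervention, "medication_cost_per_year"),
            arm.medication_cost_per_year * spec.price_multiplier,
        )
        cfg = _scale_price_spec(cfg, spec.price_multiplier)
    if spec.ae_duration_mode is not None:
        cfg = set_path(cfg, ("utilities", "ae_duration_mode"), spec.ae_duration_mode)
    if spec.conversion_factor is not None:
        cfg = set_path(
            cfg, ("costs", "nonmedication_conversion_factor"), spec.conversion_factor
        )
        # under this scenario the conversion factor is itself uncertain
        from .config import ParamSpec

        names = {s.name for s in cfg.param_specs}
        if "conversion_factor" not in names:
            cfg = replace(
                cfg,
                param_specs=cfg.param_specs
                + (
                    ParamSpec(
                        name="conversion_factor",
                        paths=(("costs", "nonmedication_conversion_factor"),),
                        dist="uniform",
                        args=(0.8, 1.0),
                    ),
                ),
            )
    if spec.horizon_years is not None:
        cfg = set_path(cfg, ("settings", "horizon_years"), spec.horizon_years)
    if spec.discount_rate is not None:
        cfg = set_path(cfg, ("settings", "annual_discount_rate"), spec.discount_rate)
    for (arm_name, endpoint), dist in spec.survival_overrides:
        if arm_name not in cfg.arms or endpoint not in ("os", "pfs"):
            raise ConfigError(f"unknown survival override target {(arm_name, endpoint)}")
        if not isinstance(dist, SurvivalDist):
            raise ConfigError("survival override must be a SurvivalDist")
        cfg = set_path(cfg, ("arms", arm_name, endpoint), dist)
    return cfg


@dataclass
class ScenarioResult:
    """Deterministic and probabilistic outputs of one scenario."""

    name: str
    spec: ScenarioSpec
    deterministic: pd.DataFrame   # per comparator: increments, ICER, INMB
    psa: PsaResult | None

    def to_frame(self) -> pd.DataFrame:
        df = self.deterministic.copy()
        df.insert(0, "scenario", self.name)
        if self.psa is not None:
            psa = self.psa
            measure = self.spec.effect_measure
            df["p_cost_effective"] = [
                psa.prob_cost_effective(c, effect_measure=measure)
                for c in df["comparator"]
            ]
            df["evpi_per_person"] = [
                psa.evpi(c, effect_measure=measure) for c in df["comparator"]
            ]
        return df


def _deterministic_table(cfg: AnalysisConfig, measure: str) -> pd.DataFrame:
    outcomes = evaluate_arms(cfg)
    wtp = cfg.settings.wtp_per_qaly
    rows = []
    for comp in cfg.comparators:
        res = cea.icer(
            outcomes[cfg.intervention], outcomes[comp], effect_measure=measure, wtp=wtp
        )
        rows.append(
            {
                "comparator": comp,
                "effect_measure": measure,
                "delta_cost": res.delta_cost,
                "delta_effect": res.delta_effect,
                "icer": res.icer,
                "dominance": res.dominance,
                "inmb": res.inmb,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(
    config: AnalysisConfig,
    spec: ScenarioSpec,
    n_psa: int = 1000,
    seed: int | None = None,
) -> ScenarioResult:
    """Apply a scenario and produce deterministic + probabilistic results."""
    cfg = apply_scenario(config, spec)
    det = _deterministic_table(cfg, spec.effect_measure)
    psa = run_psa(cfg, n_iterations=n_psa, seed=seed) if n_psa > 0 else None
    return ScenarioResult(name=spec.name, spec=spec, deterministic=det, psa=psa)


def price_reduction_grid(
    config: AnalysisConfig,
    reductions=None,
    n_psa: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Deterministic and probabilistic results per price-reduction step.

    ``reductions`` are fractions of the intervention medication price removed
    (default 0 to 60% in 10% steps).  Returns one row per reduction and
    comparator with the ICER, INMB and probability of cost-effectiveness.
    """
    if reductions is None:
        reductions = np.round(np.arange(0.0, 0.61, 0.1), 10)
    frames = []
    for red in reductions:
        if not 0 <= red <= 1:
            raise ConfigError(f"price reduction {red} outside [0, 1]")
        spec = ScenarioSpec(
            name=f"price_reduction_{int(round(red * 100))}pct",
            price_multiplier=1.0 - float(red),
        )
        result = run_scenario(config, spec, n_psa=n_psa, seed=seed)
        df = result.to_frame()
        df.insert(1, "price_reduction", float(red))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def default_battery() -> list[ScenarioSpec]:
    """The published scenario list (minus price steps, which have their own grid)."""
    return [
        ScenarioSpec(name="base_case"),
        ScenarioSpec(name="life_years", effect_measure="ly"),
        ScenarioSpec(name="conversion_factor_0.9", conversion_factor=0.9),
        ScenarioSpec(name="ae_first_six_months", ae_duration_mode="first_six_months"),
        ScenarioSpec(name="ae_whole_horizon", ae_duration_mode="whole_horizon"),
    ]
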