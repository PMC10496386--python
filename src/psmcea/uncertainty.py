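"""Deterministic (tornado) and probabilistic sensitivity analysis.

Probabilistic sampling draws every parameter independently from its
configured distribution.  Gamma-distributed costs are specified as
(mean, SD) and moment-matched to shape/scale, because the first printed
argument of each cost distribution equals its base-case mean.  Normal draws
of strictly positive survival parameters are redrawn until positive.

Reproducibility: each parameter gets its own named random substream derived
from the master seed (CRC-32 of the parameter name mixed into the seed
sequence), so adding or removing one parameter never perturbs another's
draws, and a fixed seed reproduces the draw table bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cea
from .config import AnalysisConfig, ParamSpec, apply_value, evaluate_arms

__all__ = [
    "sample_params",
    "run_psa",
    "one_way_dsa",
    "PsaResult",
    "DsaRow",
]

_MAX_REDRAW_ROUNDS = 100


def _param_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(zlib.crc32(name.encode()),))
    )


def _draw(spec: ParamSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.dist == "normal":
        mean, sd = spec.args
        x = rng.normal(mean, sd, size=n)
        if spec.positive:
            for _ in range(_MAX_REDRAW_ROUNDS):
                bad = x <= 0
                if not bad.any():
                    break
                x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            else:
                raise RuntimeError(
                    f"{spec.name}: could not draw positive values from "
                    f"normal({mean}, {sd})"
                )
        return x
    if spec.dist == "gamma_ms":
        mean, sd = spec.args
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape=shape, scale=scale, size=n)
    if spec.dist == "beta":
        a, b = spec.args
        return rng.beta(a, b, size=n)
    if spec.dist == "uniform":
        lo, hi = spec.args
        return rng.uniform(lo, hi, size=n)
    raise ValueError(f"{spec.name}: no probabilistic distribution configured")


def sample_params(
    specs, n: int, seed: int
) -> pd.DataFrame:
    """Sample n independent joint parameter sets (one column per parameter)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = {}
    for spec in specs:
        if spec.dist == "fixed":
            continue
        cols[spec.name] = _draw(spec, n, _param_rng(seed, spec.name))
    return pd.DataFrame(cols)


@dataclass
class PsaResult:
    """Per-draw parameters and outcomes of a probabilistic analysis."""

    params: pd.DataFrame                  # n_draws x n_params
    outcomes: pd.DataFrame                # per draw: cost/qaly/ly per arm
    intervention: str
    comparators: tuple
    wtp: float
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.outcomes)

    def delta(self, comparator: str, quantity: str) -> np.ndarray:
        i, c = self.intervention, comparator
        return (
            self.outcomes[f"{quantity}_{i}"] - self.outcomes[f"{quantity}_{c}"]
        ).to_numpy()

    def inmb(
        self,
        comparator: str,
        wtp: float | None = None,
        effect_measure: str = "qaly",
    ) -> np.ndarray:
        w = self.wtp if wtp is None else wtp
        return w * self.delta(comparator, effect_measure) - self.delta(
            comparator, "cost"
        )

    def nmb(
        self, arm: str, wtp: float | None = None, effect_measure: str = "qaly"
    ) -> np.ndarray:
        w = self.wtp if wtp is None else wtp
        return (
            w * self.outcomes[f"{effect_measure}_{arm}"] - self.outcomes[f"cost_{arm}"]
        ).to_numpy()

    def prob_cost_effective(
        self,
        comparator: str,
        wtp: float | None = None,
        effect_measure: str = "qaly",
    ) -> float:
        return float(np.mean(self.inmb(comparator, wtp, effect_measure) > 0))

    def ceac(self, comparator: str, wtp_grid=None) -> list:
        grid = cea.default_wtp_grid(self.wtp) if wtp_grid is None else wtp_grid
        return cea.ceac(
            self.delta(comparator, "cost"), self.delta(comparator, "qaly"), grid
        )

    def evpi(
        self,
        comparator: str,
        wtp: float | None = None,
        effect_measure: str = "qaly",
    ) -> float:
        return cea.evpi(
            self.nmb(self.intervention, wtp, effect_measure),
            self.nmb(comparator, wtp, effect_measure),
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.comparators:
            rows.append(
                {
                    "comparator": c,
                    "mean_delta_cost": float(np.mean(self.delta(c, "cost"))),
                    "mean_delta_qaly": float(np.mean(self.delta(c, "qaly"))),
                    "mean_delta_ly": float(np.mean(self.delta(c, "ly"))),
                    "p_cost_effective": self.prob_cost_effective(c),
                    "evpi_per_person": self.evpi(c),
                    "wtp": self.wtp,
                    "n_draws": self.n_draws,
                }
            )
        return pd.DataFrame(rows)

    def draw_table(self) -> pd.DataFrame:
        """One row per draw: sampled parameters, outcomes, INMB per comparison."""
        out = pd.concat([self.params, self.outcomes], axis=1)
        for c in self.comparators:
            out[f"inmb_vs_{c}"] = self.inmb(c)
        return out


def run_psa(
    config: AnalysisConfig, n_iterations: int = 1000, seed: int | None = None
) -> PsaResult:
    """Monte-Carlo probabilistic sensitivity analysis over the full model."""
    master = config.seed if seed is None else seed
    specs = [s for s in config.param_specs if s.dist != "fixed"]
    params = sample_params(specs, n_iterations, master)
    by_name = {s.name: s for s in specs}

    records = []
    values = params.to_dict("records")
    for row in values:
        cfg = config
        for name, value in row.items():
            cfg = apply_value(cfg, by_name[name], float(value))
        outcomes = evaluate_arms(cfg)
        rec = {}
        for arm, o in outcomes.items():
            rec[f"cost_{arm}"] = o.cost_total
            rec[f"qaly_{arm}"] = o.qaly_total
            rec[f"ly_{arm}"] = o.ly_total
        records.append(rec)
    return PsaResult(
        params=params,
        outcomes=pd.DataFrame(records),
        intervention=config.intervention,
        comparators=config.comparators,
        wtp=config.settings.wtp_per_qaly,
        seed=master,
    )


@dataclass
class DsaRow:
    parameter: str
    base_value: float
    low: float
    high: float
    output_at_low: float
    output_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


def _dsa_output(
    config: AnalysisConfig, comparator: str, output: str
) -> float:
    outcomes = evaluate_arms(config)
    res = cea.icer(
        outcomes[config.intervention],
        outcomes[comparator],
        wtp=config.settings.wtp_per_qaly,
    )
    if output == "inmb":
        return res.inmb
    if output == "icer":
        return np.nan if res.icer is None else res.icer
    raise ValueError(f"unknown DSA output {output!r}")


def one_way_dsa(
    config: AnalysisConfig, comparator: str, output: str = "inmb"
) -> list[DsaRow]:
    """One-way tornado: vary each parameter to its bounds, all else at base.

    Returns rows sorted by swing (largest first) on the chosen output
    (incremental net monetary benefit by default, or the ICER).
    """
    rows = []
    for spec in config.param_specs:
        if spec.dsa_low is None:
            continue
        base = config.base_value(spec)
        at_low = _dsa_output(apply_value(config, spec, spec.dsa_low), comparator, output)
        at_high = _dsa_output(apply_value(config, spec, spec.dsa_high), comparator, output)
        rows.append(
            DsaRow(
                parameter=spec.name,
                base_value=base,
                low=spec.dsa_low,
                high=spec.dsa_high,
                output_at_low=at_low,
                output_at_high=at_high,
            )
        )
    rows.sort(key=lambda r: r.swing, reverse=True)
    return rows


def dsa_frame(rows: list[DsaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "base_value": [r.base_value for r in rows],
            "low": [r.low for r in rows],
            "high": [r.high for r in rows],
            "output_at_low": [r.output_at_low for r in rows],
            "output_at_high": [r.output_at_high for r in rows],
            "swing": [r.swing for r in rows],
        }
    )
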