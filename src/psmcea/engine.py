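"""Three-state partitioned-survival cohort engine.

State occupancy is read directly off the survival curves each cycle:

* progression-free  ``pf(t) = min(PFS(t), OS(t))``
* progressed        ``pd(t) = OS(t) - pf(t)``
* dead              ``1 - OS(t)``

Life-years, QALYs and costs accrue as (occupancy x rate x cycle length),
discounted continuously at ``(1+r)^(-t_years)``.  With the half-cycle
correction enabled (default) occupancy is evaluated at cycle midpoints,
i.e. the trapezoid/midpoint approximation to the underlying integrals;
disabled, it is evaluated at cycle ends.

Costs attach to states the way a single-payer perspective books them:
medication and non-medication outpatient costs to the progression-free
state (second-line therapy runs until progression), supportive care to the
progressed state, and a one-off companion-diagnostic (genetic testing) fee
at model start for arms that require biomarker confirmation.

Quality-of-life decrements: an administration-route disutility is applied
to the progression-free utility of intravenously treated arms; a one-off
grade>=3 adverse-event decrement (proportion x disutility x duration) is
applied in the first cycle by default, or per-cycle over the first six
months / the whole horizon in scenario variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd

from .survival import MONTHS_PER_YEAR, HybridSurvival, SurvivalDist

__all__ = [
    "ModelSettings",
    "UtilityInputs",
    "CostInputs",
    "StrategyArm",
    "CohortTrace",
    "ArmOutcomes",
    "state_occupancy",
    "accrue",
    "run_arm",
]

Curve = Union[SurvivalDist, HybridSurvival]

AE_DURATION_MODES = ("first_cycle", "first_six_months", "whole_horizon")
TESTING_POLICIES = ("none", "intervention_only", "all_arms")


@dataclass(frozen=True)
class ModelSettings:
    """Global decision-model settings (times in years, money in NT$)."""

    horizon_years: float = 5.0
    cycle_length_years: float = 1.0 / 12.0
    annual_discount_rate: float = 0.03
    wtp_per_qaly: float = 2_928_570.0
    half_cycle_correction: bool = True

    def __post_init__(self):
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if not 0 < self.cycle_length_years <= self.horizon_years:
            raise ValueError("cycle_length_years must be in (0, horizon]")
        if not 0 <= self.annual_discount_rate < 1:
            raise ValueError("annual_discount_rate must be in [0, 1)")
        if self.wtp_per_qaly < 0:
            raise ValueError("wtp_per_qaly must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and treatment disutilities."""

    u_pf: float = 0.76
    u_pd: float = 0.68
    disutility_ae: float = 0.16
    disutility_iv: float = 0.025
    ae_duration_mode: str = "first_cycle"

    def __post_init__(self):
        for name in ("u_pf", "u_pd", "disutility_ae", "disutility_iv"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ae_duration_mode not in AE_DURATION_MODES:
            raise ValueError(
                f"ae_duration_mode must be one of {AE_DURATION_MODES}, "
                f"got {self.ae_duration_mode!r}"
            )


@dataclass(frozen=True)
class CostInputs:
    """Arm-independent cost inputs (annual NT$ rates; fee is one-off)."""

    supportive_care_per_year: float = 497_710.0
    genetic_testing_fee: float = 30_000.0
    testing_fee_policy: str = "intervention_only"
    nonmedication_conversion_factor: float = 1.0

    def __post_init__(self):
        if self.supportive_care_per_year < 0 or self.genetic_testing_fee < 0:
            raise ValueError("cost rates must be >= 0")
        if self.testing_fee_policy not in TESTING_POLICIES:
            raise ValueError(
                f"testing_fee_policy must be one of {TESTING_POLICIES}, "
                f"got {self.testing_fee_policy!r}"
            )
        if not 0 < self.nonmedication_conversion_factor <= 1:
            raise ValueError("nonmedication_conversion_factor must be in (0, 1]")


@dataclass(frozen=True)
class StrategyArm:
    """One treatment strategy: survival curves plus arm-specific inputs."""

    name: str
    os: Curve
    pfs: Curve
    medication_cost_per_year: float
    nonmedication_cost_per_year: float
    ae_grade3_proportion: float
    iv_administered: bool = False
    requires_genetic_testing: bool = False

    def __post_init__(self):
        if self.medication_cost_per_year < 0 or self.nonmedication_cost_per_year < 0:
            raise ValueError("cost rates must be >= 0")
        if not 0 <= self.ae_grade3_proportion <= 1:
            raise ValueError("ae_grade3_proportion must be in [0, 1]")


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounting for one arm."""

    t_eval_years: np.ndarray    # evaluation time of each cycle (mid or end)
    t_end_years: np.ndarray     # cycle end times
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    discount: np.ndarray
    cycle_length_years: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_years": self.t_eval_years,
                "pf": self.pf,
                "pd": self.pd,
                "dead": self.dead,
                "discount": self.discount,
            }
        )


@dataclass
class ArmOutcomes:
    """Discounted totals for one arm over the model horizon."""

    arm: str
    ly_pf: float
    ly_total: float
    qaly_pf: float
    qaly_total: float
    cost_medication: float
    cost_nonmedication: float
    cost_testing: float
    cost_pd_supportive: float

    @property
    def cost_pf_total(self) -> float:
        return self.cost_medication + self.cost_nonmedication + self.cost_testing

    @property
    def cost_total(self) -> float:
        return self.cost_pf_total + self.cost_pd_supportive

    def effect(self, measure: str) -> float:
        if measure == "qaly":
            return self.qaly_total
        if measure == "ly":
            return self.ly_total
        raise ValueError(f"unknown effect measure {measure!r}")

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "ly_pf": self.ly_pf,
            "ly_total": self.ly_total,
            "qaly_pf": self.qaly_pf,
            "qaly_total": self.qaly_total,
            "cost_medication": self.cost_medication,
            "cost_nonmedication": self.cost_nonmedication,
            "cost_testing": self.cost_testing,
            "cost_pf_total": self.cost_pf_total,
            "cost_pd_supportive": self.cost_pd_supportive,
            "cost_total": self.cost_total,
        }


def state_occupancy(os: Curve, pfs: Curve, settings: ModelSettings) -> CohortTrace:
    """Evaluate partitioned state occupancy per cycle.

    PFS is clipped at OS so progressed-state occupancy is never negative
    (parametric PFS tails can cross the OS curve at long extrapolation).
    """
    dt = settings.cycle_length_years
    n = settings.n_cycles
    ends = dt * np.arange(1, n + 1)
    t_eval = ends - dt / 2.0 if settings.half_cycle_correction else ends
    months = t_eval * MONTHS_PER_YEAR
    s_os = np.asarray(os.survival(months), dtype=float)
    s_pfs = np.asarray(pfs.survival(months), dtype=float)
    pf = np.minimum(s_pfs, s_os)
    pd_ = s_os - pf
    dead = 1.0 - s_os
    disc = (1.0 + settings.annual_discount_rate) ** (-t_eval)
    return CohortTrace(
        t_eval_years=t_eval,
        t_end_years=ends,
        pf=pf,
        pd=pd_,
        dead=dead,
        discount=disc,
        cycle_length_years=dt,
    )


def _ae_qaly_loss(
    trace: CohortTrace, arm: StrategyArm, utilities: UtilityInputs
) -> float:
    """Discounted QALY loss from grade>=3 adverse events."""
    per_event = arm.ae_grade3_proportion * utilities.disutility_ae
    dt = trace.cycle_length_years
    mode = utilities.ae_duration_mode
    if mode == "first_cycle":
        # one-off decrement for the whole cohort in cycle 1
        return per_event * dt * trace.discount[0]
    alive = trace.pf + trace.pd
    if mode == "first_six_months":
        window = trace.t_end_years <= 0.5 + 1e-12
    else:  # whole_horizon
        window = np.ones_like(alive, dtype=bool)
    return per_event * float(
        np.sum(alive[window] * dt * trace.discount[window])
    )


def accrue(
    trace: CohortTrace,
    arm: StrategyArm,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> ArmOutcomes:
    """Accrue discounted life-years, QALYs and costs over a cohort trace."""
    dt = trace.cycle_length_years
    w = dt * trace.discount  # discounted cycle weights

    pf_years = float(np.sum(trace.pf * w))
    pd_years = float(np.sum(trace.pd * w))

    u_pf = utilities.u_pf - (utilities.disutility_iv if arm.iv_administered else 0.0)
    qaly_pf = u_pf * pf_years - _ae_qaly_loss(trace, arm, utilities)
    qaly_pd = utilities.u_pd * pd_years

    fee = 0.0
    if costs.testing_fee_policy == "all_arms" or (
        costs.testing_fee_policy == "intervention_only" and arm.requires_genetic_testing
    ):
        fee = costs.genetic_testing_fee  # charged at t = 0, undiscounted

    conv = costs.nonmedication_conversion_factor
    return ArmOutcomes(
        arm=arm.name,
        ly_pf=pf_years,
        ly_total=pf_years + pd_years,
        qaly_pf=qaly_pf,
        qaly_total=qaly_pf + qaly_pd,
        cost_medication=arm.medication_cost_per_year * pf_years,
        cost_nonmedication=arm.nonmedication_cost_per_year * conv * pf_years,
        cost_testing=fee,
        cost_pd_supportive=costs.supportive_care_per_year * pd_years,
    )


def run_arm(
    arm: StrategyArm,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> ArmOutcomes:
    """Convenience composition: occupancy then accrual for one arm."""
    trace = state_occupancy(arm.os, arm.pfs, settings)
    return accrue(trace, arm, costs, utilities, settings)
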