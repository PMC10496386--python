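"""Incremental cost-effectiveness metrics: ICER, (I)NMB, CEAC and EVPI.

Conventions
-----------
* ICER = delta-cost / delta-effect, computed from unrounded totals.  When
  the signs of the increments disagree the comparison is tagged *dominant*
  (cheaper and more effective) or *dominated* (dearer and less effective)
  instead of reporting a meaningless ratio.
* INMB = WTP x delta-effect - delta-cost; positive at a threshold means
  the intervention is cost-effective there.
* The CEAC reports, per willingness-to-pay value, the fraction of
  probabilistic draws with positive INMB.
* EVPI = E[max_s NMB_s] - max_s E[NMB_s], evaluated pairwise (intervention
  versus one comparator) to match a two-way decision framing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ArmOutcomes

__all__ = [
    "IncrementalResult",
    "CeacPoint",
    "icer",
    "inmb",
    "ceac",
    "evpi",
    "default_wtp_grid",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison of two strategy arms."""

    intervention: str
    comparator: str
    effect_measure: str
    delta_cost: float
    delta_effect: float
    icer: float | None          # NT$ per effect unit; None when tagged/undefined
    dominance: str | None       # "dominant" / "dominated" / None
    wtp: float
    inmb: float


def icer(
    intervention: ArmOutcomes,
    comparator: ArmOutcomes,
    effect_measure: str = "qaly",
    wtp: float = 2_928_570.0,
) -> IncrementalResult:
    """Incremental cost-effectiveness of ``intervention`` over ``comparator``."""
    d_cost = intervention.cost_total - comparator.cost_total
    d_eff = intervention.effect(effect_measure) - comparator.effect(effect_measure)
    dominance = None
    ratio: float | None
    if d_eff == 0.0:
        ratio = None  # undefined ICER; INMB still informative
    elif d_eff > 0 and d_cost <= 0:
        dominance, ratio = DOMINANT, None
    elif d_eff < 0 and d_cost >= 0:
        dominance, ratio = DOMINATED, None
    else:
        ratio = d_cost / d_eff
    return IncrementalResult(
        intervention=intervention.arm,
        comparator=comparator.arm,
        effect_measure=effect_measure,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=ratio,
        dominance=dominance,
        wtp=wtp,
        inmb=wtp * d_eff - d_cost,
    )


def inmb(
    intervention: ArmOutcomes,
    comparator: ArmOutcomes,
    wtp: float,
    effect_measure: str = "qaly",
) -> float:
    """Incremental net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    d_cost = intervention.cost_total - comparator.cost_total
    d_eff = intervention.effect(effect_measure) - comparator.effect(effect_measure)
    return wtp * d_eff - d_cost


@dataclass(frozen=True)
class CeacPoint:
    wtp: float
    probability: float


def default_wtp_grid(wtp_threshold: float = 2_928_570.0) -> np.ndarray:
    """0 to 6,000,000 NT$ in 100,000 steps, always including the threshold."""
    grid = np.arange(0.0, 6_000_001.0, 100_000.0)
    return np.unique(np.append(grid, wtp_threshold))


def ceac(
    delta_costs: np.ndarray,
    delta_effects: np.ndarray,
    wtp_grid: np.ndarray,
) -> list[CeacPoint]:
    """Cost-effectiveness acceptability curve from per-draw increments."""
    dc = np.asarray(delta_costs, dtype=float)
    de = np.asarray(delta_effects, dtype=float)
    if dc.size == 0 or dc.shape != de.shape:
        raise ValueError("need at least one draw with matching shapes")
    points = []
    for w in np.asarray(wtp_grid, dtype=float):
        p = float(np.mean(w * de - dc > 0))
        points.append(CeacPoint(wtp=float(w), probability=p))
    return points


def ceac_frame(points_by_comparator: dict[str, list[CeacPoint]]) -> pd.DataFrame:
    """Long-to-wide CEAC table: one wtp column plus one column per comparator."""
    out = None
    for name, pts in points_by_comparator.items():
        df = pd.DataFrame(
            {"wtp": [p.wtp for p in pts], f"p_ce_vs_{name}": [p.probability for p in pts]}
        )
        out = df if out is None else out.merge(df, on="wtp")
    return out


def evpi(nmb_intervention: np.ndarray, nmb_comparator: np.ndarray) -> float:
    """Per-person expected value of perfect information (pairwise).

    Both arguments are per-draw net monetary benefits at a fixed WTP.
    """
    a = np.asarray(nmb_intervention, dtype=float)
    b = np.asarray(nmb_comparator, dtype=float)
    if a.size < 1 or a.shape != b.shape:
        raise ValueError("need matching per-draw NMB arrays")
    e_max = float(np.mean(np.maximum(a, b)))
    max_e = max(float(np.mean(a)), float(np.mean(b)))
    return e_max - max_e
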