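"""Parametric survival laws and censored-data survival estimation.

The cohort model partitions state occupancy directly from overall-survival
(OS) and progression-free-survival (PFS) curves, so everything downstream
rests on the objects defined here:

* :class:`SurvivalDist` — a parametric law (Weibull, log-normal or
  generalized gamma) with time measured in **months**.
* :class:`KMCurve` — a Kaplan–Meier step function estimated from
  right-censored individual patient data.
* :class:`HybridSurvival` — a KM curve over the observed follow-up spliced
  to a rescaled parametric tail, the usual device for extrapolating
  trial-duration evidence to a modelling horizon.

Parameter conventions follow standard survival-regression software
(accelerated-failure-time form):

* ``weibull(scale, shape)``: ``S(t) = exp(-(t/scale)**shape)``; the median is
  ``scale * ln(2)**(1/shape)``.
* ``lognormal(mu, sigma)``: ``mu``/``sigma`` are mean and SD of log-time in
  log-months; the median is ``exp(mu)``.
* ``gengamma(mu, sigma, q)``: Prentice location/scale/shape.  ``q = 1``
  recovers ``weibull(exp(mu), 1/sigma)`` and ``q = 0`` recovers
  ``lognormal(mu, sigma)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "SurvivalDist",
    "PseudoIPD",
    "KMCurve",
    "HybridSurvival",
    "FitResult",
    "FitError",
    "survival_at",
    "median_survival",
    "rmst",
    "sample_times",
    "fit_mle",
    "km_estimate",
    "build_hybrid",
]

MONTHS_PER_YEAR = 12.0

FAMILIES = ("weibull", "lognormal", "gengamma")
_N_PARAMS = {"weibull": 2, "lognormal": 2, "gengamma": 3}


class ParameterError(ValueError):
    """A survival-distribution parameter violates its domain."""


@dataclass(frozen=True)
class SurvivalDist:
    """A parametric survival law over time in months.

    Parameters
    ----------
    family : {"weibull", "lognormal", "gengamma"}
    params : tuple of float
        ``weibull``: (scale > 0, shape > 0);
        ``lognormal``: (mu, sigma > 0);
        ``gengamma``: (mu, sigma > 0, q) in the Prentice parameterization.
    label : str
        Free-text tag carried through outputs.
    """

    family: str
    params: tuple
    label: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown survival family {self.family!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _N_PARAMS[self.family]:
            raise ParameterError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, "
                f"got {len(params)}"
            )
        if not all(np.isfinite(params)):
            raise ParameterError(f"non-finite parameters {params}")
        if self.family == "weibull":
            if params[0] <= 0 or params[1] <= 0:
                raise ParameterError(f"weibull scale/shape must be > 0, got {params}")
        elif self.family == "lognormal":
            if params[1] <= 0:
                raise ParameterError(f"lognormal sigma must be > 0, got {params}")
        else:  # gengamma
            if params[1] <= 0:
                raise ParameterError(f"gengamma sigma must be > 0, got {params}")

    # -- evaluation ------------------------------------------------------
    def survival(self, t):
        """S(t) for t in months (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be >= 0")
        with np.errstate(divide="ignore"):
            logt = np.log(np.where(t > 0, t, 1.0))
        if self.family == "weibull":
            scale, shape = self.params
            s = np.exp(-((t / scale) ** shape))
        elif self.family == "lognormal":
            mu, sigma = self.params
            s = stats.norm.sf((logt - mu) / sigma)
        else:
            mu, sigma, q = self.params
            w = (logt - mu) / sigma
            if q == 0.0:
                s = stats.norm.sf(w)
            else:
                a = q**-2.0
                u = a * np.exp(np.clip(q * w, -700.0, 700.0))
                s = special.gammaincc(a, u) if q > 0 else special.gammainc(a, u)
        s = np.where(t == 0, 1.0, s)
        return float(s) if s.ndim == 0 else s

    def log_density(self, t):
        """log f(t) of the event-time density, for likelihood work."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("density defined for t > 0")
        logt = np.log(t)
        if self.family == "weibull":
            scale, shape = self.params
            z = t / scale
            return np.log(shape / scale) + (shape - 1) * np.log(z) - z**shape
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.norm.logpdf((logt - mu) / sigma) - np.log(sigma) - logt
        mu, sigma, q = self.params
        w = (logt - mu) / sigma
        if q == 0.0:
            return stats.norm.logpdf(w) - np.log(sigma) - logt
        a = q**-2.0
        return (
            np.log(abs(q))
            + a * np.log(a)
            - special.gammaln(a)
            + a * (q * w - np.exp(np.clip(q * w, -700.0, 700.0)))
            - np.log(sigma)
            - logt
        )

    def median(self):
        """Exact median survival time in months."""
        if self.family == "weibull":
            scale, shape = self.params
            return scale * np.log(2.0) ** (1.0 / shape)
        if self.family == "lognormal":
            return float(np.exp(self.params[0]))
        mu, sigma, q = self.params
        if q == 0.0:
            return float(np.exp(mu))
        a = q**-2.0
        # invert S(t) = 0.5 through the underlying gamma variable
        u = special.gammainccinv(a, 0.5) if q > 0 else special.gammaincinv(a, 0.5)
        return float(np.exp(mu + sigma * np.log(u / a) / q))

    def ppf_survival(self, u):
        """Time t (months) at which S(t) = u, for u in (0, 1)."""
        u = np.clip(np.asarray(u, dtype=float), 1e-15, 1.0 - 1e-15)
        if self.family == "weibull":
            scale, shape = self.params
            return scale * (-np.log(u)) ** (1.0 / shape)
        if self.family == "lognormal":
            mu, sigma = self.params
            return np.exp(mu + sigma * stats.norm.isf(u))
        mu, sigma, q = self.params
        if q == 0.0:
            return np.exp(mu + sigma * stats.norm.isf(u))
        a = q**-2.0
        g = special.gammainccinv(a, u) if q > 0 else special.gammaincinv(a, u)
        return np.exp(mu + sigma * np.log(g / a) / q)

    def sample(self, n, rng):
        """Inverse-CDF sampling of n event times (months)."""
        if n <= 0:
            raise ValueError("n must be > 0")
        return self.ppf_survival(rng.uniform(size=int(n)))


def survival_at(dist, t):
    """Survival probability of ``dist`` (or any curve object) at t months."""
    return dist.survival(t)


def median_survival(dist: SurvivalDist) -> float:
    """Median survival in months; satisfies S(median) = 0.5."""
    return dist.median()


def rmst(dist, horizon_months: float, annual_discount_rate: float = 0.0) -> float:
    """Discounted restricted mean survival time, in **years**.

    Computes ``(1/12) * integral_0^T S(t) (1+r)^(-t/12) dt`` with t in months.
    With ``annual_discount_rate = 0`` this is the ordinary restricted mean.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    if not 0 <= annual_discount_rate < 1:
        raise ValueError("discount rate must be in [0, 1)")
    log1pr = np.log1p(annual_discount_rate)

    def integrand(t):
        return dist.survival(t) * np.exp(-log1pr * t / MONTHS_PER_YEAR)

    val, _ = integrate.quad(integrand, 0.0, horizon_months, limit=400)
    return val / MONTHS_PER_YEAR


def sample_times(dist: SurvivalDist, n: int, seed) -> np.ndarray:
    """Draw n event times (months) reproducibly from ``dist``."""
    rng = np.random.default_rng(seed)
    return dist.sample(n, rng)


# ---------------------------------------------------------------------------
# individual patient data and Kaplan-Meier estimation
# ---------------------------------------------------------------------------

@dataclass
class PseudoIPD:
    """Simulated individual patient data (right-censored times in months).

    ``time`` holds positive follow-up times; ``event`` is 1 for an observed
    event and 0 for administrative censoring at the censoring horizon.
    """

    time: np.ndarray
    event: np.ndarray
    censor_horizon: float | None = None
    seed: int | None = None
    generating_dist: SurvivalDist | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all follow-up times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self):
        return self.time.size

    @property
    def n_events(self):
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        missing = {"time_months", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"IPD csv missing columns: {sorted(missing)}")
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit step function (right-continuous)."""

    times: np.ndarray          # step locations, months (starts at 0)
    survival: np.ndarray       # S just after each step location
    n_risk: np.ndarray         # number at risk just before each location
    max_follow_up: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=float)
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise ValueError("KM curve must start at (0, 1)")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("KM survival must be non-increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = self.survival[np.clip(idx, 0, len(self.times) - 1)]
        return float(s) if s.ndim == 0 else s

    survival_at = __call__

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "n_risk": self.n_risk}
        )


def km_estimate(ipd: PseudoIPD) -> KMCurve:
    """Kaplan-Meier estimate of the survival function from censored IPD.

    Delegates the product-limit computation to lifelines.
    """
    from lifelines import KaplanMeierFitter

    if ipd.n_events == 0:
        warnings.warn("no events observed; KM curve is flat at 1.0")
        return KMCurve(
            times=np.array([0.0]),
            survival=np.array([1.0]),
            n_risk=np.array([float(ipd.n)]),
            max_follow_up=float(ipd.time.max()),
        )
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.insert(times, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
        at_risk = np.insert(at_risk, 0, float(ipd.n))
    return KMCurve(times, surv, at_risk, max_follow_up=float(ipd.time.max()))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

class FitError(RuntimeError):
    """Parametric fit failed to converge; carries diagnostics."""


@dataclass
class FitResult:
    dist: SurvivalDist
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int
    # 95% Wald confidence intervals per parameter, (low, high) tuples
    conf_int: tuple = ()


def _loglik(dist: SurvivalDist, ipd: PseudoIPD) -> float:
    ev = ipd.event.astype(bool)
    ll = 0.0
    if ev.any():
        ll += float(np.sum(dist.log_density(ipd.time[ev])))
    if (~ev).any():
        s = dist.survival(ipd.time[~ev])
        ll += float(np.sum(np.log(np.maximum(s, 1e-300))))
    return ll


def fit_mle(ipd: PseudoIPD, family: str) -> FitResult:
    """Maximum-likelihood fit of a parametric family to right-censored IPD.

    Uses the lifelines univariate fitters; returns the fitted law together
    with the maximized log-likelihood, AIC ``2p - 2l`` and BIC
    ``p ln(n) - 2l``, and per-parameter 95% Wald intervals.
    """
    from lifelines import (
        GeneralizedGammaFitter,
        LogNormalFitter,
        WeibullFitter,
    )
    from lifelines.exceptions import ConvergenceError

    if family not in FAMILIES:
        raise ParameterError(f"unknown survival family {family!r}")
    if ipd.n_events < 10:
        raise ValueError("at least 10 events are required for a stable fit")

    fitter_cls = {
        "weibull": WeibullFitter,
        "lognormal": LogNormalFitter,
        "gengamma": GeneralizedGammaFitter,
    }[family]

    last_exc = None
    for initial in (None, "scale_up", "scale_down"):
        fitter = fitter_cls()
        kwargs = {}
        if initial is not None:
            base = np.asarray(fitter._initial_values, dtype=float)
            kwargs["initial_point"] = base * (1.5 if initial == "scale_up" else 0.5)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(ipd.time, ipd.event, **kwargs)
        except (ConvergenceError, ValueError, Exception) as exc:  # noqa: BLE001
            last_exc = exc
            continue
        ci = fitter.summary[["coef lower 95%", "coef upper 95%"]]
        if family == "weibull":
            dist = SurvivalDist("weibull", (fitter.lambda_, fitter.rho_))
            ci_pairs = tuple(tuple(ci.loc[p]) for p in ("lambda_", "rho_"))
        elif family == "lognormal":
            dist = SurvivalDist("lognormal", (fitter.mu_, fitter.sigma_))
            ci_pairs = tuple(tuple(ci.loc[p]) for p in ("mu_", "sigma_"))
        else:
            sigma = float(np.exp(fitter.ln_sigma_))
            dist = SurvivalDist("gengamma", (fitter.mu_, sigma, fitter.lambda_))
            ci_mu = tuple(ci.loc["mu_"])
            ci_sigma = tuple(np.exp(ci.loc["ln_sigma_"]))
            ci_pairs = (ci_mu, ci_sigma, tuple(ci.loc["lambda_"]))
        ll = _loglik(dist, ipd)
        if not np.isfinite(ll):
            last_exc = FitError("non-finite log-likelihood at optimum")
            continue
        p = _N_PARAMS[family]
        return FitResult(
            dist=dist,
            loglik=ll,
            aic=2 * p - 2 * ll,
            bic=p * np.log(ipd.n) - 2 * ll,
            n=ipd.n,
            n_events=ipd.n_events,
            conf_int=ci_pairs,
        )
    raise FitError(
        f"{family} fit did not converge after 3 starts "
        f"(n={ipd.n}, events={ipd.n_events}): {last_exc}"
    )


# ---------------------------------------------------------------------------
# hybrid KM + parametric extrapolation
# ---------------------------------------------------------------------------

@dataclass
class HybridSurvival:
    """KM curve up to ``switch_time``, rescaled parametric tail beyond it.

    The tail is multiplied by ``KM(switch)/S_tail(switch)`` so the spliced
    curve is continuous at the switch and non-increasing overall.
    """

    km: KMCurve
    tail: SurvivalDist
    switch_time: float
    _scale: float = field(init=False, repr=False)

    def __post_init__(self):
        if self.switch_time < 0:
            raise ValueError("switch_time must be >= 0")
        if self.switch_time > self.km.max_follow_up and self.switch_time > 0:
            raise ValueError("switch_time outside KM support")
        s_tail = self.tail.survival(self.switch_time)
        if s_tail <= 0:
            raise ValueError("parametric tail is 0 at the switch time")
        self._scale = self.km(self.switch_time) / s_tail

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        tail = np.minimum(self._scale * self.tail.survival(t), 1.0)
        s = np.where(t <= self.switch_time, self.km(t), tail)
        return float(s) if s.ndim == 0 else s

    __call__ = survival


def build_hybrid(km: KMCurve, tail: SurvivalDist, switch_time: float) -> HybridSurvival:
    """Splice a KM curve to a rescaled parametric tail at ``switch_time``."""
    return HybridSurvival(km=km, tail=tail, switch_time=switch_time)
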