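"""Survival-time samplers, censoring calibration and scenario presets.

The Monte Carlo benchmarks draw failure times from exponential, Weibull
(S(t) = exp{-(t/theta)^eta}) or piecewise-exponential laws, censor them by
independent uniform times U(0, a) with per-arm limits calibrated so that
P(C < X) hits a target censoring rate, and organize arm pairs into five
named scenarios:

====  ==========================================================
null  both arms exponential with hazard 0.25 (type-I error runs)
A     proportional hazards (exponential 0.25 vs 0.5)
B     early crossing, survival at the crossing point above 0.6
C     middle crossing, survival at the crossing point in [0.4, 0.6]
D     late crossing, survival at the crossing point in [0.2, 0.4]
====  ==========================================================

The B/C/D Weibull pairs were chosen so the crossing-level bands hold
exactly (the bands are verified analytically by ``crossing_point``); a
unit test pins them down.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

from .survcore import SurvivalSample

__all__ = [
    "Exponential", "WeibullParams", "PiecewiseExponential",
    "CensoringSpec", "ScenarioConfig",
    "sample_survival_times", "calibrate_censoring", "apply_censoring",
    "crossing_point", "preset", "generate_scenario", "PRESET_LAWS",
]


@dataclass(frozen=True)
class Exponential:
    """Constant-hazard law, S(t) = exp(-rate * t)."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def survival(self, t):
        return np.exp(-self.rate * np.asarray(t, dtype=float))

    def ppf(self, u):
        """Inverse CDF: time at which the CDF reaches u."""
        return -np.log1p(-np.asarray(u, dtype=float)) / self.rate


@dataclass(frozen=True)
class WeibullParams:
    """Weibull law with shape eta and scale theta, S(t)=exp{-(t/theta)^eta}."""

    eta: float
    theta: float

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.theta <= 0:
            raise ValueError("shape and scale must be positive")

    def survival(self, t):
        return np.exp(-((np.asarray(t, dtype=float) / self.theta) ** self.eta))

    def ppf(self, u):
        return self.theta * (-np.log1p(-np.asarray(u, dtype=float))) ** (1.0 / self.eta)


@dataclass(frozen=True)
class PiecewiseExponential:
    """Piecewise-constant hazard; one more rate than breakpoints."""

    breakpoints: tuple
    rates: tuple

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        rt = tuple(float(r) for r in self.rates)
        if len(rt) != len(bp) + 1:
            raise ValueError("need exactly one more rate than breakpoints")
        if any(r <= 0 for r in rt):
            raise ValueError("all rates must be positive")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or (bp and bp[0] <= 0):
            raise ValueError("breakpoints must be positive and increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates", rt)

    def _edges(self):
        return np.concatenate([[0.0], np.asarray(self.breakpoints)])

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        edges = self._edges()
        rates = np.asarray(self.rates)
        spans = np.clip(t[..., None] - edges, 0.0, None)
        widths = np.diff(np.concatenate([edges, [np.inf]]))
        return np.sum(rates * np.minimum(spans, widths), axis=-1)

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def ppf(self, u):
        """Invert H(t) = -log(1-u) across the hazard segments."""
        target = -np.log1p(-np.asarray(u, dtype=float))
        edges = self._edges()
        rates = np.asarray(self.rates)
        widths = np.diff(np.concatenate([edges, [np.inf]]))
        cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths[:-1])])
        idx = np.searchsorted(cum, target, side="right") - 1
        return edges[idx] + (target - cum[idx]) / rates[idx]


@dataclass(frozen=True)
class CensoringSpec:
    """Uniform censoring with per-arm upper limits a (arm 1) and b (arm 2)."""

    kind: str = "none"       # none | uniform
    a: float | None = None
    b: float | None = None
    target_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "uniform"):
            raise ValueError("kind must be 'none' or 'uniform'")
        if self.kind == "uniform":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValueError("uniform censoring needs positive limits a, b")

    def limit(self, group: int) -> float | None:
        if self.kind == "none":
            return None
        return self.a if group == 1 else self.b


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating law for each arm plus censoring and sample sizes."""

    label: str
    law1: object
    law2: object
    n1: int
    n2: int
    censoring: CensoringSpec


def sample_survival_times(law, n: int, seed=None) -> np.ndarray:
    """Inverse-CDF draws from a survival law; ``seed`` may be a Generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.asarray(law.ppf(rng.random(n)))


def _expected_uncensored_area(law, a: float) -> float:
    """int_0^a S(t) dt, exactly for the exponential, by quadrature otherwise."""
    if isinstance(law, Exponential):
        return (1.0 - np.exp(-law.rate * a)) / law.rate
    val, _ = integrate.quad(lambda t: float(law.survival(t)), 0.0, a,
                            limit=200)
    return val


def censoring_rate(law, a: float) -> float:
    """Censoring probability P(C < X) for C ~ U(0, a) and X ~ law.

    P(C < X) = E[S_X(C)] = (1/a) int_0^a S(t) dt.
    """
    return _expected_uncensored_area(law, a) / a


def calibrate_censoring(law, target_rate: float, tol: float = 1e-6) -> float:
    """Solve P(C < X) = target_rate for C ~ U(0, a) by bisection.

    The censoring probability (1/a) int_0^a S(t) dt decreases from 1 to 0
    as ``a`` grows, so the root is unique.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie strictly between 0 and 1")
    lo, hi = tol, 1.0
    while censoring_rate(law, hi) > target_rate:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"censoring rate {target_rate} unattainable")
    sol = optimize.brentq(lambda a: censoring_rate(law, a) - target_rate,
                          lo, hi, xtol=tol)
    return float(sol)


def apply_censoring(times: np.ndarray, censoring: CensoringSpec,
                    seed=None, group: int = 1) -> SurvivalSample:
    """T = min(X, C), delta = I[X <= C] with C ~ U(0, limit) for this arm."""
    times = np.asarray(times, dtype=float)
    if censoring.kind == "none":
        return SurvivalSample(times, np.ones(times.size, dtype=int), group=group)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    limit = censoring.limit(group)
    c = rng.uniform(0.0, limit, size=times.size)
    observed = np.minimum(times, c)
    status = (times <= c).astype(int)
    return SurvivalSample(observed, status, group=group)


def crossing_point(law1, law2, t_max: float = 1e3):
    """Interior crossing time of two survival curves, with its survival level.

    Returns ``(t_star, s_star)`` or ``None`` when the curves do not cross.
    Two Weibulls with different shapes cross at the closed-form point
    t* = exp[(eta1 log theta1 - eta2 log theta2) / (eta1 - eta2)];
    other pairs are solved by bisection on S1 - S2.

    Raises ``ValueError`` when the two laws are identical.
    """
    if law1 == law2:
        raise ValueError("curves are identical; no unique crossing point")
    if isinstance(law1, WeibullParams) and isinstance(law2, WeibullParams):
        if law1.eta == law2.eta:
            return None  # proportional-type ordering, no interior crossing
        t_star = float(np.exp((law1.eta * np.log(law1.theta)
                               - law2.eta * np.log(law2.theta))
                              / (law1.eta - law2.eta)))
        return t_star, float(law1.survival(t_star))
    if isinstance(law1, Exponential) and isinstance(law2, Exponential):
        return None
    diff = lambda t: float(law1.survival(t) - law2.survival(t))
    grid = np.geomspace(1e-6, t_max, 4000)
    vals = np.array([diff(t) for t in grid])
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size == 0:
        return None
    i = flips[0]
    t_star = float(optimize.brentq(diff, grid[i], grid[i + 1], xtol=1e-10))
    return t_star, float(law1.survival(t_star))


# ----------------------------------------------------------------------
# scenario presets

PRESET_LAWS: dict[str, tuple] = {
    "null": (Exponential(0.25), Exponential(0.25)),
    "A": (Exponential(0.25), Exponential(0.5)),
    # early crossing, S(t*) > 0.6: decreasing- vs increasing-hazard Weibulls
    "B": (WeibullParams(0.5, 10.0), WeibullParams(2.0, 3.0)),
    # middle crossing, S(t*) in [0.4, 0.6]
    "C": (WeibullParams(2.0, 4.0), WeibullParams(0.6, 5.0)),
    # late crossing, S(t*) in [0.2, 0.4]
    "D": (WeibullParams(3.0, 3.0), WeibullParams(1.0, 2.64)),
}

CROSSING_BANDS = {"B": (0.6, 1.0), "C": (0.4, 0.6), "D": (0.2, 0.4)}


@lru_cache(maxsize=256)
def _calibrated_limits(label: str, rate: float) -> tuple[float, float]:
    law1, law2 = PRESET_LAWS[label]
    return calibrate_censoring(law1, rate), calibrate_censoring(law2, rate)


def preset(label: str, n1: int, n2: int,
           censoring_rate: float = 0.0) -> ScenarioConfig:
    """Build a scenario from a named preset and a target censoring rate.

    Per-arm uniform limits are calibrated separately against each arm's
    law, so both arms hit the same expected censoring fraction.
    """
    if label not in PRESET_LAWS:
        raise ValueError(f"unknown scenario label {label!r}")
    law1, law2 = PRESET_LAWS[label]
    if censoring_rate <= 0.0:
        spec = CensoringSpec(kind="none", target_rate=0.0)
    else:
        a, b = _calibrated_limits(label, round(float(censoring_rate), 6))
        spec = CensoringSpec(kind="uniform", a=a, b=b,
                             target_rate=censoring_rate)
    return ScenarioConfig(label=label, law1=law1, law2=law2,
                          n1=n1, n2=n2, censoring=spec)


def generate_scenario(config: ScenarioConfig,
                      seed=None) -> tuple[SurvivalSample, SurvivalSample]:
    """Draw one replicate pair of censored samples from a scenario."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x1 = sample_survival_times(config.law1, config.n1, rng)
    x2 = sample_survival_times(config.law2, config.n2, rng)
    s1 = apply_censoring(x1, config.censoring, rng, group=1)
    s2 = apply_censoring(x2, config.censoring, rng, group=2)
    return s1, s2.relabel(2)
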