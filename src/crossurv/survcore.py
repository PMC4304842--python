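"""Core containers and estimators for two-sample right-censored survival data.

Everything downstream (rank tests, supremum tests, Kaplan-Meier difference
tests, the smooth tests) is built on three objects defined here:

* :class:`SurvivalSample` -- one arm's observed times and event indicators,
* :class:`RiskTable` -- per distinct pooled event time, the at-risk and
  death counts in each arm, together with the truncation index ``tau``
  (the last event time at which both arms still have somebody at risk),
* :class:`StepEstimate` -- a right-continuous step function holding a
  Kaplan-Meier, Nelson-Aalen or censoring-survival estimate with
  pointwise variances.

Tie convention: at equal observed times, events are processed before
censorings, so a subject censored at ``t`` is still at risk at ``t``.  The
censoring-distribution Kaplan-Meier mirrors this by flipping the roles of
the indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurvivalSample",
    "RiskTable",
    "StepEstimate",
    "NoEventsError",
    "build_risk_table",
    "kaplan_meier",
    "nelson_aalen",
    "censoring_km",
    "pooled_sample",
]


class NoEventsError(ValueError):
    """Raised when a risk table is requested but no event was observed."""


@dataclass(frozen=True)
class SurvivalSample:
    """One group's right-censored observations.

    Parameters
    ----------
    times:
        Observed times ``T = min(X, Cr)``, all strictly positive.
    status:
        Event indicators ``delta = I[X <= Cr]`` (1 = event, 0 = censored).
    group:
        Arm label, 1 or 2.
    """

    times: np.ndarray
    status: np.ndarray
    group: int = 1

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        status = np.atleast_1d(np.asarray(self.status, dtype=int))
        if times.ndim != 1 or status.ndim != 1:
            raise ValueError("times and status must be one-dimensional")
        if times.size != status.size:
            raise ValueError(
                f"times (n={times.size}) and status (n={status.size}) differ in length"
            )
        if times.size < 1:
            raise ValueError("a survival sample needs at least one subject")
        if not np.all(times > 0):
            raise ValueError("all observed times must be strictly positive")
        if not np.all((status == 0) | (status == 1)):
            raise ValueError("status must contain only 0 (censored) or 1 (event)")
        if self.group not in (1, 2):
            raise ValueError("group label must be 1 or 2")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status)

    @property
    def size(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def relabel(self, group: int) -> "SurvivalSample":
        return SurvivalSample(self.times, self.status, group=group)


def pooled_sample(sample1: SurvivalSample, sample2: SurvivalSample) -> SurvivalSample:
    """Concatenate two arms into a single (label-free) sample."""
    return SurvivalSample(
        np.concatenate([sample1.times, sample2.times]),
        np.concatenate([sample1.status, sample2.status]),
        group=1,
    )


@dataclass(frozen=True)
class RiskTable:
    """Pooled risk table over the distinct event times of both arms.

    ``tau_index`` is the (0-based) index of the last row at which both
    groups still have at least one subject at risk; rank statistics sum
    rows ``0..tau_index`` only.  Rows beyond ``tau_index`` are kept so the
    full follow-up remains visible to estimators and plots.
    """

    event_times: np.ndarray  # t_1 < ... (J,)
    d: np.ndarray            # pooled deaths per row
    d1: np.ndarray           # group-1 deaths per row
    n: np.ndarray            # pooled at risk just before t_j
    n1: np.ndarray           # group-1 at risk
    n2: np.ndarray           # group-2 at risk
    tau_index: int
    n_total1: int
    n_total2: int

    @property
    def n_rows(self) -> int:
        return int(self.event_times.size)

    @property
    def tau(self) -> float:
        """The truncation time t_tau."""
        if self.tau_index < 0:
            return float("nan")
        return float(self.event_times[self.tau_index])

    def truncated(self) -> "RiskTable":
        """A copy containing only the rows up to and including ``tau_index``."""
        m = self.tau_index + 1
        return RiskTable(
            self.event_times[:m], self.d[:m], self.d1[:m],
            self.n[:m], self.n1[:m], self.n2[:m],
            tau_index=self.tau_index,
            n_total1=self.n_total1, n_total2=self.n_total2,
        )

    def logrank_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed-minus-expected increments and hypergeometric variances.

        Returns ``(e, v)`` over *all* rows; callers apply the tau mask.
        Rows with a single subject at risk contribute zero variance.
        """
        d, n, n1 = self.d, self.n, self.n1
        e = self.d1 - n1 * d / n
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (n1 / n) * (1.0 - n1 / n) * d * (n - d) / (n - 1.0)
        v = np.where(n > 1, v, 0.0)
        return e, v

    def pooled_km_left(self) -> np.ndarray:
        """Pooled Kaplan-Meier left limit S(t_j-) at each event row."""
        surv = np.cumprod(1.0 - self.d / self.n)
        return np.concatenate([[1.0], surv[:-1]])


def build_risk_table(sample1: SurvivalSample, sample2: SurvivalSample) -> RiskTable:
    """Construct the pooled risk table for two arms.

    At-risk counts use the convention that subjects censored at ``t``
    remain at risk at ``t`` (events precede censorings at ties).
    """
    if sample1.n_events + sample2.n_events == 0:
        raise NoEventsError("no events observed in either group")

    event_times = np.unique(np.concatenate([
        sample1.times[sample1.status == 1],
        sample2.times[sample2.status == 1],
    ]))

    def _counts(s: SurvivalSample) -> tuple[np.ndarray, np.ndarray]:
        order = np.sort(s.times)
        # at risk just before t_j: subjects with T >= t_j
        n_at_risk = s.size - np.searchsorted(order, event_times, side="left")
        ev = np.sort(s.times[s.status == 1])
        deaths = (np.searchsorted(ev, event_times, side="right")
                  - np.searchsorted(ev, event_times, side="left"))
        return n_at_risk.astype(float), deaths.astype(float)

    n1, d1 = _counts(sample1)
    n2, d2 = _counts(sample2)
    both = (n1 >= 1) & (n2 >= 1)
    tau_index = int(np.max(np.nonzero(both)[0])) if both.any() else -1
    return RiskTable(
        event_times=event_times,
        d=d1 + d2, d1=d1,
        n=n1 + n2, n1=n1, n2=n2,
        tau_index=tau_index,
        n_total1=sample1.size, n_total2=sample2.size,
    )


@dataclass(frozen=True)
class StepEstimate:
    """A right-continuous step function with pointwise variances.

    ``kind`` is one of ``survival``, ``cumulative_hazard`` or
    ``censoring_survival``.  Before the first knot the value is the
    natural baseline (1 for survival kinds, 0 for the cumulative hazard).
    """

    knots: np.ndarray
    values: np.ndarray
    variances: np.ndarray
    kind: str = "survival"

    @property
    def _baseline(self) -> float:
        return 0.0 if self.kind == "cumulative_hazard" else 1.0

    def at(self, t) -> np.ndarray:
        """Right-continuous evaluation: the value at the latest knot <= t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        vals = np.concatenate([[self._baseline], self.values])
        return vals[idx + 1]

    def left_limit(self, t) -> np.ndarray:
        """Value strictly before ``t`` (the step active on ``[prev, t)``)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="left") - 1
        vals = np.concatenate([[self._baseline], self.values])
        return vals[idx + 1]

    def variance_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        var = np.concatenate([[0.0], self.variances])
        return var[idx + 1]


def _own_risk_process(times: np.ndarray, indicator: np.ndarray):
    """Distinct times with indicator==1, and (n, d) within one sample."""
    knots = np.unique(times[indicator == 1])
    order = np.sort(times)
    n = times.size - np.searchsorted(order, knots, side="left")
    ev = np.sort(times[indicator == 1])
    d = (np.searchsorted(ev, knots, side="right")
         - np.searchsorted(ev, knots, side="left"))
    return knots, n.astype(float), d.astype(float)


def kaplan_meier(sample: SurvivalSample) -> StepEstimate:
    """Product-limit estimate of the survival function with Greenwood variance."""
    knots, n, d = _own_risk_process(sample.times, sample.status)
    if knots.size == 0:
        return StepEstimate(np.empty(0), np.empty(0), np.empty(0), kind="survival")
    surv = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood = np.cumsum(np.where(n > d, d / (n * (n - d)), 0.0))
    var = surv**2 * greenwood
    return StepEstimate(knots, surv, var, kind="survival")


def nelson_aalen(sample: SurvivalSample) -> StepEstimate:
    """Cumulative-hazard estimate: sum of d_j/n_j with variance sum d_j/n_j^2."""
    knots, n, d = _own_risk_process(sample.times, sample.status)
    if knots.size == 0:
        return StepEstimate(np.empty(0), np.empty(0), np.empty(0),
                            kind="cumulative_hazard")
    return StepEstimate(knots, np.cumsum(d / n), np.cumsum(d / n**2),
                        kind="cumulative_hazard")


def censoring_km(sample: SurvivalSample) -> StepEstimate:
    """Kaplan-Meier of the censoring distribution (roles of delta flipped)."""
    flipped = 1 - sample.status
    knots, n, d = _own_risk_process(sample.times, flipped)
    if knots.size == 0:
        return StepEstimate(np.empty(0), np.empty(0), np.empty(0),
                            kind="censoring_survival")
    surv = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood = np.cumsum(np.where(n > d, d / (n * (n - d)), 0.0))
    return StepEstimate(knots, surv, surv**2 * greenwood, kind="censoring_survival")
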