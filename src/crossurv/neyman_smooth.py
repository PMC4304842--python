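"""Adaptive Neyman smooth tests for the two-sample hazard ratio.

The null of equal hazards is embedded in a model where the log hazard
ratio is a combination of ``d`` smooth functions of (transformed) time.
Basis functions are shifted Legendre polynomials, orthonormal on [0, 1],
evaluated at the pooled cumulative-hazard time transform
``x_j = Lambda(t_j) / Lambda(t_tau)``.  The partial-likelihood score in
each direction is a weighted log-rank numerator, so the fixed-dimension
statistic ``T_d = U' Sigma^{-1} U`` is a quadratic form in weighted
log-rank scores.

Two variants are exposed:

* NY1 -- fixed dimension, default d = 4;
* NY2 -- data-driven nested dimension, default d_max = 8, d0 = 0, with the
  Schwarz rule  S = argmax_d [T_d - (d - d0) log(n_events)].

Both are calibrated by group-label permutation (the dimension selection is
redone inside every permutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._engine import PooledPermutation, _shifted_legendre
from .survcore import RiskTable, SurvivalSample
from .wlr_tests import TestResult

__all__ = ["NYConfig", "SmoothScore", "basis_matrix", "smooth_score",
           "select_dimension", "ny_test"]


@dataclass(frozen=True)
class NYConfig:
    """Settings for the smooth tests."""

    d: int = 4              # fixed dimension (NY1)
    d_max: int = 8          # maximum nested dimension (NY2)
    d0: int = 0             # forced high-priority basis functions
    permutations: int = 2000
    seed: int | None = None
    basis: str = "legendre"

    def __post_init__(self) -> None:
        if not (1 <= self.d <= self.d_max <= 12):
            raise ValueError("need 1 <= d <= d_max <= 12")
        if self.d0 >= self.d_max:
            raise ValueError("d0 must be smaller than d_max")
        if self.permutations < 100:
            raise ValueError("at least 100 permutations are required")
        if self.basis != "legendre":
            raise ValueError("only the Legendre basis is implemented")


@dataclass
class SmoothScore:
    """Score vector, covariance and quadratic form for one dimension."""

    U: np.ndarray
    Sigma: np.ndarray
    T_d: float
    selected_d: int | None = None


def _time_transform(table: RiskTable) -> np.ndarray:
    """Pooled cumulative-hazard transform over rows <= tau.

    Basis functions are evaluated at the midpoint of each Nelson-Aalen
    step, x_j = (Lambda(t_j) - d_j/(2 n_j)) / Lambda(t_tau): the
    continuity correction noticeably improves the chi-square
    approximation of T_d in moderate samples.
    """
    m = table.tau_index + 1
    inc = table.d[:m] / table.n[:m]
    lam = np.cumsum(inc)
    if lam[-1] <= 0:
        raise ValueError("pooled cumulative hazard is zero at tau")
    return (lam - 0.5 * inc) / lam[-1]


def basis_matrix(table: RiskTable, d: int) -> np.ndarray:
    """(J_tau, d) matrix of shifted Legendre values, degrees 1..d.

    Degree 0 is excluded: the constant direction reproduces the plain
    log-rank statistic, which is handled by the d0 convention.  When the
    table has fewer rows than ``d`` the dimension is truncated with a
    warning.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    x = _time_transform(table)
    if x.size < d:
        warnings.warn(
            f"only {x.size} risk-table rows at or before tau; truncating "
            f"basis dimension from {d} to {x.size}", stacklevel=2)
        d = x.size
    return _shifted_legendre(x, d).T  # (J, d)


def smooth_score(table: RiskTable, d: int) -> SmoothScore:
    """Score vector U, covariance Sigma and quadratic form T_d."""
    phi = basis_matrix(table, d)
    m = table.tau_index + 1
    e, v = table.logrank_terms()
    e, v = e[:m], v[:m]
    U = phi.T @ e
    Sigma = (phi * v[:, None]).T @ phi
    if not np.any(Sigma):
        return SmoothScore(U, Sigma, 0.0)
    try:
        T = float(U @ np.linalg.solve(Sigma, U))
        if not np.isfinite(T) or T < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        T = float(U @ np.linalg.pinv(Sigma, rcond=1e-10, hermitian=True) @ U)
    return SmoothScore(U, Sigma, max(T, 0.0))


def select_dimension(t_stats, n_events: int, d0: int = 0) -> int:
    """Schwarz rule: argmax_{d0 < d <= d_max} T_d - (d - d0) log(n_events).

    ``t_stats`` holds T_d for d = 1..d_max.  Ties break toward smaller d.
    """
    t_stats = np.asarray(t_stats, dtype=float)
    dims = np.arange(1, t_stats.size + 1)
    crit = t_stats - (dims - d0) * np.log(max(n_events, 1))
    crit[: d0] = -np.inf
    return int(np.argmax(crit)) + 1


def ny_test(sample1: SurvivalSample, sample2: SurvivalSample,
            config: NYConfig | None = None,
            method: str = "ny1") -> TestResult:
    """Permutation-calibrated smooth test.

    ``method='ny1'`` uses the fixed dimension ``config.d``;
    ``method='ny2'`` selects the dimension by the Schwarz rule among
    nested models up to ``config.d_max`` and repeats the selection inside
    every permutation.  p = (1 + #{perm stat >= observed}) / (perms + 1).
    """
    config = config or NYConfig()
    if method not in ("ny1", "ny2"):
        raise ValueError("method must be 'ny1' or 'ny2'")
    pp = PooledPermutation(sample1, sample2)
    d_need = config.d if method == "ny1" else config.d_max
    d_eff = min(d_need, pp.event_times.size)
    if d_eff < d_need:
        warnings.warn(
            f"only {pp.event_times.size} pooled event times; truncating "
            f"dimension from {d_need} to {d_eff}", stacklevel=2)
    n_events = float(pp.d.sum())

    obs = pp.smooth_T(pp.observed_membership[None, :], d_eff)
    rng = np.random.default_rng(config.seed)
    memb = pp.random_memberships(config.permutations, rng)
    perm = pp.smooth_T(memb, d_eff)

    if method == "ny1":
        stat = float(obs[0, d_eff - 1])
        stat_perm = perm[:, d_eff - 1]
        extras = {"d": d_eff}
    else:
        sel_obs = int(pp.select_dimension(obs, n_events, config.d0)[0])
        stat = float(obs[0, sel_obs - 1])
        sel_perm = pp.select_dimension(perm, n_events, config.d0)
        stat_perm = perm[np.arange(perm.shape[0]), sel_perm - 1]
        extras = {"selected_d": sel_obs, "d_max": d_eff, "d0": config.d0}

    p = (1 + int(np.sum(stat_perm >= stat - 1e-12))) / (config.permutations + 1)
    extras["permutations"] = config.permutations
    return TestResult(method.upper(), stat, float(p), extras=extras)
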