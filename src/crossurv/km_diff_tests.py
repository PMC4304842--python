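"""Tests built on differences between Kaplan-Meier curves.

* ``wkm_test`` -- the Pepe-Fleming weighted Kaplan-Meier statistic: the
  integrated, censoring-weighted difference between the two survival
  curves, standardized by a plug-in variance that integrates the forward
  integral of (weight x pooled survival) against the pooled hazard.
* ``mkm_test`` -- the Shen-Cai maximum over a grid of rho/gamma-tilted
  WKM statistics, calibrated against the multivariate normal law of the
  component vector (Monte Carlo, plug-in correlation matrix).
* ``lx_test`` -- the Lin-Xu comparison of areas under the two survival
  curves (restricted means), with per-interval Greenwood variance terms
  linked by a constant pairwise correlation coefficient.
* ``lw_test`` -- the Lin-Wang sum of squared observed-minus-expected
  death counts, calibrated by group-label permutation.

All integrals run from 0 to t_tau, the last event time at which both
groups still have somebody at risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._engine import PooledPermutation
from .survcore import (RiskTable, SurvivalSample, build_risk_table,
                       censoring_km, kaplan_meier, pooled_sample)
from .wlr_tests import TestResult

__all__ = ["MKMConfig", "LXConfig", "wkm_test", "mkm_test", "lx_test", "lw_test"]


@dataclass(frozen=True)
class MKMConfig:
    """Grid and Monte Carlo settings for the maximum WKM test."""

    rho_grid: tuple = (0, 1, 2)
    gamma_grid: tuple = (0, 1, 2)
    mc_draws: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.rho_grid or not self.gamma_grid:
            raise ValueError("weight grids must be non-empty")
        if self.mc_draws < 10_000:
            raise ValueError("mc_draws must be at least 10000")


@dataclass(frozen=True)
class LXConfig:
    """Settings for the Lin-Xu area test.

    ``rho_cross`` is the constant correlation assumed between the
    per-interval area contributions when accumulating the variance of the
    restricted mean; 0.5 is the value recommended by the method's authors
    to keep the type I error near nominal.
    """

    rho_cross: float = 0.5
    sided: str = "one"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_cross <= 1.0:
            raise ValueError("rho_cross must be in [0, 1]")


# ----------------------------------------------------------------------
# shared step-integration scaffolding

def _integration_grid(s1: SurvivalSample, s2: SurvivalSample, tau: float):
    """Interval edges 0 = u_0 < ... < u_K = tau over all observed times."""
    all_t = np.concatenate([s1.times, s2.times])
    inner = np.unique(all_t[all_t < tau])
    return np.concatenate([[0.0], inner, [tau]])


def _wkm_machinery(s1: SurvivalSample, s2: SurvivalSample,
                   table: RiskTable):
    """Common pieces for WKM/MKM: grid, weights, KM values, variance core."""
    tau = table.tau
    edges = _integration_grid(s1, s2, tau)
    left, widths = edges[:-1], np.diff(edges)
    km1, km2 = kaplan_meier(s1), kaplan_meier(s2)
    c1, c2 = censoring_km(s1), censoring_km(s2)
    kmp = kaplan_meier(pooled_sample(s1, s2))
    S1, S2, Sp = km1.at(left), km2.at(left), kmp.at(left)
    C1, C2 = c1.at(left), c2.at(left)
    n1, n2 = s1.size, s2.size
    n = n1 + n2
    denom = n1 * C1 + n2 * C2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, n * C1 * C2 / denom, 0.0)
    m = table.tau_index + 1
    ev = table.event_times[:m]
    # rows of the interval grid where each event time begins
    ev_pos = np.searchsorted(edges[:-1], ev, side="left")
    haz_core = table.d[:m] / (table.n1[:m] * table.n2[:m])
    return dict(edges=edges, left=left, widths=widths, S1=S1, S2=S2, Sp=Sp,
                w=w, ev_pos=ev_pos, haz_core=haz_core, n1=n1, n2=n2, n=n)


def _component(mech: dict, tilt: np.ndarray):
    """One weighted-KM component: scaled statistic and A-integral rows."""
    wt = mech["w"] * tilt
    scale = np.sqrt(mech["n1"] * mech["n2"] / mech["n"])
    stat = scale * float(np.sum(wt * (mech["S1"] - mech["S2"]) * mech["widths"]))
    g = wt * mech["Sp"] * mech["widths"]
    rev = np.concatenate([np.cumsum(g[::-1])[::-1], [0.0]])
    A = rev[mech["ev_pos"]]          # forward integral from each event time
    return stat, A


def wkm_test(sample1: SurvivalSample, sample2: SurvivalSample) -> TestResult:
    """Pepe-Fleming weighted Kaplan-Meier test, two-sided normal p-value.

    Statistic: sqrt(n1 n2 / n) * int_0^tau w(t) [S1(t) - S2(t)] dt with the
    censoring weight w = n C1 C2 / (n1 C1 + n2 C2); with no censoring the
    weight is 1 and the statistic is the scaled area between the curves.
    """
    table = build_risk_table(sample1, sample2)
    if table.tau_index < 0:
        return TestResult("WKM", 0.0, 1.0, extras={"degenerate": True})
    mech = _wkm_machinery(sample1, sample2, table)
    stat, A = _component(mech, np.ones_like(mech["w"]))
    scale2 = mech["n1"] * mech["n2"] / mech["n"]
    V = scale2 * float(np.sum(A**2 * mech["haz_core"]))
    if V <= 0:
        return TestResult("WKM", stat, 1.0, V, extras={"degenerate": True})
    z = stat / np.sqrt(V)
    return TestResult("WKM", z, 2.0 * stats.norm.sf(abs(z)), V,
                      extras={"raw_statistic": stat})


def mkm_test(sample1: SurvivalSample, sample2: SurvivalSample,
             config: MKMConfig | None = None) -> TestResult:
    """Shen-Cai maximum weighted Kaplan-Meier test.

    Component weights tilt the censoring weight by S(t-)^rho (1-S(t-))^gamma
    over the configured grid; the statistic is the largest absolute
    standardized component and its p-value is the Monte Carlo tail of the
    maximum of a multivariate normal vector with the plug-in correlation.
    """
    config = config or MKMConfig()
    table = build_risk_table(sample1, sample2)
    if table.tau_index < 0:
        return TestResult("MKM", 0.0, 1.0, extras={"degenerate": True})
    mech = _wkm_machinery(sample1, sample2, table)
    # left limit of the pooled KM on each interval equals its value at the
    # interval's left edge (the estimate is right-continuous)
    Sp = mech["Sp"]
    stats_, rowsA = [], []
    for rho in config.rho_grid:
        for gamma in config.gamma_grid:
            tilt = Sp**rho * (1.0 - Sp) ** gamma
            s, A = _component(mech, tilt)
            stats_.append(s)
            rowsA.append(A)
    stats_ = np.array(stats_)
    Amat = np.array(rowsA)           # (m, J_tau)
    scale2 = mech["n1"] * mech["n2"] / mech["n"]
    cov = scale2 * (Amat * mech["haz_core"]) @ Amat.T
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ok = sd > 0
    if not ok.any():
        return TestResult("MKM", 0.0, 1.0, extras={"degenerate": True})
    z = np.where(ok, stats_ / np.where(ok, sd, 1.0), 0.0)
    R = cov[np.ix_(ok, ok)] / np.outer(sd[ok], sd[ok])
    R = _nearest_correlation(R)
    m_obs = float(np.max(np.abs(z)))
    rng = np.random.default_rng(config.seed)
    draws = rng.multivariate_normal(np.zeros(R.shape[0]), R,
                                    size=config.mc_draws,
                                    method="eigh")
    exceed = int(np.sum(np.max(np.abs(draws), axis=1) >= m_obs))
    p = (1 + exceed) / (config.mc_draws + 1)
    return TestResult("MKM", m_obs, float(p),
                      extras={"components": z.tolist(),
                              "correlation": R.tolist()})


def _nearest_correlation(R: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= floor:
        return R
    w = np.clip(w, floor, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


# ----------------------------------------------------------------------

def _restricted_area(sample: SurvivalSample, tau: float, rho_cross: float):
    """Area under one arm's KM to tau, and its correlated-interval variance.

    The area is decomposed over the arm's own event times; each interval
    contributes S(u_{k-1}) * width, with a Greenwood standard deviation
    sd(S(u_{k-1})) * width.  Contributions are combined with the constant
    pairwise correlation ``rho_cross``:
    Var = (1 - rho) sum sd_k^2 + rho (sum sd_k)^2.
    """
    km = kaplan_meier(sample)
    ev = km.knots[km.knots < tau]
    edges = np.concatenate([[0.0], ev, [tau]])
    left, widths = edges[:-1], np.diff(edges)
    area = float(np.sum(km.at(left) * widths))
    sd = np.sqrt(np.clip(km.variance_at(left), 0.0, None)) * widths
    var = (1.0 - rho_cross) * float(np.sum(sd**2)) \
        + rho_cross * float(np.sum(sd)) ** 2
    return area, var


def lx_test(sample1: SurvivalSample, sample2: SurvivalSample,
            config: LXConfig | None = None) -> TestResult:
    """Lin-Xu area-between-curves test.

    Compares the areas A_i under the two KM curves up to t_tau through
    Z = (A1 - A2) / sqrt(Var A1 + Var A2).  The one-sided version (LX1)
    is oriented as group 1 minus group 2, p = P(N(0,1) >= Z); the
    two-sided version (LX2) tests |Z|.
    """
    config = config or LXConfig()
    table = build_risk_table(sample1, sample2)
    if table.tau_index < 0:
        return TestResult("LX", 0.0, 1.0, extras={"degenerate": True})
    tau = table.tau
    a1, v1 = _restricted_area(sample1, tau, config.rho_cross)
    a2, v2 = _restricted_area(sample2, tau, config.rho_cross)
    V = v1 + v2
    if V <= 0:
        return TestResult("LX", 0.0, 1.0, V, extras={"degenerate": True})
    z = (a1 - a2) / np.sqrt(V)
    if config.sided == "one":
        return TestResult("LX1", float(z), float(stats.norm.sf(z)), V,
                          sided="one", extras={"area1": a1, "area2": a2})
    return TestResult("LX2", float(abs(z)),
                      float(min(1.0, 2.0 * stats.norm.sf(abs(z)))), V,
                      sided="two", extras={"area1": a1, "area2": a2})


def lw_test(sample1: SurvivalSample, sample2: SurvivalSample,
            permutations: int = 2000, seed: int | None = None) -> TestResult:
    """Lin-Wang squared observed-minus-expected test, permutation p-value.

    T = sum_{j<=tau} (d1_j - n1_j d_j / n_j)^2.  The reference law is the
    group-label permutation distribution of T (the risk table is re-derived
    for every relabelling), which is exact under exchangeability.
    """
    pp = PooledPermutation(sample1, sample2)
    t_obs = float(pp.lw_stat(pp.observed_membership[None, :])[0])
    rng = np.random.default_rng(seed)
    memb = pp.random_memberships(permutations, rng)
    t_perm = pp.lw_stat(memb)
    p = (1 + int(np.sum(t_perm >= t_obs - 1e-12))) / (permutations + 1)
    return TestResult("LW", t_obs, float(p),
                      extras={"permutations": permutations})
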