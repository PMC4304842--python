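"""Qiu-Sheng style two-stage procedure for crossing hazards.

Stage 1 is the ordinary log-rank test.  If it does not reject at its
allotted level, stage 2 runs a weighted log-rank statistic whose weight
flips sign at a candidate crossing point: for each admissible split k the
weight is +1 for risk-table rows up to k and -1 afterwards, and the stage-2
statistic is the maximum absolute standardized value over splits.  Its null
distribution is obtained by group-label permutation, which is exact under
exchangeability.  The two stages are asymptotically independent under the
null, so spending alpha_1 = alpha_2 = 1 - sqrt(1 - alpha) keeps the overall
level at alpha:  alpha_1 + (1 - alpha_1) alpha_2 = alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._engine import PooledPermutation
from .survcore import RiskTable, SurvivalSample, build_risk_table
from .wlr_tests import TestResult, WeightSpec, weighted_logrank

__all__ = ["TwoStageResult", "estimate_crossing", "ts_test"]


@dataclass
class TwoStageResult:
    """Outcome of the two-stage procedure.

    ``stage2`` and ``crossing_estimate`` are None when stage 1 already
    rejected (or when the risk table was too short for a sign-change
    weight).  ``p_overall`` combines the stage p-values via independence,
    1 - (1 - p1)(1 - p2); the rejection decision itself is taken per
    stage at levels alpha_1 = alpha_2 = 1 - sqrt(1 - alpha).
    """

    stage1: TestResult
    stage2: TestResult | None
    crossing_estimate: float | None
    p_overall: float
    reject: bool
    alpha_stage: float


def estimate_crossing(table: RiskTable) -> tuple[int, float]:
    """Best sign-change split of the risk table.

    For each candidate split k (excluding the first and last rows at or
    before tau) compute the standardized statistic with weight +1 for rows
    <= k and -1 beyond; return the 0-based row index maximizing the
    absolute standardized statistic, and that maximum.

    Raises ``ValueError`` when fewer than 3 rows precede tau.
    """
    m = table.tau_index + 1
    if m < 3:
        raise ValueError("need at least 3 risk-table rows at or before tau")
    e, v = table.logrank_terms()
    e, v = e[:m], v[:m]
    V = float(v.sum())
    cum = np.cumsum(e)
    u_split = 2.0 * cum - cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(u_split) / np.sqrt(V) if V > 0 else np.zeros(m)
    z[0] = -np.inf
    z[m - 1] = -np.inf
    k = int(np.argmax(z[: m]))
    stat = float(z[k]) if np.isfinite(z[k]) else 0.0
    return k, stat


def ts_test(sample1: SurvivalSample, sample2: SurvivalSample,
            alpha: float = 0.05, permutations: int = 2000,
            seed: int | None = None) -> TwoStageResult:
    """Run the two-stage procedure.

    Stage-2 calibration permutes group labels of the pooled (time, status)
    pairs, recomputing the max-over-splits statistic (with its own
    truncation rule) for every relabelling.
    """
    alpha_stage = 1.0 - np.sqrt(1.0 - alpha)
    table = build_risk_table(sample1, sample2)
    stage1 = weighted_logrank(table, WeightSpec.logrank())
    p1 = stage1.p_value

    if p1 <= alpha_stage or stage1.degenerate:
        return TwoStageResult(stage1, None, None, p_overall=float(p1),
                              reject=bool(p1 <= alpha_stage),
                              alpha_stage=float(alpha_stage))

    if table.tau_index + 1 < 3:
        # no admissible sign-change split: fall back to stage 1 only
        return TwoStageResult(stage1, None, None, p_overall=float(p1),
                              reject=False, alpha_stage=float(alpha_stage))

    k, stat_obs = estimate_crossing(table)
    crossing_time = float(table.event_times[k])

    pp = PooledPermutation(sample1, sample2)
    rng = np.random.default_rng(seed)
    memb = pp.random_memberships(permutations, rng)
    stat_perm, _ = pp.split_max_stat(memb)
    p2 = (1 + int(np.sum(stat_perm >= stat_obs - 1e-12))) / (permutations + 1)
    stage2 = TestResult("TS-stage2", stat_obs, float(p2),
                        extras={"split_index": k,
                                "crossing_time": crossing_time,
                                "permutations": permutations})
    p_overall = float(np.clip(1.0 - (1.0 - p1) * (1.0 - p2), 0.0, 1.0))
    return TwoStageResult(stage1, stage2, crossing_time,
                          p_overall=p_overall,
                          reject=bool(p2 <= alpha_stage),
                          alpha_stage=float(alpha_stage))
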