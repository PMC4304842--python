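"""Monte Carlo harness for power and type-I-error estimation.

``run_monte_carlo`` repeatedly draws a replicate pair from a scenario,
runs one registered test, and reports the rejection proportion at the
chosen significance level together with its Monte Carlo standard error.
Replicates use pre-spawned independent random streams from a single
master seed, so results are reproducible bit-for-bit and independent of
evaluation order.

A replicate on which a test flags a degenerate variance counts as a
non-rejection (an uninformative sample cannot reject) and is tallied in
the result's ``degenerate`` counter.

Permutation-calibrated tests (LW, the two-stage second stage, NY1/NY2)
accept a reduced permutation budget inside benchmarks; the default here
is 500 against the 2000 used for one-off analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .km_diff_tests import LXConfig, MKMConfig, lw_test, lx_test, mkm_test, wkm_test
from .neyman_smooth import NYConfig, ny_test
from .simulate import ScenarioConfig, generate_scenario
from .sup_tests import cvm_tests, mks_test, renyi_test
from .survcore import NoEventsError, build_risk_table
from .two_stage import ts_test
from .wlr_tests import TestResult, WeightSpec, shl_combined, weighted_logrank

__all__ = ["MCResult", "run_monte_carlo", "summarize_table",
           "TEST_REGISTRY", "run_test"]


# ----------------------------------------------------------------------
# registry: name -> callable(sample1, sample2, seed, permutations) -> TestResult

def _wlr(weight: WeightSpec):
    def run(s1, s2, seed=None, permutations=None):
        return weighted_logrank(build_risk_table(s1, s2), weight)
    return run


def _shl(which: str):
    def run(s1, s2, seed=None, permutations=None):
        return getattr(shl_combined(build_risk_table(s1, s2)), which)
    return run


def _renyi(s1, s2, seed=None, permutations=None):
    return renyi_test(build_risk_table(s1, s2))


def _mks(s1, s2, seed=None, permutations=None):
    return mks_test(build_risk_table(s1, s2))


def _cvm(index: int):
    def run(s1, s2, seed=None, permutations=None):
        return cvm_tests(build_risk_table(s1, s2))[index]
    return run


def _wkm(s1, s2, seed=None, permutations=None):
    return wkm_test(s1, s2)


def _mkm(s1, s2, seed=None, permutations=None):
    return mkm_test(s1, s2, MKMConfig(seed=seed, mc_draws=20_000))


def _lx(sided: str):
    def run(s1, s2, seed=None, permutations=None):
        return lx_test(s1, s2, LXConfig(sided=sided))
    return run


def _lw(s1, s2, seed=None, permutations=None):
    return lw_test(s1, s2, permutations=permutations or 2000, seed=seed)


def _ts(s1, s2, seed=None, permutations=None):
    res = ts_test(s1, s2, permutations=permutations or 2000, seed=seed)
    out = TestResult("TS", float("nan"), res.p_overall,
                     extras={"reject": res.reject,
                             "crossing_estimate": res.crossing_estimate})
    if res.stage1.degenerate:
        out.extras["degenerate"] = True
    return out


def _ny(method: str):
    def run(s1, s2, seed=None, permutations=None):
        cfg = NYConfig(permutations=permutations or 2000, seed=seed)
        return ny_test(s1, s2, cfg, method=method)
    return run


# Column order mirrors the conventional reporting order of the suite.
TEST_REGISTRY: dict[str, Callable] = {
    "LR": _wlr(WeightSpec.logrank()),
    "GW": _wlr(WeightSpec.gehan()),
    "TW": _wlr(WeightSpec.tarone_ware()),
    "G01": _wlr(WeightSpec.fleming_harrington(0, 1)),
    "G10": _wlr(WeightSpec.fleming_harrington(1, 0)),
    "G11": _wlr(WeightSpec.fleming_harrington(1, 1)),
    "RY": _renyi,
    "MKS": _mks,
    "CVM1": _cvm(0),
    "CVM2": _cvm(1),
    "WKM": _wkm,
    "MKM": _mkm,
    "SHL1": _shl("shl1"),
    "SHL2": _shl("shl2"),
    "SHL3": _shl("shl3"),
    "LW": _lw,
    "LX1": _lx("one"),
    "LX2": _lx("two"),
    "TS": _ts,
    "NY1": _ny("ny1"),
    "NY2": _ny("ny2"),
}


def run_test(name: str, s1, s2, seed=None, permutations=None) -> TestResult:
    """Run one registered test by name."""
    try:
        fn = TEST_REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown test {name!r}; choices: "
                         f"{', '.join(TEST_REGISTRY)}") from None
    return fn(s1, s2, seed=seed, permutations=permutations)


@dataclass
class MCResult:
    """Aggregated Monte Carlo rejection rate for one test and scenario."""

    test: str
    scenario: str
    n1: int
    n2: int
    censoring_rate: float
    reps: int
    alpha: float
    rejections: int
    degenerate: int
    seed: int | None

    @property
    def proportion(self) -> float:
        return self.rejections / self.reps

    @property
    def mc_se(self) -> float:
        p = self.proportion
        return float(np.sqrt(p * (1.0 - p) / self.reps))


def _rejects(result, alpha: float) -> bool:
    if isinstance(result, TestResult):
        if result.degenerate:
            return False
        if "reject" in result.extras:
            return bool(result.extras["reject"])
        return result.p_value <= alpha
    raise TypeError(f"unexpected result type {type(result)!r}")


def run_monte_carlo(test, scenario: ScenarioConfig, reps: int = 5000,
                    alpha: float = 0.05, seed: int | None = None,
                    permutations: int = 500) -> MCResult:
    """Estimate a rejection proportion by simulation.

    ``test`` is a registry name or a callable with the registry signature.
    Each replicate receives two child seeds spawned from the master seed:
    one for data generation, one for any randomness inside the test
    (permutations or Monte Carlo calibration).
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    fn = TEST_REGISTRY[test] if isinstance(test, str) else test
    name = test if isinstance(test, str) else getattr(test, "__name__", "custom")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(reps)
    rejections = 0
    degenerate = 0
    for ss in streams:
        data_seed, test_seed = ss.spawn(2)
        s1, s2 = generate_scenario(scenario, np.random.default_rng(data_seed))
        try:
            res = fn(s1, s2,
                     seed=int(test_seed.generate_state(1)[0] % (2**31)),
                     permutations=permutations)
        except NoEventsError:
            degenerate += 1
            continue
        if isinstance(res, TestResult) and res.degenerate:
            degenerate += 1
            continue
        if _rejects(res, alpha):
            rejections += 1
    return MCResult(test=name, scenario=scenario.label,
                    n1=scenario.n1, n2=scenario.n2,
                    censoring_rate=scenario.censoring.target_rate,
                    reps=reps, alpha=alpha, rejections=rejections,
                    degenerate=degenerate, seed=seed)


def summarize_table(results) -> pd.DataFrame:
    """Pivot a collection of MCResult into a (size, censoring) x test table.

    Columns follow the registry order; missing cells stay blank (NaN).
    """
    rows = []
    for r in results:
        rows.append({
            "N": f"({r.n1}, {r.n2})",
            "CENR": f"{round(100 * r.censoring_rate):d}%",
            "scenario": r.scenario,
            "test": r.test,
            "proportion": r.proportion,
        })
    df = pd.DataFrame(rows)
    table = df.pivot_table(index=["scenario", "N", "CENR"], columns="test",
                           values="proportion", aggfunc="first")
    order = [t for t in TEST_REGISTRY if t in table.columns]
    extra = [t for t in table.columns if t not in TEST_REGISTRY]
    return table[order + extra]
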