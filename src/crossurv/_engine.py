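"""Vectorized group-label permutation machinery.

Permuting group labels leaves the pooled sample -- hence the pooled event
grid, the pooled death counts d_j, the pooled at-risk counts n_j and the
pooled Kaplan-Meier / Nelson-Aalen estimates -- unchanged.  Only the
group-1 counts (n1_j, d1_j) move.  This module precomputes the fixed
pooled structure once and obtains the per-permutation counts for a whole
batch of label assignments with two matrix products, so permutation
p-values cost a few matmuls instead of thousands of risk-table rebuilds.
"""

from __future__ import annotations

import numpy as np

from .survcore import NoEventsError, RiskTable, SurvivalSample

__all__ = ["PooledPermutation"]


class PooledPermutation:
    """Pooled structure of a two-sample dataset plus batched label counts.

    Parameters
    ----------
    sample1, sample2:
        The two arms.  The pooled event grid and pooled counts are fixed;
        membership vectors select which subjects belong to group 1.
    """

    def __init__(self, sample1: SurvivalSample, sample2: SurvivalSample):
        times = np.concatenate([sample1.times, sample2.times])
        status = np.concatenate([sample1.status, sample2.status])
        if status.sum() == 0:
            raise NoEventsError("no events observed in either group")
        self.times = times
        self.status = status
        self.n_total = times.size
        self.n1_size = sample1.size
        self.n2_size = sample2.size

        self.event_times = np.unique(times[status == 1])  # (J,)
        J = self.event_times.size
        # subject-by-row indicators
        self.at_risk = (times[:, None] >= self.event_times[None, :]).astype(float)
        self.death = ((times[:, None] == self.event_times[None, :])
                      & (status[:, None] == 1)).astype(float)
        self.d = self.death.sum(axis=0)          # pooled deaths (J,)
        self.n = self.at_risk.sum(axis=0)        # pooled at risk (J,)
        # pooled Nelson-Aalen increments and KM left limits are fixed
        self.dlambda = self.d / self.n
        self.cumhaz = np.cumsum(self.dlambda)
        # midpoint of each Nelson-Aalen step: the smooth-test time
        # transform evaluates basis functions here (continuity correction)
        self.cumhaz_mid = self.cumhaz - 0.5 * self.dlambda
        km = np.cumprod(1.0 - self.dlambda)
        self.km_left = np.concatenate([[1.0], km[:-1]])
        self.observed_membership = np.concatenate([
            np.ones(sample1.size), np.zeros(sample2.size)
        ])

    # ------------------------------------------------------------------
    def random_memberships(self, n_perm: int, rng: np.random.Generator) -> np.ndarray:
        """(n_perm, N) 0/1 matrix: label permutations preserving group sizes."""
        u = rng.random((n_perm, self.n_total))
        order = np.argsort(u, axis=1)
        memb = np.zeros((n_perm, self.n_total))
        rows = np.arange(n_perm)[:, None]
        memb[rows, order[:, : self.n1_size]] = 1.0
        return memb

    def all_memberships(self) -> np.ndarray:
        """Every group assignment of size n1 (for exhaustive small-n oracles)."""
        from itertools import combinations

        combos = list(combinations(range(self.n_total), self.n1_size))
        memb = np.zeros((len(combos), self.n_total))
        for i, c in enumerate(combos):
            memb[i, list(c)] = 1.0
        return memb

    def counts(self, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-permutation group-1 at-risk and death counts, each (P, J)."""
        membership = np.atleast_2d(membership)
        n1 = membership @ self.at_risk
        d1 = membership @ self.death
        return n1, d1

    # ------------------------------------------------------------------
    def terms(self, membership: np.ndarray):
        """Batched log-rank building blocks.

        Returns ``(e, v, mask)`` each of shape (P, J): observed-minus-
        expected increments, hypergeometric variances, and the tau mask
        (True for rows where both groups still have somebody at risk;
        because at-risk counts are non-increasing this is a prefix).
        """
        n1, d1 = self.counts(membership)
        d, n = self.d, self.n
        e = d1 - n1 * d / n
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (n1 / n) * (1.0 - n1 / n) * d * (n - d) / (n - 1.0)
        v = np.where(n > 1, v, 0.0)
        mask = (n1 >= 1) & ((n - n1) >= 1)
        return e, v * mask, mask

    def logrank_z(self, membership: np.ndarray) -> np.ndarray:
        """Batched standardized log-rank statistics, shape (P,)."""
        e, v, mask = self.terms(membership)
        U = (e * mask).sum(axis=1)
        V = v.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(V > 0, U / np.sqrt(V), 0.0)
        return z

    def lw_stat(self, membership: np.ndarray) -> np.ndarray:
        """Batched sum of squared observed-minus-expected increments."""
        e, _, mask = self.terms(membership)
        return (e**2 * mask).sum(axis=1)

    def split_max_stat(self, membership: np.ndarray):
        """Batched max-over-splits sign-change statistic.

        For each candidate split k (excluding the first and last rows at
        or before tau) the weight is +1 for rows <= k and -1 after; the
        statistic is max_k |U_k| / sqrt(V) with V the unweighted log-rank
        variance.  Returns ``(stat, argmax_row)``.
        """
        e, v, mask = self.terms(membership)
        em = e * mask
        cum = np.cumsum(em, axis=1)
        total = cum[:, -1:]
        u_split = 2.0 * cum - total          # (P, J), split after row k
        V = v.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(V > 0, np.abs(u_split) / np.sqrt(V), 0.0)
        # candidate splits: rows 1 .. tau_index-1 (0-based), need >=3 rows
        n_valid = mask.sum(axis=1)           # (P,)
        cols = np.arange(e.shape[1])[None, :]
        candidate = (cols >= 1) & (cols <= (n_valid[:, None] - 2)) & mask
        z = np.where(candidate, z, -np.inf)
        stat = z.max(axis=1)
        stat = np.where(np.isfinite(stat), stat, 0.0)
        argmax = z.argmax(axis=1)
        return stat, argmax

    def smooth_T(self, membership: np.ndarray, d_max: int,
                 ridge: float = 0.0) -> np.ndarray:
        """Batched nested smooth-test statistics T_d for d = 1..d_max.

        The time transform x_j = Lambda(t_j)/Lambda(t_tau) uses the pooled
        Nelson-Aalen estimate (fixed across permutations) normalized by
        its value at the per-permutation truncation row.  Basis functions
        are shifted Legendre polynomials, orthonormal on [0, 1], degree
        1..d_max.  Returns an array of shape (P, d_max); entries where the
        score covariance is singular fall back to a pseudo-inverse.
        """
        e, v, mask = self.terms(membership)
        P, J = e.shape
        n_valid = mask.sum(axis=1).astype(int)
        tau_idx = np.maximum(n_valid - 1, 0)
        lam_tau = self.cumhaz[tau_idx][:, None]   # (P,1)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(lam_tau > 0, self.cumhaz_mid[None, :] / lam_tau, 0.0)
        x = np.clip(x, 0.0, 1.0)
        phi = _shifted_legendre(x, d_max)          # (d_max, P, J)
        em = e * mask
        U = np.einsum("kpj,pj->pk", phi, em)       # (P, d_max)
        Sigma = np.einsum("kpj,lpj,pj->pkl", phi, phi, v)  # (P, d, d)
        out = np.empty((P, d_max))
        for d in range(1, d_max + 1):
            Ud = U[:, :d]
            Sd = Sigma[:, :d, :d]
            if ridge:
                Sd = Sd + ridge * np.eye(d)
            out[:, d - 1] = _batched_quadform(Ud, Sd)
        return out

    def select_dimension(self, T: np.ndarray, n_events: float,
                         d0: int = 0) -> np.ndarray:
        """Schwarz rule: argmax_d T_d - (d - d0) log(n_events), d > d0."""
        d_max = T.shape[1]
        dims = np.arange(1, d_max + 1)
        penalty = (dims - d0) * np.log(max(n_events, 1.0))
        crit = T - penalty[None, :]
        crit[:, : d0] = -np.inf  # force d >= d0 + 1
        return crit.argmax(axis=1) + 1  # ties -> smaller d via argmax


def _shifted_legendre(x: np.ndarray, d_max: int) -> np.ndarray:
    """Orthonormal shifted Legendre polynomials degree 1..d_max on [0, 1].

    phi_k(x) = sqrt(2k+1) P_k(2x - 1); returned shape is (d_max,) + x.shape.
    """
    u = 2.0 * x - 1.0
    polys = np.empty((d_max + 1,) + x.shape)
    polys[0] = 1.0
    if d_max >= 1:
        polys[1] = u
    for k in range(1, d_max):
        polys[k + 1] = ((2 * k + 1) * u * polys[k] - k * polys[k - 1]) / (k + 1)
    norms = np.sqrt(2.0 * np.arange(1, d_max + 1) + 1.0)
    return polys[1:] * norms.reshape((d_max,) + (1,) * x.ndim)


def _batched_quadform(U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """U' S^{-1} U for stacks of vectors/matrices, pseudo-inverse fallback."""
    try:
        sol = np.linalg.solve(S, U[..., None])[..., 0]
        out = np.einsum("pk,pk->p", U, sol)
        bad = ~np.isfinite(out) | (out < 0)
    except np.linalg.LinAlgError:
        bad = np.ones(U.shape[0], dtype=bool)
        out = np.empty(U.shape[0])
    if bad.any():
        pinv = np.linalg.pinv(S[bad], rcond=1e-10, hermitian=True)
        sol = np.einsum("pkl,pl->pk", pinv, U[bad])
        out[bad] = np.einsum("pk,pk->p", U[bad], sol)
    return np.maximum(out, 0.0)


def risk_table_from_pooled(pp: PooledPermutation,
                           membership: np.ndarray) -> RiskTable:
    """Materialize an ordinary :class:`RiskTable` for one membership row."""
    n1, d1 = pp.counts(membership)
    n1, d1 = n1[0], d1[0]
    both = (n1 >= 1) & ((pp.n - n1) >= 1)
    tau_index = int(np.max(np.nonzero(both)[0])) if both.any() else -1
    n1_size = int(membership.sum())
    return RiskTable(
        event_times=pp.event_times, d=pp.d, d1=d1,
        n=pp.n, n1=n1, n2=pp.n - n1,
        tau_index=tau_index,
        n_total1=n1_size, n_total2=pp.n_total - n1_size,
    )
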