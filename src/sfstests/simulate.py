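"""Coalescent/Poisson SFS simulator: scenario spectra, critical values and power.

The simulator works in two stages that mirror the independent-sites
(free-recombination, small-theta) regime:

1.  *Genealogy stage* — Monte-Carlo structured-coalescent sampling of mean
    per-class branch lengths, giving the alternative spectrum shape
    xibar_i = E(ell_i)/2 with time in units of 2N generations (so the
    single-population neutral limit is exactly 1/i).  Two demographic
    scenarios are built in besides the neutral one:

    * ``subdivision(M)`` — two demes of size N/2 exchanging migrants at
      scaled symmetric rate M (per-lineage migration rate M/2, within-deme
      pair coalescence rate 2), with all n lineages sampled from deme 1.
      As M -> infinity the demes merge into a single population of size N and
      the spectrum returns to 1/i exactly, magnitude included.
    * ``expansion(T, growth)`` — a step size change by a factor
      growth = N0/N at time T before present.  The present size N0 is the
      reference: theta = 2 p mu N0, T is in units of 4 N0 generations, the
      pair coalescence rate is 1 more recently than T and N0/N (faster, the
      ancestral population being smaller) beyond it.  As T -> infinity the
      neutral spectrum is recovered.

2.  *Mutation stage* — given a mean spectrum mu_i = theta * L * xibar_i, SFS
    replicates are independent Poisson draws per class.

Critical values are empirical quantiles of a test statistic over null
replicates; power is the fraction of alternative replicates beyond them, with
binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .linear_tests import LinearTest
from .nonlinear_tests import PolynomialTest

__all__ = [
    "ScenarioConfig",
    "StatisticSpec",
    "as_test_spec",
    "expected_branch_spectrum",
    "sample_sfs",
    "critical_values",
    "rejection_rate",
    "power_study",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A demographic scenario for the genealogy stage.

    kind: "neutral", "subdivision" (param M > 0: scaled symmetric migration
    rate) or "expansion" (params T > 0 in units of 4N generations and
    growth = N0/N > 0).
    """

    kind: str
    n: int
    theta: float = 0.05
    L: int = 1000
    M: Optional[float] = None
    T: Optional[float] = None
    growth: float = 10.0
    genealogies: int = 100_000
    seed: int = 1

    def __post_init__(self):
        if self.kind not in ("neutral", "subdivision", "expansion"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "subdivision" and (self.M is None or self.M <= 0):
            raise ValueError("subdivision requires M > 0")
        if self.kind == "expansion":
            if self.T is None or self.T <= 0:
                raise ValueError("expansion requires T > 0")
            if self.growth <= 0:
                raise ValueError("expansion requires growth factor > 0")
        if self.n < 2:
            raise ValueError("n >= 2 required")

    @property
    def label(self) -> str:
        if self.kind == "subdivision":
            return f"subdivision(M={self.M:g})"
        if self.kind == "expansion":
            return f"expansion(T={self.T:g},N0/N={self.growth:g})"
        return "neutral"


# ---------------------------------------------------------------------------
# genealogy kernels (numba)
#
# Branch lengths are accumulated per subtended-leaf count; lineage state is a
# pair of integer arrays (deme, descendant count).  All exponential clocks are
# competing risks; times are in units of 2N generations.

@njit(cache=True)
def _subdivision_kernel(n, M, reps, seed):
    np.random.seed(seed)
    ell = np.zeros(n)      # index j: total branch length subtending j leaves
    ell2 = np.zeros(n)     # per-replicate sums of squares, for standard errors
    for _ in range(reps):
        deme = np.zeros(n, dtype=np.int64)   # all sampled from deme 1 (=0)
        desc = np.ones(n, dtype=np.int64)
        k = n
        rep = np.zeros(n)
        while k > 1:
            k0 = 0
            for a in range(k):
                if deme[a] == 0:
                    k0 += 1
            k1 = k - k0
            # demes of size N/2 => pair coalescence rate 2 per pair
            rc0 = 2.0 * k0 * (k0 - 1) / 2.0
            rc1 = 2.0 * k1 * (k1 - 1) / 2.0
            rm = k * M / 2.0
            total = rc0 + rc1 + rm
            dt = np.random.exponential(1.0 / total)
            for a in range(k):
                rep[desc[a] - 1] += dt
            u = np.random.random() * total
            if u < rc0 + rc1:
                target = 0 if u < rc0 else 1
                # uniform pair within the target deme
                kd = k0 if target == 0 else k1
                p = np.random.randint(kd * (kd - 1) // 2)
                # map p to an (a_idx, b_idx) pair among lineages of the deme
                a_pick = 0
                while p >= kd - 1 - a_pick:
                    p -= kd - 1 - a_pick
                    a_pick += 1
                b_pick = a_pick + 1 + p
                ai = -1
                bi = -1
                cnt = -1
                for a in range(k):
                    if deme[a] == target:
                        cnt += 1
                        if cnt == a_pick:
                            ai = a
                        elif cnt == b_pick:
                            bi = a
                desc[ai] += desc[bi]
                desc[bi] = desc[k - 1]
                deme[bi] = deme[k - 1]
                k -= 1
            else:
                a = np.random.randint(k)
                deme[a] = 1 - deme[a]
        for j in range(n):
            ell[j] += rep[j]
            ell2[j] += rep[j] * rep[j]
    return ell, ell2


@njit(cache=True)
def _expansion_kernel(n, tau, rate_ancient, reps, seed):
    # single population; pair coalescence rate 1 for t < tau, rate_ancient after
    np.random.seed(seed)
    ell = np.zeros(n)
    ell2 = np.zeros(n)
    for _ in range(reps):
        desc = np.ones(n, dtype=np.int64)
        k = n
        t = 0.0
        rep = np.zeros(n)
        while k > 1:
            pair = k * (k - 1) / 2.0
            rate = pair * (1.0 if t < tau else rate_ancient)
            dt = np.random.exponential(1.0 / rate)
            if t < tau and t + dt > tau:
                # clock crosses the size change: advance to the boundary and redraw
                for a in range(k):
                    rep[desc[a] - 1] += tau - t
                t = tau
                continue
            for a in range(k):
                rep[desc[a] - 1] += dt
            t += dt
            p = np.random.randint(k * (k - 1) // 2)
            a_pick = 0
            while p >= k - 1 - a_pick:
                p -= k - 1 - a_pick
                a_pick += 1
            b_pick = a_pick + 1 + p
            desc[a_pick] += desc[b_pick]
            desc[b_pick] = desc[k - 1]
            k -= 1
        for j in range(n):
            ell[j] += rep[j]
            ell2[j] += rep[j] * rep[j]
    return ell, ell2


def expected_branch_spectrum(config: ScenarioConfig):
    """Mean spectrum shape xibar (per unit theta*L) with Monte-Carlo SEs.

    The neutral case is analytic (exactly 1/i).  Otherwise mean per-class
    branch lengths are averaged over ``config.genealogies`` sampled
    genealogies and divided by 2, so that a single population of size N gives
    1/i.  Returns ``(xibar, se)`` over classes i = 1..n-1.
    """
    n = config.n
    i = np.arange(1, n)
    if config.kind == "neutral":
        return 1.0 / i, np.zeros(n - 1)
    reps = config.genealogies
    seed = int(config.seed) % (2**31 - 1)
    if config.kind == "subdivision":
        ell, ell2 = _subdivision_kernel(n, float(config.M), reps, seed)
    else:
        tau = 2.0 * float(config.T)           # 4N0 generations -> units of 2N0
        ell, ell2 = _expansion_kernel(n, tau, float(config.growth), reps, seed)
    mean = ell[: n - 1] / reps
    var = ell2[: n - 1] / reps - mean**2
    se = np.sqrt(np.maximum(var, 0.0) / reps)
    return mean / 2.0, se / 2.0


def sample_sfs(mu: np.ndarray, replicates: int, seed: int) -> np.ndarray:
    """Independent-sites SFS replicates: rows of Poisson(mu_i) draws."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mean spectrum must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(mu, size=(replicates, len(mu))).astype(float)


# ---------------------------------------------------------------------------
# evaluating a heterogeneous collection of tests on replicate matrices

@dataclass
class StatisticSpec:
    """A test plus the tail(s) it rejects on, for the power machinery."""

    name: str
    tail: str  # "left" | "right" | "both"
    evaluate_many: callable  # (X: replicates x classes) -> statistics


def as_test_spec(test, mu_null: np.ndarray, tail: str) -> StatisticSpec:
    """Adapt a LinearTest or PolynomialTest to the power-study interface.

    Linear statistics are normalised with the analytic independent-sites null
    variance at the known-theta mean ``mu_null``; polynomial tests carry
    their own construction model.
    """
    if isinstance(test, LinearTest):
        var = float(np.sum(test.w**2 * mu_null))
        return StatisticSpec(test.name, tail, lambda X, t=test, v=var: t.evaluate_many(X, v))
    if isinstance(test, PolynomialTest):
        return StatisticSpec(test.name, tail, lambda X, t=test: t.evaluate_many(X))
    raise TypeError(f"unsupported test object {type(test)!r}")


def critical_values(stats: np.ndarray, alpha: float, tail: str = "both"):
    """Empirical critical values from null statistics.

    ``both`` returns the (alpha/2, 1-alpha/2) quantiles; one-sided tails put
    the whole alpha in that tail and the other bound at +-inf.
    """
    stats = np.asarray(stats, dtype=float)
    if len(stats) < 1000:
        raise ValueError("at least 1e3 null replicates are required for critical values")
    if np.ptp(stats) == 0.0:
        import warnings
        warnings.warn("degenerate null distribution: all statistics identical")
    if tail == "both":
        return (float(np.quantile(stats, alpha / 2)),
                float(np.quantile(stats, 1 - alpha / 2)))
    if tail == "left":
        return float(np.quantile(stats, alpha)), math.inf
    if tail == "right":
        return -math.inf, float(np.quantile(stats, 1 - alpha))
    raise ValueError(f"unknown tail {tail!r}")


def rejection_rate(stats: np.ndarray, lower: float, upper: float) -> float:
    stats = np.asarray(stats, dtype=float)
    return float(np.mean((stats < lower) | (stats > upper)))


def _binomial_ci(p: float, m: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2)
    denom = 1 + z**2 / m
    centre = (p + z**2 / (2 * m)) / denom
    half = z * math.sqrt(p * (1 - p) / m + z**2 / (4 * m**2)) / denom
    return max(centre - half, 0.0), min(centre + half, 1.0)


def power_study(tests: Sequence[StatisticSpec], null_mu: np.ndarray,
                alt_mus: dict, alpha: float = 0.05, replicates: int = 100_000,
                seed: int = 1, null_replicates: Optional[int] = None) -> pd.DataFrame:
    """Monte-Carlo power of a set of tests across alternative scenarios.

    ``alt_mus`` maps a scenario label to its mean spectrum (same dimension as
    ``null_mu``).  Critical values are estimated once per test from
    ``null_replicates`` null draws (4x ``replicates`` by default, so that
    threshold noise is small against the rejection-rate noise), then applied
    to fresh replicates of every alternative.  Returns a tidy frame with
    Wilson 95% confidence intervals.
    """
    null_replicates = null_replicates or 4 * replicates
    X0 = sample_sfs(null_mu, null_replicates, seed)
    thresholds = {}
    for t in tests:
        thresholds[t.name] = critical_values(t.evaluate_many(X0), alpha, t.tail)
    rows = []
    for j, (label, mu) in enumerate(alt_mus.items()):
        if len(mu) != len(null_mu):
            raise ValueError(f"scenario {label!r}: dimension mismatch with the null")
        X = sample_sfs(mu, replicates, seed + 1000 + j)
        for t in tests:
            lo, hi = thresholds[t.name]
            p = rejection_rate(t.evaluate_many(X), lo, hi)
            ci_lo, ci_hi = _binomial_ci(p, replicates)
            rows.append({"scenario": label, "test": t.name, "tail": t.tail,
                         "power": p, "ci_lo": ci_lo, "ci_hi": ci_hi,
                         "alpha": alpha, "replicates": replicates, "seed": seed})
    return pd.DataFrame(rows)
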