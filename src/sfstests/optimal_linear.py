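"""Optimal linear tests, Gaussian power, generalised optimisation and the tunable family.

Optimal linear tests maximise the expected value of the normalised statistic
under a specified alternative scenario with mean spectrum shape xibar.  With
the scalar product between spectra defined through the inverse covariance,

    <x, y> = sum_ij x_i (c^-1)_ij y_j,

the optimal test has the geometric form

    T_O = (<xi, xibar> - <xi, xi0> <xi0, xibar> / <xi0, xi0>)
          / sqrt(<xibar, xibar> - <xi0, xibar>^2 / <xi0, xi0>),

i.e. the component of the observed spectrum along the deviation of xibar from
the span of the neutral shape xi0.  Adding any multiple of xi0 to xibar
leaves the test unchanged.

Beyond maximising the mean, any optimisation criterion M(E, V) built from the
mean E and variance V of the test under the alternative (power at a given
significance level, variance-penalised mean, ...) is maximised within the
one-parameter "tunable" family

    Omega_i(lambda) = (1/i) [1 - a_n / ((1 + lambda i xibar_i)
                      sum_j 1/(j (1 + lambda j xibar_j)))],

whose lambda -> 0+ direction reproduces the usual optimal weights
xibar_i - (1/i) sum_j xibar_j / a_n.

Two z-value conventions appear in the power formulas: the erf convention
tau = erfinv(1 - 2 alpha) and the Phi convention tau = Phi^-1(1 - alpha) =
sqrt(2) erfinv(1 - 2 alpha).  ``gaussian_power`` uses the exact Gaussian
expression in the Phi convention; ``gaussian_power_erf_form`` evaluates the
erf-convention closed form literally (the two coincide where the alternative
equals the null and for alpha = power = 1/2 but differ by sqrt(2) factors in
between; see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erf, erfinv
from scipy.stats import norm

from .linear_tests import CovarianceModel
from .spectrum import SpectrumCounts, harmonic

__all__ = [
    "ScenarioSpectra",
    "OptimisationCriterion",
    "OptimiseResult",
    "scalar_product",
    "optimal_linear_test",
    "optimal_linear_weights",
    "optimal_max_value",
    "gaussian_power",
    "gaussian_power_erf_form",
    "tunable_weights",
    "tunable_limit_direction",
    "optimise",
]


@dataclass
class ScenarioSpectra:
    """Null and alternative mean spectrum shapes with their covariance models.

    ``xi0`` and ``xibar`` are per-unit-theta*L shapes (the neutral shape is
    1/i); actual expected counts are theta * L * shape.  ``cov_null`` defaults
    to the independent-sites diagonal Poisson covariance at the null mean, and
    ``cov_alt`` (needed by power criteria) to the one at the alternative mean.
    """

    n: int
    xibar: np.ndarray
    theta: float
    L: int
    xi0: Optional[np.ndarray] = None
    cov_null: Optional[CovarianceModel] = None
    cov_alt: Optional[CovarianceModel] = None
    folded: bool = False

    def __post_init__(self):
        self.xibar = np.asarray(self.xibar, dtype=float)
        if np.any(self.xibar < 0):
            raise ValueError("alternative spectrum shape must be entry-wise >= 0")
        if self.xi0 is None:
            if self.folded:
                i = np.arange(1, self.n // 2 + 1)
                self.xi0 = self.n / (i * (self.n - i) * (1.0 + (i == self.n - i)))
            else:
                self.xi0 = 1.0 / np.arange(1, self.n)
        else:
            self.xi0 = np.asarray(self.xi0, dtype=float)
        if self.xibar.shape != self.xi0.shape:
            raise ValueError("xibar and xi0 dimensions disagree")
        if self.cov_null is None:
            self.cov_null = CovarianceModel.independent_sites(self.thetaL * self.xi0)
        if self.cov_alt is None:
            self.cov_alt = CovarianceModel.independent_sites(self.thetaL * self.xibar)

    @property
    def thetaL(self) -> float:
        return self.theta * self.L

    @property
    def mu(self) -> np.ndarray:
        return self.thetaL * self.xi0

    @property
    def mubar(self) -> np.ndarray:
        return self.thetaL * self.xibar

    def degenerate(self, rtol: float = 1e-12) -> bool:
        """True when xibar is proportional to xi0, i.e. no linear test can see it."""
        num = self.xibar @ self.xi0
        denom = self.xi0 @ self.xi0
        resid = self.xibar - (num / denom) * self.xi0
        return bool(np.linalg.norm(resid) <= rtol * max(np.linalg.norm(self.xibar), 1e-300))


@dataclass(frozen=True)
class OptimisationCriterion:
    """A criterion M(E, V) for choosing among tests of null mean 0, variance 1.

    kinds: ``mean_max`` (M = E), ``one_tail_power``, ``two_tail_power``
    (Gaussian power at significance alpha), ``variance_penalty``
    (M = E / (1 + V)^nu).
    """

    kind: str = "mean_max"
    alpha: float = 0.05
    nu: float = 1.0

    def __post_init__(self):
        if self.kind not in ("mean_max", "one_tail_power", "two_tail_power",
                             "variance_penalty"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not 0.0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")

    @property
    def tau_erf(self) -> float:
        """z-value in the erf convention, erfinv(1 - 2 alpha)."""
        return float(erfinv(1.0 - 2.0 * self.alpha))

    @property
    def tau_phi(self) -> float:
        """z-value in the Phi convention, Phi^-1(1 - alpha)."""
        return float(norm.ppf(1.0 - self.alpha))

    def value(self, E: float, V: float) -> float:
        if self.kind == "mean_max":
            return E
        if self.kind == "one_tail_power":
            return float(norm.cdf((E - self.tau_phi) / math.sqrt(V)))
        if self.kind == "two_tail_power":
            tp = float(norm.ppf(1.0 - self.alpha / 2.0))
            s = math.sqrt(V)
            return float(norm.cdf((E - tp) / s) + norm.cdf((-tp - E) / s))
        return E / (1.0 + V) ** self.nu


def scalar_product(x: np.ndarray, y: np.ndarray, cov: CovarianceModel) -> float:
    """<x, y> = x' C^-1 y (symmetric, positive semidefinite bilinear form)."""
    return float(np.asarray(x, dtype=float) @ cov.solve(y))


def _projection_pieces(scen: ScenarioSpectra):
    cov = scen.cov_null
    g00 = scalar_product(scen.xi0, scen.xi0, cov)
    g01 = scalar_product(scen.xi0, scen.xibar, cov)
    g11 = scalar_product(scen.xibar, scen.xibar, cov)
    denom_sq = g11 - g01 * g01 / g00
    return g00, g01, g11, denom_sq


def optimal_linear_test(spec: SpectrumCounts, scen: ScenarioSpectra) -> float:
    """Evaluate the optimal linear test statistic T_O on a spectrum."""
    if scen.degenerate():
        raise ValueError("degenerate alternative: xibar is proportional to xi0")
    g00, g01, _, denom_sq = _projection_pieces(scen)
    if denom_sq <= 0:
        raise ValueError("degenerate alternative: zero denominator in the optimal test")
    num = (scalar_product(spec.counts, scen.xibar, scen.cov_null)
           - scalar_product(spec.counts, scen.xi0, scen.cov_null) * g01 / g00)
    return num / math.sqrt(denom_sq)


def optimal_max_value(scen: ScenarioSpectra) -> float:
    """Expected value of the optimal test when the data follow the alternative.

    theta L sqrt(<xibar, xibar> - <xi0, xibar>^2 / <xi0, xi0>); this is the
    maximum expectation achievable by any normalised linear test under the
    alternative scenario (the minimum, with opposite sign, is attained by the
    sign-flipped weights).
    """
    _, _, _, denom_sq = _projection_pieces(scen)
    if denom_sq <= 0:
        raise ValueError("degenerate alternative: xibar is proportional to xi0")
    return scen.thetaL * math.sqrt(denom_sq)


def optimal_linear_weights(scen: ScenarioSpectra) -> np.ndarray:
    """Usual optimal weights Omega_i = xibar_i - (1/i) sum_j xibar_j / a_n.

    These are the weights implied by the geometric optimal test under the
    independent-sites covariance, and the lambda -> 0+ member of the tunable
    family.  They sum to zero exactly.
    """
    n = scen.n
    i = np.arange(1, n)
    return scen.xibar - (1.0 / i) * (scen.xibar.sum() / harmonic(n))


# ---------------------------------------------------------------------------
# Gaussian power

def _power_pieces(Omega: np.ndarray, scen: ScenarioSpectra):
    if scen.cov_alt is None:
        raise ValueError(
            "alternative covariance not available; use the simulate module's "
            "Monte-Carlo power instead of the Gaussian approximation"
        )
    Omega = np.asarray(Omega, dtype=float)
    w = np.arange(1, len(Omega) + 1) * Omega
    mean_alt = float(w @ scen.mubar)
    sd0 = math.sqrt(scen.cov_null.quadratic_form(w))
    sd1 = math.sqrt(scen.cov_alt.quadratic_form(w))
    if sd0 <= 0 or sd1 <= 0:
        raise ZeroDivisionError("degenerate weights: zero variance")
    return mean_alt, sd0, sd1


def gaussian_power(Omega: np.ndarray, scen: ScenarioSpectra,
                   criterion: OptimisationCriterion) -> float:
    """Exact one-tail (right) Gaussian power of the test at the criterion's alpha.

    Power = Phi((E_alt - Phi^-1(1-alpha) sd_null) / sd_alt) where E_alt is
    the alternative mean of the unnormalised numerator and sd_null, sd_alt
    its standard deviations under the two models.  Monotone decreasing in the
    z-value, equal to alpha when the alternative matches the null.
    """
    mean_alt, sd0, sd1 = _power_pieces(Omega, scen)
    return float(norm.cdf((mean_alt - criterion.tau_phi * sd0) / sd1))


def gaussian_power_erf_form(Omega: np.ndarray, scen: ScenarioSpectra,
                            criterion: OptimisationCriterion) -> float:
    """The erf-convention closed form, evaluated literally:

    (1/2) [1 + erf((E_alt - tau sqrt(Var_null)) / sqrt(Var_alt))] with
    tau = erfinv(1 - 2 alpha).  Reduces to alpha at the null point and to 1/2
    when the alternative mean sits exactly on the critical value, but carries
    no sqrt(2) factors, so between those anchors it is only an approximation
    to `gaussian_power`.
    """
    mean_alt, sd0, sd1 = _power_pieces(Omega, scen)
    return float(0.5 * (1.0 + erf((mean_alt - criterion.tau_erf * sd0) / sd1)))


# ---------------------------------------------------------------------------
# tunable family

def tunable_weights(lam: float, xibar: np.ndarray, n: int) -> np.ndarray:
    """Weights of the tunable optimal family at parameter lambda >= 0.

    Omega_i(lambda) = (1/i) [1 - a_n / ((1 + lambda i xibar_i) S(lambda))]
    with S(lambda) = sum_j 1 / (j (1 + lambda j xibar_j)); the weights sum to
    zero for every lambda by the telescoping of S.
    """
    xibar = np.asarray(xibar, dtype=float)
    i = np.arange(1, n)
    g = 1.0 + lam * i * xibar
    if np.any(g <= 0):
        raise ValueError("lambda outside the domain: 1 + lambda * i * xibar_i must stay positive")
    S = np.sum(1.0 / (i * g))
    return (1.0 / i) * (1.0 - harmonic(n) / (g * S))


def tunable_limit_direction(xibar: np.ndarray, n: int) -> np.ndarray:
    """Direction of dOmega/dlambda at lambda = 0+ (the usual optimal weights)."""
    xibar = np.asarray(xibar, dtype=float)
    i = np.arange(1, n)
    return xibar - (1.0 / i) * (xibar.sum() / harmonic(n))


@dataclass
class OptimiseResult:
    lam: float
    Omega: np.ndarray
    M: float
    E: float
    V: float
    local_maxima: list = field(default_factory=list)  # [(lambda, M), ...]


def _ev_of_weights(Omega: np.ndarray, scen: ScenarioSpectra):
    """Normalised-test mean E and variance V under the alternative."""
    w = np.arange(1, len(Omega) + 1) * np.asarray(Omega, dtype=float)
    v0 = scen.cov_null.quadratic_form(w)
    if v0 <= 0:
        return -np.inf, np.inf
    E = float(w @ scen.mubar) / math.sqrt(v0)
    V = scen.cov_alt.quadratic_form(w) / v0
    return E, V


def optimise(criterion: OptimisationCriterion, scen: ScenarioSpectra,
             lambda_grid: Optional[np.ndarray] = None) -> OptimiseResult:
    """Maximise M(E(lambda), V(lambda)) over the tunable family.

    Scans a logarithmic grid (default 200 points over [1e-4, 1e4], plus the
    analytic lambda -> 0+ limit direction), reports every local maximum found,
    and refines the best grid point by bounded scalar optimisation in
    log-lambda.  The weights of the family can change abruptly with the
    scenario and several local maxima may coexist, hence the exhaustive scan.
    """
    if scen.degenerate():
        raise ValueError("degenerate alternative: xibar is proportional to xi0")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 4, 200)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    def weights_at(lam: float) -> np.ndarray:
        if lam == 0.0:
            return tunable_limit_direction(scen.xibar, scen.n)
        return tunable_weights(lam, scen.xibar, scen.n)

    lams = np.concatenate([[0.0], lambda_grid])
    Ms = np.empty(len(lams))
    for k, lam in enumerate(lams):
        E, V = _ev_of_weights(weights_at(lam), scen)
        Ms[k] = criterion.value(E, V)

    local = [(float(lams[k]), float(Ms[k])) for k in range(len(lams))
             if (k == 0 or Ms[k] >= Ms[k - 1]) and (k == len(lams) - 1 or Ms[k] >= Ms[k + 1])]

    k_best = int(np.argmax(Ms))
    lam_best, M_best = float(lams[k_best]), float(Ms[k_best])
    if 0 < k_best < len(lams) - 1 and lams[k_best - 1] > 0:
        lo, hi = math.log(lams[k_best - 1]), math.log(lams[k_best + 1])
        res = minimize_scalar(
            lambda x: -criterion.value(*_ev_of_weights(weights_at(math.exp(x)), scen)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > M_best:
            lam_best, M_best = math.exp(res.x), -res.fun

    Omega = weights_at(lam_best)
    E, V = _ev_of_weights(Omega, scen)
    return OptimiseResult(lam=lam_best, Omega=Omega, M=M_best, E=E, V=V,
                          local_maxima=local)
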