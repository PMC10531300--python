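"""Polynomial (nonlinear) neutrality tests under the independent-sites moment model.

With unlinked sites and small theta the class counts xi_i are independent
Poisson variables with means mu_i = theta * L * xi0_i, so every moment of the
spectrum factorises over distinct classes into raw Poisson moments
(Touchard polynomials):

    E(xi_i^k) = sum_j S(k, j) mu_i^j      (S = Stirling numbers, 2nd kind),

which reproduces the second-moment formula mu_ij = mu_i delta_ij + mu_i mu_j
and extends it to all orders.  A polynomial test of degree d is a symmetric
form in the counts; grouping index tuples I into ordered multisets I~ with
multiplicity sigma_I, the unnormalised statistic is

    t = gamma + sum_{I~} What_{I~} m_{I~}(xi),   What_{I~} = sigma_I W_I,

where m_{I~} is the monomial prod xi_i over the multiset.

Two centring classes exist.  *Strongly centred* tests have zero null mean for
every plugged-in theta estimate: the weight vector is orthogonal to every
Taylor coefficient (in theta*L) of the null moment vector.  *Weakly centred*
tests are centred only at the true theta, form a larger class, and are
therefore more powerful when theta is well estimated but not robust to a
biased theta.  The optimal (maximum alternative-mean) members of both classes
are linear-algebra solutions in moment space; for both, the variance of the
unnormalised optimum under the null equals its expected value under the
alternative, which pins the normalisation and is used as a self-check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement
from typing import Optional, Sequence, Tuple

import numpy as np

from .linear_tests import PINV_FLOOR
from .spectrum import SpectrumCounts, null_mean_spectrum, watterson_theta

__all__ = [
    "MomentModel",
    "PolynomialTest",
    "poisson_moment",
    "poisson_moment_taylor",
    "multisets_up_to",
    "multiset_multiplicity",
    "fu_g_renormalised",
    "fu_g_diagonal",
    "quadratic_sc_optimal",
    "quadratic_wc_optimal",
    "linear_wc_optimal",
    "general_optimal",
    "evaluate_polynomial",
    "wc_linear_max_expectation",
    "sc_linear_max_expectation",
]

#: refuse moment matrices over more ordered multisets than this
MULTISET_CAP = 5000


# ---------------------------------------------------------------------------
# Poisson product moments

@lru_cache(maxsize=64)
def _stirling2_row(k: int) -> Tuple[float, ...]:
    """Stirling numbers of the second kind S(k, 0..k)."""
    row = [1.0]
    for kk in range(1, k + 1):
        new = [0.0] * (kk + 1)
        for j in range(1, kk + 1):
            new[j] = (row[j] if j < len(row) else 0.0) * j + row[j - 1]
        row = new
    return tuple(row)


def _multiplicities(I: Sequence[int]) -> dict:
    out: dict = {}
    for idx in I:
        out[idx] = out.get(idx, 0) + 1
    return out


def poisson_moment(mu: np.ndarray, I: Sequence[int]) -> float:
    """Raw moment E(prod_{i in I} xi_i) for independent Poisson counts.

    ``I`` is a multiset of 1-based class indices.  E.g. E(xi_i xi_j) =
    mu_i mu_j for i != j, E(xi_i^2) = mu_i + mu_i^2, E(xi_i^3) =
    mu_i + 3 mu_i^2 + mu_i^3.  The empty multiset has moment 1.
    """
    mu = np.asarray(mu, dtype=float)
    out = 1.0
    for idx, k in _multiplicities(I).items():
        S = _stirling2_row(k)
        m = mu[idx - 1]
        out *= sum(S[j] * m**j for j in range(1, k + 1))
    return out


def poisson_moment_taylor(shape: np.ndarray, I: Sequence[int], max_order: int) -> np.ndarray:
    """Taylor coefficients in theta*L of the null moment mu_I.

    With mu_i = theta L shape_i, each distinct index of multiplicity k
    contributes the polynomial sum_j S(k,j) shape_i^j (theta L)^j; the product
    over distinct indices is returned as coefficients of (theta L)^m for
    m = 0..max_order (the m = 0 entry is zero for non-empty multisets).
    """
    shape = np.asarray(shape, dtype=float)
    poly = np.zeros(max_order + 1)
    poly[0] = 1.0
    for idx, k in _multiplicities(I).items():
        S = _stirling2_row(k)
        factor = np.zeros(max_order + 1)
        for j in range(1, min(k, max_order) + 1):
            factor[j] = S[j] * shape[idx - 1] ** j
        poly = np.convolve(poly, factor)[: max_order + 1]
    return poly


def multisets_up_to(num_classes: int, d: int):
    """Ordered multisets I~ over classes 1..num_classes of sizes 1..d."""
    ms = []
    for size in range(1, d + 1):
        ms.extend(combinations_with_replacement(range(1, num_classes + 1), size))
    return ms


def multiset_multiplicity(I: Sequence[int]) -> int:
    """sigma_I: number of distinct orderings of the index sequence."""
    sigma = math.factorial(len(I))
    for k in _multiplicities(I).values():
        sigma //= math.factorial(k)
    return sigma


# ---------------------------------------------------------------------------
# moment model

@dataclass
class MomentModel:
    """First moments of null and alternative spectra plus the Poisson closure.

    ``xi0`` and ``xibar`` are per-unit-theta*L shapes; ``theta`` is the value
    plugged into the moments (the true value in known-theta mode, an estimate
    otherwise).  All higher moments follow from the independent-Poisson
    closure, consistently with the printed second moments and the rho = inf
    regime.
    """

    n: int
    xibar: np.ndarray
    theta: float
    L: int = 1
    xi0: Optional[np.ndarray] = None
    folded: bool = False
    theta_policy: str = "known"  # "known" | "watterson"

    def __post_init__(self):
        self.xibar = np.asarray(self.xibar, dtype=float)
        if self.xi0 is None:
            self.xi0 = null_mean_spectrum(self.n, 1.0, 1, folded=self.folded)
        else:
            self.xi0 = np.asarray(self.xi0, dtype=float)
        if self.xibar.shape != self.xi0.shape:
            raise ValueError("xibar and xi0 dimensions disagree")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")

    @property
    def thetaL(self) -> float:
        return self.theta * self.L

    @property
    def mu(self) -> np.ndarray:
        return self.thetaL * self.xi0

    @property
    def mubar(self) -> np.ndarray:
        return self.thetaL * self.xibar

    def at_theta(self, theta: float) -> "MomentModel":
        return MomentModel(n=self.n, xibar=self.xibar, theta=theta, L=self.L,
                           xi0=self.xi0, folded=self.folded,
                           theta_policy=self.theta_policy)

    def moment(self, I: Sequence[int], alt: bool = False) -> float:
        return poisson_moment(self.mubar if alt else self.mu, I)

    def moment_vector(self, ms, alt: bool = False) -> np.ndarray:
        mu = self.mubar if alt else self.mu
        return np.array([poisson_moment(mu, I) for I in ms])

    def covariance_matrix(self, ms, alt: bool = False) -> np.ndarray:
        """C_{I~ J~} = mu_{I~ + J~} - mu_{I~} mu_{J~} over ordered multisets."""
        mu = self.mubar if alt else self.mu
        m1 = np.array([poisson_moment(mu, I) for I in ms])
        k = len(ms)
        C = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                C[a, b] = C[b, a] = poisson_moment(mu, ms[a] + ms[b]) - m1[a] * m1[b]
        return C

    def taylor_matrix(self, ms, max_order: int) -> np.ndarray:
        """U[I~, m] = coefficient of (theta L)^{m+1} of the null moment mu_{I~}."""
        return np.array(
            [poisson_moment_taylor(self.xi0, I, max_order)[1:] for I in ms]
        )


# ---------------------------------------------------------------------------
# polynomial test container

def _solve_spd(C: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """C^{-1} Y via Cholesky, falling back to an eigenvalue-floored pseudo-inverse."""
    try:
        return np.linalg.solve(C, Y)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(C)
        floor = PINV_FLOOR * vals.max()
        inv = np.where(vals > floor, 1.0 / np.maximum(vals, floor), 0.0)
        return vecs @ (inv[:, None] * (vecs.T @ np.atleast_2d(Y.T).T))


@dataclass
class PolynomialTest:
    """A centred polynomial statistic in the SFS with its construction model.

    ``coeffs`` holds What_{I~} = sigma_I W_I per ordered multiset (so the
    statistic is gamma + sum What m_{I~}); ``weight(I)`` returns the symmetric
    tensor entry W_I of the theorem normalisation.
    """

    degree: int
    n: int
    multisets: list
    coeffs: np.ndarray
    gamma: float
    centring: str  # "strong" | "weak"
    model: MomentModel
    name: str = ""

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if len(self.coeffs) != len(self.multisets):
            raise ValueError("coefficient vector does not match multiset list")
        self._index = {I: k for k, I in enumerate(self.multisets)}

    def weight(self, I: Sequence[int]) -> float:
        """Symmetric tensor weight W_I (Omega or Gamma entry) for an index tuple."""
        key = tuple(sorted(I))
        return self.coeffs[self._index[key]] / multiset_multiplicity(key)

    def monomials(self, xi: np.ndarray) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        return np.array([np.prod(xi[np.array(I) - 1]) for I in self.multisets])

    def numerator(self, xi: np.ndarray) -> float:
        return self.gamma + float(self.coeffs @ self.monomials(xi))

    def null_variance(self, model: Optional[MomentModel] = None) -> float:
        model = model or self.model
        C = model.covariance_matrix(self.multisets)
        return float(self.coeffs @ C @ self.coeffs)

    def alt_expectation(self, model: Optional[MomentModel] = None) -> float:
        model = model or self.model
        return self.gamma + float(self.coeffs @ model.moment_vector(self.multisets, alt=True))

    def null_expectation(self, model: Optional[MomentModel] = None) -> float:
        model = model or self.model
        return self.gamma + float(self.coeffs @ model.moment_vector(self.multisets))

    def evaluate(self, spec: SpectrumCounts, theta_hat: Optional[float] = None) -> float:
        """Normalised statistic; variance from the Poisson model at theta_hat
        (the construction model's theta when not given)."""
        model = self.model if theta_hat is None else self.model.at_theta(theta_hat)
        var = self.null_variance(model)
        if var <= 0:
            raise ZeroDivisionError(f"degenerate polynomial test {self.name!r}")
        return self.numerator(spec.counts) / math.sqrt(var)

    def evaluate_many(self, X: np.ndarray) -> np.ndarray:
        """Vectorised normalised statistic over replicate rows of X."""
        var = self.null_variance()
        if var <= 0:
            raise ZeroDivisionError(f"degenerate polynomial test {self.name!r}")
        X = np.asarray(X, dtype=float)
        num = np.full(X.shape[0], self.gamma)
        for k, I in enumerate(self.multisets):
            if self.coeffs[k] == 0.0:
                continue
            cols = np.array(I) - 1
            num += self.coeffs[k] * np.prod(X[:, cols], axis=1)
        return num / math.sqrt(var)

    # -- serialisation ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "degree": self.degree, "n": self.n,
            "multisets": [list(I) for I in self.multisets],
            "coeffs": self.coeffs.tolist(), "gamma": self.gamma,
            "centring": self.centring, "name": self.name,
            "model": {"n": self.model.n, "xibar": self.model.xibar.tolist(),
                      "theta": self.model.theta, "L": self.model.L,
                      "xi0": self.model.xi0.tolist(), "folded": self.model.folded,
                      "theta_policy": self.model.theta_policy},
        })

    @classmethod
    def from_json(cls, s: str) -> "PolynomialTest":
        d = json.loads(s)
        m = d["model"]
        model = MomentModel(n=m["n"], xibar=np.array(m["xibar"]), theta=m["theta"],
                            L=m["L"], xi0=np.array(m["xi0"]), folded=m["folded"],
                            theta_policy=m["theta_policy"])
        return cls(degree=d["degree"], n=d["n"],
                   multisets=[tuple(I) for I in d["multisets"]],
                   coeffs=np.array(d["coeffs"]), gamma=d["gamma"],
                   centring=d["centring"], model=model, name=d["name"])


def evaluate_polynomial(test: PolynomialTest, spec: SpectrumCounts,
                        theta_hat: Optional[float] = None) -> float:
    """Normalised polynomial statistic; Watterson plug-in when the test's
    model asks for it and no value is supplied."""
    if theta_hat is None and test.model.theta_policy == "watterson":
        theta_hat = watterson_theta(spec)
    return test.evaluate(spec, theta_hat=theta_hat)


# ---------------------------------------------------------------------------
# Fu's G

def fu_g_diagonal(spec: SpectrumCounts, theta_hat: Optional[float] = None) -> float:
    """Fu's G_xi: mean over classes of (xi_i - mu_i)^2 / Var(xi_i) with the
    diagonal (independent-sites) variance Var(xi_i) = mu_i."""
    if theta_hat is None:
        theta_hat = watterson_theta(spec)
    mu = null_mean_spectrum(spec.n, theta_hat, spec.L, folded=spec.folded)
    return float(np.mean((spec.counts - mu) ** 2 / mu))


def fu_g_renormalised(spec: SpectrumCounts, theta_hat: Optional[float] = None) -> float:
    """Renormalised Fu's G: (Q - (n-1)) / sqrt(Var Q) with
    Q = sum_i (xi_i - mu_i)^2 / mu_i.

    Under the independent-sites model the covariance is diagonal, E(Q) equals
    the number of classes and Var(Q) = sum_i 1/mu_i + 2 * (#classes); both are
    evaluated at the plugged-in theta (Watterson by default).  The monotone
    map from Q preserves the power of the unnormalised form at any threshold.
    """
    if theta_hat is None:
        theta_hat = watterson_theta(spec)
    mu = null_mean_spectrum(spec.n, theta_hat, spec.L, folded=spec.folded)
    k = len(mu)
    Q = float(np.sum((spec.counts - mu) ** 2 / mu))
    var = float(np.sum(1.0 / mu)) + 2.0 * k
    return (Q - k) / math.sqrt(var)


def fu_g_many(X: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Vectorised renormalised Fu's G at fixed (known-theta) null mean mu."""
    X = np.asarray(X, dtype=float)
    k = len(mu)
    Q = np.sum((X - mu) ** 2 / mu, axis=1)
    var = float(np.sum(1.0 / mu)) + 2.0 * k
    return (Q - k) / math.sqrt(var)


# ---------------------------------------------------------------------------
# optimal polynomial tests

def general_optimal(model: MomentModel, degree: int, centring: str = "strong",
                    cap: int = MULTISET_CAP) -> PolynomialTest:
    """Optimal polynomial test of a given degree and centring class.

    Strong: What = C^-1 mubar projected (in the C^-1 metric) onto the
    orthogonal complement of the null-moment Taylor directions, so that the
    null mean vanishes order by order in theta*L; gamma = 0.
    Weak: What = C^-1 (mubar - mu), gamma = -mu' C^-1 (mubar - mu).

    ``C`` is the null covariance of the monomials over ordered multisets.
    For degree 1 the strong solution reproduces the geometric optimal linear
    test; for degree 2 both closed-form quadratic constructors.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if centring not in ("strong", "weak"):
        raise ValueError("centring must be 'strong' or 'weak'")
    ms = multisets_up_to(len(model.xi0), degree)
    if len(ms) > cap:
        raise ValueError(
            f"{len(ms)} ordered multisets exceed the cap {cap}; "
            "reduce the degree or raise the cap"
        )
    C = model.covariance_matrix(ms)
    mubar = model.moment_vector(ms, alt=True)
    if centring == "weak":
        mu = model.moment_vector(ms)
        coeffs = _solve_spd(C, mubar - mu)
        gamma = -float(mu @ coeffs)
    else:
        U = model.taylor_matrix(ms, degree)
        Ci_mubar = _solve_spd(C, mubar)
        Ci_U = _solve_spd(C, U)
        A = U.T @ Ci_U
        beta = np.linalg.solve(A, U.T @ Ci_mubar)
        coeffs = Ci_mubar - Ci_U @ beta
        gamma = 0.0
    if np.max(np.abs(coeffs)) <= 0.0:
        raise ZeroDivisionError("degenerate optimal test: alternative equals the null")
    return PolynomialTest(degree=degree, n=model.n, multisets=ms, coeffs=coeffs,
                          gamma=gamma, centring=centring, model=model,
                          name=f"optimal_{centring}_d{degree}")


def _quadratic_container(model: MomentModel, O1: np.ndarray, O2: np.ndarray,
                         gamma: float, centring: str, name: str) -> PolynomialTest:
    """Pack per-class linear weights O1 and the symmetric matrix O2 (full
    double-sum convention) into ordered-multiset coefficients."""
    n = model.n
    ms = multisets_up_to(len(model.xi0), 2)
    coeffs = np.empty(len(ms))
    k = len(model.xi0)
    for a, I in enumerate(ms):
        if len(I) == 1:
            coeffs[a] = O1[I[0] - 1]
        else:
            i, j = I
            coeffs[a] = O2[i - 1, j - 1] if i == j else 2.0 * O2[i - 1, j - 1]
    if np.max(np.abs(coeffs)) == 0.0 and gamma == 0.0:
        raise ZeroDivisionError(f"degenerate test {name!r}: alternative equals the null")
    return PolynomialTest(degree=2, n=n, multisets=ms, coeffs=coeffs, gamma=gamma,
                          centring=centring, model=model, name=name)


def quadratic_sc_optimal(model: MomentModel) -> PolynomialTest:
    """Closed-form optimal strongly centred quadratic test (independent sites).

    With r_i = mubar_i / mu_i, R = sum(mubar) / sum(mu):

        W^(1)_i  = (sum(mu) + 2 - sum(mubar)) (r_i - R) - (r_i^2 - R^2) / 2
        W^(2)_ii = -(r_i - R) + (r_i^2 - R^2) / 2
        W^(2)_ij = ((r_i r_j - R^2) - (r_i - R) - (r_j - R)) / 2

    The statistic is the full double sum sum_i W^(1)_i xi_i +
    sum_ij W^(2)_ij xi_i xi_j; its null variance equals its alternative
    expectation, and its null mean vanishes for any plugged-in theta.
    """
    mu, mubar = model.mu, model.mubar
    if np.any(mu <= 0) or np.any(mubar <= 0):
        raise ValueError("closed-form quadratic weights require positive mu and mubar")
    r = mubar / mu
    R = mubar.sum() / mu.sum()
    Smu, Smubar = mu.sum(), mubar.sum()
    O1 = (Smu + 2.0 - Smubar) * (r - R) - 0.5 * (r**2 - R**2)
    O2 = 0.5 * ((np.outer(r, r) - R**2) - (r[:, None] - R) - (r[None, :] - R))
    np.fill_diagonal(O2, -(r - R) + 0.5 * (r**2 - R**2))
    return _quadratic_container(model, O1, O2, 0.0, "strong", "quadratic_sc_optimal")


def quadratic_wc_optimal(model: MomentModel) -> PolynomialTest:
    """Closed-form optimal weakly centred quadratic test (independent sites).

    With r_i = mubar_i / mu_i:

        G^(1)_i  = (sum(mu) + 2 - sum(mubar)) (r_i - 1) - (r_i^2 - 1) / 2
        G^(2)_ii = (r_i - 1)^2 / 2
        G^(2)_ij = (r_i - 1)(r_j - 1) / 2
        gamma    = (sum(mu) - sum(mubar)) (sum(mu) + 2 - sum(mubar)) / 2

    Centred if and only if the plugged-in theta equals the true theta.
    """
    mu, mubar = model.mu, model.mubar
    if np.any(mu <= 0) or np.any(mubar <= 0):
        raise ValueError("closed-form quadratic weights require positive mu and mubar")
    r = mubar / mu
    Smu, Smubar = mu.sum(), mubar.sum()
    G1 = (Smu + 2.0 - Smubar) * (r - 1.0) - 0.5 * (r**2 - 1.0)
    G2 = 0.5 * np.outer(r - 1.0, r - 1.0)
    gamma = 0.5 * (Smu - Smubar) * (Smu + 2.0 - Smubar)
    return _quadratic_container(model, G1, G2, gamma, "weak", "quadratic_wc_optimal")


def linear_wc_optimal(model: MomentModel,
                      cov: Optional[np.ndarray] = None) -> PolynomialTest:
    """Optimal weakly centred first-order polynomial test.

    Gamma^(1) = c^-1 (mubar - mu), gamma = -mu' c^-1 (mubar - mu), with the
    null covariance c (diagonal Poisson by default).  Its alternative
    expectation is the full quadratic form (mubar-mu)' c^-1 (mubar-mu), which
    always dominates the strongly centred linear maximum.
    """
    mu, mubar = model.mu, model.mubar
    if cov is None:
        G1 = (mubar - mu) / mu
    else:
        G1 = _solve_spd(np.asarray(cov, dtype=float), mubar - mu)
    gamma = -float(mu @ G1)
    ms = multisets_up_to(len(model.xi0), 1)
    return PolynomialTest(degree=1, n=model.n, multisets=ms, coeffs=G1, gamma=gamma,
                          centring="weak", model=model, name="linear_wc_optimal")


def wc_linear_max_expectation(model: MomentModel) -> float:
    """(mubar - mu)' c^-1 (mubar - mu): alternative mean of the unnormalised
    weakly centred linear optimum (the square of the normalised mean)."""
    d = model.mubar - model.mu
    return float(np.sum(d * d / model.mu))


def sc_linear_max_expectation(model: MomentModel) -> float:
    """Alternative mean of the unnormalised strongly centred linear optimum:
    the weakly centred maximum minus (mu' c^-1 (mubar-mu))^2 / (mu' c^-1 mu)."""
    mu, mubar = model.mu, model.mubar
    d = mubar - mu
    return wc_linear_max_expectation(model) - float(np.sum(d)) ** 2 / float(mu.sum())
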