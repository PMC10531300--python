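"""Normalised linear tests T_Omega, covariance models, and undetectable deviations.

A linear test contrasts two unbiased theta estimators:

    T_Omega = sum_i i Omega_i xi_i / sqrt(Var(sum_j j Omega_j xi_j)),

with sum_i Omega_i = 0, so that E(T_Omega) = 0 and Var(T_Omega) = 1 under the
null model when the covariance model is exact.  The default covariance model
is the independent-sites (free recombination, small theta) one, under which
the class counts are independent Poisson variables with mean mu_i and the
numerator variance is sum_i (i Omega_i)^2 mu_i.

No single linear test is generic: for every weight vector there exists a
spectrum, maximally different from the neutral one (an entire frequency class
can be empty), on which the test's expectation vanishes.
`undetectable_deviation` constructs such a spectrum explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import null_space

from .spectrum import (SpectrumCounts, harmonic, null_mean_spectrum,
                       watterson_theta)

__all__ = [
    "CovarianceModel",
    "LinearTest",
    "undetectable_deviation",
    "joint_constraint_null_space",
]

#: eigenvalue floor (relative to the largest eigenvalue) for pseudo-inverses
#: of empirical covariance matrices, which can be rank-deficient.
PINV_FLOOR = 1e-12


@dataclass
class CovarianceModel:
    """Covariance of the SFS class counts under a model.

    ``independent_sites``: diagonal Poisson covariance c_ii = mu_i (the
    second-moment model mu_ij = mu_i delta_ij + mu_i mu_j, i.e. Cov = diag(mu)).
    ``empirical``: a full matrix estimated from simulated replicates.
    """

    kind: str
    mean: np.ndarray
    matrix: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if self.kind == "independent_sites":
            if self.matrix is None:
                self.matrix = np.diag(self.mean)
        elif self.kind == "empirical":
            if self.matrix is None:
                raise ValueError("empirical covariance model requires a matrix")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
                raise ValueError("covariance matrix must be symmetric")
        else:
            raise ValueError(f"unknown covariance kind {self.kind!r}")

    @classmethod
    def independent_sites(cls, mean: np.ndarray) -> "CovarianceModel":
        return cls(kind="independent_sites", mean=mean)

    @classmethod
    def from_replicates(cls, X: np.ndarray) -> "CovarianceModel":
        X = np.asarray(X, dtype=float)
        return cls(kind="empirical", mean=X.mean(axis=0), matrix=np.cov(X, rowvar=False))

    @property
    def diagonal(self) -> bool:
        return self.kind == "independent_sites"

    def quadratic_form(self, w: np.ndarray) -> float:
        """w' C w, the variance of sum_i w_i xi_i."""
        w = np.asarray(w, dtype=float)
        if self.diagonal:
            return float(np.sum(w * w * self.mean))
        return float(w @ self.matrix @ w)

    def solve(self, y: np.ndarray) -> np.ndarray:
        """C^{-1} y, with an eigenvalue-floored pseudo-inverse for empirical matrices."""
        y = np.asarray(y, dtype=float)
        if self.diagonal:
            if np.any(self.mean <= 0):
                raise np.linalg.LinAlgError("singular diagonal covariance (zero mean class)")
            return y / self.mean
        vals, vecs = np.linalg.eigh(self.matrix)
        floor = PINV_FLOOR * vals.max()
        inv = np.where(vals > floor, 1.0 / np.maximum(vals, floor), 0.0)
        return vecs @ (inv * (vecs.T @ y))


@dataclass
class LinearTest:
    """A centred weight vector with a name; evaluates the normalised statistic."""

    Omega: np.ndarray
    name: str = ""
    folded: bool = False

    def __post_init__(self):
        self.Omega = np.asarray(self.Omega, dtype=float)
        s = self.Omega.sum()
        scale = np.abs(self.Omega).sum() or 1.0
        if abs(s) > 1e-9 * scale:
            raise ValueError(f"weights must sum to 0 (centredness), got {s!r}")

    @property
    def w(self) -> np.ndarray:
        """Coefficients of the numerator on the class counts: w_i = i * Omega_i."""
        return np.arange(1, len(self.Omega) + 1) * self.Omega

    def numerator(self, spec: SpectrumCounts) -> float:
        if spec.counts.shape != self.Omega.shape:
            raise ValueError("spectrum dimension does not match test weights")
        return float(self.w @ spec.counts)

    def evaluate(self, spec: SpectrumCounts, cov: Optional[CovarianceModel] = None,
                 theta: Optional[float] = None) -> float:
        """Normalised statistic of the test on a spectrum.

        The variance in the denominator comes from ``cov`` if given; otherwise
        from the independent-sites model at theta (Watterson plug-in from the
        spectrum itself when ``theta`` is None).
        """
        if cov is None:
            if theta is None:
                theta = watterson_theta(spec)
            mean = null_mean_spectrum(spec.n, theta, spec.L, folded=spec.folded)
            cov = CovarianceModel.independent_sites(mean)
        var = cov.quadratic_form(self.w)
        if var <= 0:
            raise ZeroDivisionError(f"degenerate test {self.name!r}: zero numerator variance")
        return self.numerator(spec) / np.sqrt(var)

    def evaluate_many(self, X: np.ndarray, var: float) -> np.ndarray:
        """Vectorised statistic over replicate rows of X with a fixed variance."""
        if var <= 0:
            raise ZeroDivisionError(f"degenerate test {self.name!r}: zero numerator variance")
        return (np.asarray(X, dtype=float) @ self.w) / np.sqrt(var)

    def record(self, spec: SpectrumCounts, cov: Optional[CovarianceModel] = None,
               theta: Optional[float] = None) -> dict:
        if cov is None:
            if theta is None:
                theta = watterson_theta(spec)
            mean = null_mean_spectrum(spec.n, theta, spec.L, folded=spec.folded)
            cov = CovarianceModel.independent_sites(mean)
        num = self.numerator(spec)
        var = cov.quadratic_form(self.w)
        return {"test": self.name, "numerator": num, "variance": var,
                "statistic": num / np.sqrt(var)}


# ---------------------------------------------------------------------------
# Theorem-1 machinery

def undetectable_deviation(Omega: np.ndarray, n: int):
    """Construct a spectrum shape invisible to the test defined by ``Omega``.

    Returns ``(Delta, alpha, composite)`` where ``composite_i =
    alpha/(i a_n) + (1 - alpha) Delta_i`` is entry-wise >= 0 with minimum
    exactly 0 (at least one frequency class is completely empty), yet the test
    numerator on it vanishes because sum_i i Omega_i Delta_i = 0.

    Construction: ``Delta`` is taken from the null space of the single
    constraint vector (i Omega_i), choosing the basis direction with maximal
    angle to the neutral shape 1/i (which always lies in that null space since
    sum Omega_i = 0), sign-flipped to have a negative entry.  The mixture
    minimum is a concave piecewise-linear function of alpha, positive at
    alpha=1 and negative at alpha=0, so its unique zero is
    ``alpha* = max_i Delta_i / (Delta_i - 1/(i a_n))`` over classes with
    Delta_i < 0, which is used in closed form.
    """
    Omega = np.asarray(Omega, dtype=float)
    if n < 4:
        raise ValueError("n >= 4 is required (the constraint null space must exceed the 1/i line)")
    if Omega.shape != (n - 1,):
        raise ValueError("Omega must have length n-1")
    scale = np.abs(Omega).sum()
    if scale == 0:
        raise ValueError("Omega must not be identically zero")
    if abs(Omega.sum()) > 1e-9 * scale:
        raise ValueError("Omega must sum to zero")

    i = np.arange(1, n)
    a_n = harmonic(n)
    neutral = 1.0 / (i * a_n)

    constraint = (i * Omega)[None, :]
    basis = null_space(constraint)  # (n-1) x (n-2), orthonormal columns
    assert basis.shape[1] >= 2, "constraint null space unexpectedly small"

    u = neutral / np.linalg.norm(neutral)
    cosines = np.abs(u @ basis)
    k = int(np.argmin(cosines))  # maximal angle; argmin takes the lowest index on ties
    Delta = basis[:, k].copy()
    if Delta.min() >= 0:
        Delta = -Delta
    # orthogonal to u (up to rounding) => mixed signs, so Delta_min < 0 holds

    neg = Delta < 0
    alpha = float(np.max(Delta[neg] / (Delta[neg] - neutral[neg])))
    alpha = min(max(alpha, 0.0), 1.0)

    composite = alpha * neutral + (1.0 - alpha) * Delta
    j = int(np.argmin(composite))
    composite[j] = 0.0
    composite = np.maximum(composite, 0.0)
    return Delta, alpha, composite


def joint_constraint_null_space(Omegas) -> np.ndarray:
    """Null space of the stacked constraints sum_i i Omega_i^k Delta_i = 0.

    With n-2 linearly independent centred weight vectors the null space is
    one-dimensional and spanned by the neutral shape 1/i: no deviation other
    than a rescaling of the neutral spectrum is invisible to all tests
    jointly.
    """
    Omegas = np.atleast_2d(np.asarray(Omegas, dtype=float))
    i = np.arange(1, Omegas.shape[1] + 1)
    return null_space(Omegas * i)
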