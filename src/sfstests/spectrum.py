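"""Site frequency spectrum containers, neutral expectations and linear theta estimators.

The unfolded spectrum xi_i counts segregating sites whose derived allele is
carried by i of the n sampled haploid sequences (1 <= i <= n-1).  Without an
outgroup only the folded spectrum eta_i (minor-allele count, 1 <= i <= n//2)
is observable.  Under the standard Wright-Fisher neutral model,

    E(xi_i)  = theta * L / i,
    E(eta_i) = theta * L * n / (i * (n - i) * (1 + delta_{i, n-i})),

with theta = 2 * p * mu * Ne the scaled mutation rate *per base* and L the
sequence length in bases.  All public indexing is 1-based in the allele-count
class i; internally counts are stored as a 0-based numpy array.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SpectrumCounts",
    "NeutralParams",
    "harmonic",
    "null_mean_spectrum",
    "fold",
    "theta_estimator",
    "class_sizes",
]

#: relative tolerance for weight-normalisation checks (short, well-conditioned sums)
NORMALISATION_RTOL = 1e-9


def class_sizes(n: int, folded: bool) -> int:
    """Number of allele-frequency classes: n-1 unfolded, floor(n/2) folded."""
    return n // 2 if folded else n - 1


def harmonic(n: int) -> float:
    """(n-1)-th harmonic number a_n = sum_{j=1}^{n-1} 1/j.

    This is the Watterson normalisation constant; a_n ~ log(n) + gamma + O(1/n).
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass(frozen=True)
class SpectrumCounts:
    """An observed or expected site frequency spectrum.

    Parameters
    ----------
    n : haploid sample size (>= 2).
    counts : class counts, index i = 1..n-1 (unfolded) or 1..n//2 (folded).
        Stored as floats so that expected spectra and observed spectra share
        one type; use ``validate_integral`` for strict observed data.
    folded : whether ``counts`` is a folded (minor-allele) spectrum.
    L : sequence length in bases.
    """

    n: int
    counts: np.ndarray
    folded: bool = False
    L: int = 1

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        if self.L < 1:
            raise ValueError(f"sequence length L must be >= 1, got {self.L}")
        counts = np.asarray(self.counts, dtype=float)
        expected = class_sizes(self.n, self.folded)
        if counts.shape != (expected,):
            raise ValueError(
                f"counts must have length {expected} for n={self.n} "
                f"({'folded' if self.folded else 'unfolded'}), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("spectrum counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def S(self) -> float:
        """Total number of segregating sites."""
        return float(self.counts.sum())

    @property
    def classes(self) -> np.ndarray:
        """1-based allele-count classes i."""
        return np.arange(1, len(self.counts) + 1)

    def validate_integral(self, atol: float = 1e-8) -> None:
        if not np.allclose(self.counts, np.round(self.counts), atol=atol):
            raise ValueError("spectrum counts are not integral")

    def with_counts(self, counts: np.ndarray) -> "SpectrumCounts":
        return replace(self, counts=np.asarray(counts, dtype=float))


@dataclass(frozen=True)
class NeutralParams:
    """Standard-neutral-model parameters.

    ``theta`` is the scaled mutation rate per base (2 p mu Ne).  ``N`` enters
    only as the 1/N frequency cutoff used to normalise divergent weight
    functions such as the Watterson 1/f weight.
    """

    theta: float
    L: int = 1
    N: int = 10**6

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.N < 2:
            raise ValueError("population size N must be >= 2")

    @property
    def thetaL(self) -> float:
        return self.theta * self.L


def null_mean_spectrum(n: int, theta: float, L: int = 1, folded: bool = False) -> np.ndarray:
    """Expected class counts under the standard neutral model.

    Unfolded entry i is theta*L/i; folded entry i is
    theta*L*n/(i*(n-i)*(1+delta_{i,n-i})) so that the class i = n/2 (n even),
    which folds onto itself, is not double counted.
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if L < 1:
        raise ValueError("L must be >= 1")
    if not folded:
        i = np.arange(1, n)
        return theta * L / i
    i = np.arange(1, n // 2 + 1)
    delta = (i == n - i).astype(float)
    return theta * L * n / (i * (n - i) * (1.0 + delta))


def null_spectrum(n: int, theta: float, L: int = 1, folded: bool = False) -> SpectrumCounts:
    """`null_mean_spectrum` wrapped in a :class:`SpectrumCounts`."""
    return SpectrumCounts(n=n, counts=null_mean_spectrum(n, theta, L, folded), folded=folded, L=L)


def fold(spec: SpectrumCounts) -> SpectrumCounts:
    """Fold an unfolded spectrum: eta_i = xi_i + xi_{n-i} (i < n/2), eta_{n/2} = xi_{n/2}.

    The total number of segregating sites is preserved.
    """
    if spec.folded:
        raise ValueError("spectrum is already folded")
    n = spec.n
    xi = spec.counts
    m = n // 2
    eta = np.empty(m)
    for i in range(1, m + 1):
        if i == n - i:
            eta[i - 1] = xi[i - 1]
        else:
            eta[i - 1] = xi[i - 1] + xi[n - i - 1]
    return SpectrumCounts(n=n, counts=eta, folded=True, L=spec.L)


def theta_estimator(spec: SpectrumCounts, omega: np.ndarray) -> float:
    """Linear unbiased estimator of theta per base from normalised weights.

    For the unfolded spectrum, theta_hat = (1/L) sum_i i * omega_i * xi_i with
    sum_i omega_i = 1; applied to the expected neutral spectrum this returns
    theta exactly.  For a folded spectrum the class factor i is replaced by
    i(n-i)(1+delta_{i,n-i})/n, which restores unbiasedness against E(eta_i).
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != spec.counts.shape:
        raise ValueError("weight vector does not match spectrum dimension")
    total = omega.sum()
    if not np.isclose(total, 1.0, rtol=NORMALISATION_RTOL, atol=NORMALISATION_RTOL):
        raise ValueError(f"weights must sum to 1, got {total!r}")
    i = spec.classes
    if spec.folded:
        n = spec.n
        factor = i * (n - i) * (1.0 + (i == n - i)) / n
    else:
        factor = i
    return float(np.sum(factor * omega * spec.counts) / spec.L)


def watterson_theta(spec: SpectrumCounts) -> float:
    """Watterson's estimator S / (a_n L)."""
    return spec.S / (harmonic(spec.n) * spec.L)
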