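"""Continuum weight functions, sample-size-consistent scalings and the classic-test catalogue.

A linear neutrality test is defined, independently of sample size, by a weight
function Omega(f) on population allele frequencies f in (0,1) (or a pair
omega(f), omega'(f) of estimator weights) plus optional point masses on
derived/ancestral singletons.  Discrete weights for a sample of size n are
realised through one of three scalings:

* ``centering``  -- Omega_i = Omega(i/n) + singletons - mean correction
  (exact centredness by subtraction);
* ``ratio``      -- Omega_i = omega_i - omega'_i with each vector renormalised
  to sum to 1 (the form implicitly used by most published tests; the only
  valid form for weight functions diverging like f^-k, k >= 1, such as the
  Watterson 1/f weight);
* ``binomial``   -- omega_i proportional to the binomial-kernel integral
  int C(n,i) f^i (1-f)^{n-i} omega(f) df (the sampling-based scaling followed
  by the admixture test and by optimal tests).

Every realised Omega vector sums to zero, which is the centredness condition
of a neutrality test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.stats import binom

from .spectrum import harmonic

__all__ = [
    "WeightFunction",
    "WeightScheme",
    "realise_centering",
    "realise_ratio",
    "realise_binomial",
    "watterson_weights",
    "classic_test_weights",
    "error_corrected_scheme",
    "admixture_average_weight",
    "bottleneck_beta",
    "CLASSIC_TESTS",
]


# ---------------------------------------------------------------------------
# weight functions

def _uniform(params):
    c = params.get("value", 1.0)
    return lambda f: np.full_like(np.asarray(f, dtype=float), c)


def _pairwise(params):
    # Tajima estimator weight 2(1-f)
    return lambda f: 2.0 * (1.0 - np.asarray(f, dtype=float))


def _derived_linear(params):
    return lambda f: 2.0 * np.asarray(f, dtype=float)


def _watterson(params):
    # 1/f, divergent at f=0: only meaningful under ratio scaling, where the
    # 1/log(N) normalisation cancels.
    return lambda f: 1.0 / np.asarray(f, dtype=float)


def _power(params):
    r = params["r"]
    return lambda f: (1.0 - r) * np.asarray(f, dtype=float) ** (-r)


def _exponential(params):
    beta = params["beta"]
    return lambda f: beta * np.exp(-beta * np.asarray(f, dtype=float)) / (1.0 - np.exp(-beta))


def _zero(params):
    return lambda f: np.zeros_like(np.asarray(f, dtype=float))


_KINDS = {
    "uniform": _uniform,
    "pairwise": _pairwise,
    "derived_linear": _derived_linear,
    "watterson": _watterson,
    "power": _power,
    "exponential": _exponential,
    "zero": _zero,
}

_DIVERGENT_KINDS = {"watterson"}


@dataclass(frozen=True)
class WeightFunction:
    """A weight function on (0,1): a tagged smooth part plus Dirac point masses.

    Dirac components are kept symbolic as (location, mass) pairs and are
    integrated analytically against the binomial kernel, so that tests such as
    the admixture test are exact.
    """

    kind: str = "zero"
    params: dict = field(default_factory=dict)
    diracs: tuple = ()  # ((location, mass), ...)
    fn: Optional[Callable] = None  # for kind == "custom"

    def __post_init__(self):
        if self.kind == "custom":
            if self.fn is None:
                raise ValueError("custom weight function requires fn")
        elif self.kind not in _KINDS:
            raise ValueError(f"unknown weight function kind {self.kind!r}")
        object.__setattr__(self, "diracs", tuple((float(a), float(m)) for a, m in self.diracs))

    @property
    def divergent(self) -> bool:
        if self.kind in _DIVERGENT_KINDS:
            return True
        if self.kind == "power" and self.params.get("r", 0.0) >= 1.0:
            return True
        return bool(self.params.get("divergent", False))

    def smooth(self, f):
        if self.kind == "custom":
            return np.asarray(self.fn(np.asarray(f, dtype=float)), dtype=float)
        return _KINDS[self.kind](self.params)(f)

    def __call__(self, f):
        return self.smooth(f)

    def to_dict(self) -> dict:
        if self.kind == "custom":
            raise ValueError("custom weight functions are not serialisable")
        return {"kind": self.kind, "params": dict(self.params), "diracs": list(self.diracs)}

    @classmethod
    def from_dict(cls, d: dict) -> "WeightFunction":
        return cls(kind=d["kind"], params=dict(d.get("params", {})),
                   diracs=tuple(tuple(x) for x in d.get("diracs", ())))


@dataclass(frozen=True)
class WeightScheme:
    """A complete sample-size-consistent definition of a linear test.

    For ``form == "centering"`` only ``omega`` (interpreted as Omega(f)) and
    the Omega-form singleton masses ``ds``/``as_`` are used.  For ``ratio``
    and ``binomial`` forms both ``omega`` and ``omega_prime`` with their own
    singleton masses define the two theta estimators being contrasted.
    """

    form: str  # "centering" | "ratio" | "binomial"
    omega: WeightFunction
    omega_prime: Optional[WeightFunction] = None
    ds: float = 0.0       # derived-singleton mass (Omega_ds or omega_ds)
    as_: float = 0.0      # ancestral-singleton mass
    ds_prime: float = 0.0
    as_prime: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.form not in ("centering", "ratio", "binomial"):
            raise ValueError(f"unknown scaling form {self.form!r}")
        if self.form in ("ratio", "binomial") and self.omega_prime is None:
            raise ValueError(f"{self.form} scaling requires both omega and omega_prime")

    @property
    def divergent(self) -> bool:
        div = self.omega.divergent
        if self.omega_prime is not None:
            div = div or self.omega_prime.divergent
        return div

    def realise(self, n: int) -> np.ndarray:
        if self.form == "centering":
            return realise_centering(self, n)
        if self.form == "ratio":
            return realise_ratio(self, n)
        omega, omega_prime = realise_binomial(self, n)
        return omega - omega_prime

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "form": self.form,
            "omega": self.omega.to_dict(),
            "omega_prime": None if self.omega_prime is None else self.omega_prime.to_dict(),
            "ds": self.ds, "as": self.as_,
            "ds_prime": self.ds_prime, "as_prime": self.as_prime,
            "name": self.name,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "WeightScheme":
        d = json.loads(s)
        return cls(
            form=d["form"],
            omega=WeightFunction.from_dict(d["omega"]),
            omega_prime=None if d.get("omega_prime") is None
            else WeightFunction.from_dict(d["omega_prime"]),
            ds=d.get("ds", 0.0), as_=d.get("as", 0.0),
            ds_prime=d.get("ds_prime", 0.0), as_prime=d.get("as_prime", 0.0),
            name=d.get("name", ""),
        )


# ---------------------------------------------------------------------------
# scaling realisations

def _grid(n: int) -> np.ndarray:
    return np.arange(1, n) / n


def realise_centering(scheme: WeightScheme, n: int) -> np.ndarray:
    """Centering scaling: Omega_i = Omega(i/n) + singletons - mean correction.

    The subtracted mean enforces sum_i Omega_i = 0 exactly.  Refused for
    divergent weight functions, whose correction term is not O(1/n) and
    carries a spurious dependence on the population-size cutoff; those
    schemes must use the ratio scaling.
    """
    if scheme.divergent:
        raise ValueError(
            "centering scaling is invalid for divergent weight functions "
            "(f^-k with k >= 1 near 0 or 1); use the ratio scaling"
        )
    w = scheme.omega.smooth(_grid(n)).astype(float)
    w[0] += scheme.ds
    w[-1] += scheme.as_
    w -= w.sum() / (n - 1)
    return w


def realise_ratio(scheme: WeightScheme, n: int) -> np.ndarray:
    """Ratio scaling: difference of the two independently renormalised omega vectors."""
    f = _grid(n)

    def one_side(fn: WeightFunction, ds: float, as_: float) -> np.ndarray:
        v = fn.smooth(f).astype(float)
        v[0] += ds
        v[-1] += as_
        denom = v.sum()
        if abs(denom) < 1e-300:
            raise ZeroDivisionError("degenerate weight scheme: zero normalisation sum")
        return v / denom

    omega = one_side(scheme.omega, scheme.ds, scheme.as_)
    omega_p = one_side(scheme.omega_prime, scheme.ds_prime, scheme.as_prime)
    return omega - omega_p


#: Gauss-Legendre nodes for the smooth parts of binomial-kernel integrals.
#: 256 nodes resolve the kernel for moderate n; for large n the kernel has
#: width ~ 1/sqrt(n), so the node count grows with n to keep quadrature exact
#: to ~1e-12.
_GL_BASE_NODES = 256
_gl_cache: dict = {}


def _gl_nodes(n_nodes: int):
    if n_nodes not in _gl_cache:
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        _gl_cache[n_nodes] = (0.5 * (x + 1.0), 0.5 * w)
    return _gl_cache[n_nodes]


def _binomial_side(fn: WeightFunction, n: int):
    """Numerator vector and denominator of the binomial-sampling scaling."""
    i = np.arange(1, n)
    nodes, wts = _gl_nodes(max(_GL_BASE_NODES, 64 * int(math.isqrt(n))))
    num = np.zeros(n - 1)
    den = 0.0
    if fn.kind != "zero":
        vals = fn.smooth(nodes) * wts
        # pmf matrix: rows = classes, cols = nodes
        pmf = binom.pmf(i[:, None], n, nodes[None, :])
        num += pmf @ vals
        den += float(np.sum((1.0 - nodes**n - (1.0 - nodes) ** n) * vals))
    for a, m in fn.diracs:
        num += m * binom.pmf(i, n, a)
        den += m * (1.0 - a**n - (1.0 - a) ** n)
    if abs(den) < 1e-300:
        raise ValueError("weight function not integrable/normalisable against the binomial kernel")
    return num, den


def realise_binomial(scheme: WeightScheme, n: int):
    """Binomial-sampling scaling (omega and omega' treated as frequency densities).

    Returns the pair (omega, omega') of normalised discrete weight vectors;
    Dirac components are integrated analytically, smooth parts by
    Gauss-Legendre quadrature.
    """
    num, den = _binomial_side(scheme.omega, n)
    nump, denp = _binomial_side(scheme.omega_prime, n)
    return num / den, nump / denp


def watterson_weights(n: int, N: Optional[int] = None) -> np.ndarray:
    """Normalised Watterson estimator weights omega_i = (1/i)/a_n.

    The continuum weight is the divergent 1/(f log N); under the ratio scaling
    the population-size cutoff N cancels exactly, so the discrete weights are
    independent of N (which is accepted only for interface symmetry).
    """
    i = np.arange(1, n)
    return (1.0 / i) / harmonic(n)


# ---------------------------------------------------------------------------
# catalogue of classic tests

def _scheme_tajima_d() -> WeightScheme:
    return WeightScheme(form="ratio", omega=WeightFunction("pairwise"),
                        omega_prime=WeightFunction("watterson"), name="tajima_d")


def _scheme_fay_wu_h() -> WeightScheme:
    return WeightScheme(form="ratio", omega=WeightFunction("pairwise"),
                        omega_prime=WeightFunction("derived_linear"), name="fay_wu_h")


def _scheme_zeng_e() -> WeightScheme:
    return WeightScheme(form="ratio", omega=WeightFunction("watterson"),
                        omega_prime=WeightFunction("uniform"), name="zeng_e")


def _scheme_fu_li_f() -> WeightScheme:
    return WeightScheme(form="ratio", omega=WeightFunction("zero"), ds=1.0,
                        omega_prime=WeightFunction("watterson"), name="fu_li_f")


def _scheme_bottleneck(beta: float) -> WeightScheme:
    return WeightScheme(form="ratio", omega=WeightFunction("exponential", {"beta": beta}),
                        omega_prime=WeightFunction("uniform"),
                        name=f"achaz_bottleneck(beta={beta:g})")


def _scheme_bottleneck_centering(beta: float) -> WeightScheme:
    # Omega(f) = beta e^{-beta f}/(1-e^{-beta}) - 1, realised by the centering
    # scaling; equivalent to the ratio form up to a positive multiplicative
    # factor, hence the same normalised test.
    fn = WeightFunction(
        "custom",
        fn=lambda f, b=beta: b * np.exp(-b * f) / (1.0 - np.exp(-b)) - 1.0,
    )
    return WeightScheme(form="centering", omega=fn,
                        name=f"achaz_bottleneck_centering(beta={beta:g})")


def _scheme_admixture() -> WeightScheme:
    return WeightScheme(form="binomial",
                        omega=WeightFunction("zero", diracs=((0.5, 1.0),)),
                        omega_prime=WeightFunction("uniform"), name="achaz_admixture")


def bottleneck_beta(alpha: float, n: int) -> float:
    """Weight-consistent bottleneck parameter beta = alpha * n.

    The historical per-class decay rate alpha of exp(-alpha i) corresponds to
    the sample-size-free decay rate beta of exp(-beta i/n).
    """
    return alpha * n


def error_corrected_scheme(base: WeightScheme, n: int) -> WeightScheme:
    """Singleton masses that cancel the weight function at classes 1 and n-1.

    For a ratio-form scheme the masses are -omega(1/n), -omega((n-1)/n) (and
    likewise for omega'), making the final realised weights of both singleton
    classes exactly zero, which removes the classes where sequencing errors
    concentrate.
    """
    lo, hi = 1.0 / n, (n - 1.0) / n
    if base.form == "ratio":
        return WeightScheme(
            form="ratio", omega=base.omega, omega_prime=base.omega_prime,
            ds=-float(base.omega.smooth(lo)), as_=-float(base.omega.smooth(hi)),
            ds_prime=-float(base.omega_prime.smooth(lo)),
            as_prime=-float(base.omega_prime.smooth(hi)),
            name=f"error_corrected({base.name})",
        )
    if base.form == "centering":
        return WeightScheme(
            form="centering", omega=base.omega,
            ds=-float(base.omega.smooth(lo)), as_=-float(base.omega.smooth(hi)),
            name=f"error_corrected({base.name})",
        )
    raise ValueError("error correction is defined for centering/ratio schemes")


def _fu_f_weights(n: int, r: float, r_prime: float) -> np.ndarray:
    for rr in (r, r_prime):
        if rr > 1.0:
            raise ValueError(
                f"F(r,r') with exponent {rr} > 1 requires a divergent-weight "
                "normalisation that is not defined; only r <= 1 is supported"
            )
    i = np.arange(1, n)

    def side(rr):
        v = i ** (-rr)
        return v / v.sum()

    return side(r) - side(r_prime)


def classic_test_weights(name: str, n: int, **params):
    """Realised Omega vector and metadata for a named classic test.

    Supported names: ``tajima_d``, ``fay_wu_h``, ``zeng_e``, ``fu_li_f``,
    ``fu_f`` (params r, r_prime <= 1), ``achaz_bottleneck`` (param beta, or
    alpha from which beta = alpha*n), ``achaz_admixture``, ``error_corrected``
    (param base: another catalogue name).
    """
    meta = {"name": name, "n": n, **params}
    if name == "fu_f":
        omega = _fu_f_weights(n, params["r"], params["r_prime"])
        return omega, meta
    if name == "achaz_bottleneck":
        beta = params.get("beta")
        if beta is None:
            beta = bottleneck_beta(params["alpha"], n)
        scheme = _scheme_bottleneck(beta)
        meta["beta"] = beta
    elif name == "error_corrected":
        base_name = params["base"]
        base, _ = _CATALOGUE[base_name](params)
        scheme = error_corrected_scheme(base, n)
    elif name in _CATALOGUE:
        scheme, _ = _CATALOGUE[name](params)
    else:
        raise ValueError(f"unknown classic test {name!r}")
    meta["scheme"] = scheme
    return scheme.realise(n), meta


_CATALOGUE = {
    "tajima_d": lambda p: (_scheme_tajima_d(), p),
    "fay_wu_h": lambda p: (_scheme_fay_wu_h(), p),
    "zeng_e": lambda p: (_scheme_zeng_e(), p),
    "fu_li_f": lambda p: (_scheme_fu_li_f(), p),
    "achaz_admixture": lambda p: (_scheme_admixture(), p),
}

CLASSIC_TESTS = ("tajima_d", "fay_wu_h", "zeng_e", "fu_li_f", "fu_f",
                 "achaz_bottleneck", "achaz_admixture", "error_corrected")


def admixture_average_weight(n: int, f_lo: float, f_hi: float) -> float:
    """Mean of the sample-size-rescaled admixture weights n*(omega_i - omega'_i)
    over classes with f_lo <= i/n <= f_hi (endpoints inclusive).

    This quantifies how the admixture test weights a fixed band of population
    allele frequencies as n varies; the strong n-dependence of the result is
    the canonical example of a test that is not weight-consistent.
    """
    if not (0.0 < f_lo < f_hi < 1.0):
        raise ValueError("require 0 < f_lo < f_hi < 1")
    omega, omega_p = realise_binomial(_scheme_admixture(), n)
    i = np.arange(1, n)
    mask = (i >= f_lo * n - 1e-12) & (i <= f_hi * n + 1e-12)
    if not mask.any():
        raise ValueError("no allele-frequency class falls in the requested range")
    return float(np.mean(n * (omega[mask] - omega_p[mask])))
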