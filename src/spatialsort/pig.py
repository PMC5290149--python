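"""Poisson-inverse-Gaussian (PIG) dispersal-kernel engine.

The PIG distribution is the workhorse dispersal model of this package: a
Poisson count whose rate is mixed over an inverse-Gaussian density. It is
the Sichel distribution with index fixed at -1/2, parameterized here by its
mean ``xi`` and a dimensionless shape ``omega``, giving variance
``xi * (1 + xi/omega)`` — always overdispersed relative to a Poisson with
the same mean, with Poisson recovered as ``omega -> inf``.

The pmf is evaluated in log space by a two-term forward recursion derived
from the Bessel-K recurrence, which is stable for large counts and small
shape values where direct special-function evaluation under/overflows.

Three kernel constructions sit on top of the pmf:

* :func:`symmetric_kernel` — the signed single-source kernel ``K`` on
  integer displacements, symmetric about 0;
* :func:`wave_mixture` — the equal-weight mixture ``M`` of ``K`` shifted to
  each of ``N`` contiguous source patches, used to infer kernels from the
  shape of a dispersing wave;
* :func:`pig_sample` — exact sampling via the inverse-Gaussian mixing
  representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PIGParams",
    "SignedKernel",
    "WaveMixture",
    "TruncationError",
    "pig_logpmf",
    "pig_pmf",
    "pig_logpmf_table",
    "pig_sample",
    "pig_loglik",
    "symmetric_kernel",
    "wave_mixture",
]

#: Hard cap on adaptive kernel support search.
MAX_SUPPORT_RADIUS = 10_000

#: Maximum truncated tail mass tolerated when building a finite-support kernel.
TAIL_TOL = 1e-9


class TruncationError(ValueError):
    """Raised when a requested finite support leaves too much tail mass."""


@dataclass(frozen=True)
class PIGParams:
    """Mean/shape parameterization of the PIG distribution.

    Parameters
    ----------
    xi
        Mean displacement, in patch units. Must be positive.
    omega
        Dimensionless shape. Must be positive. The implied variance is
        ``xi * (1 + xi / omega)``.
    """

    xi: float
    omega: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.xi) and self.xi > 0):
            raise ValueError(f"xi must be positive and finite, got {self.xi}")
        if not (np.isfinite(self.omega) and self.omega > 0):
            raise ValueError(f"omega must be positive and finite, got {self.omega}")

    @property
    def variance(self) -> float:
        return self.xi * (1.0 + self.xi / self.omega)


@dataclass(frozen=True)
class SignedKernel:
    """A symmetric probability mass function on integer displacements.

    ``support`` runs from ``-radius`` to ``+radius``; ``probs`` sums to 1
    over the stored support and satisfies ``prob(x) == prob(-x)``.
    """

    support: np.ndarray
    probs: np.ndarray

    @property
    def radius(self) -> int:
        return int(self.support[-1])

    def prob(self, x: int) -> float:
        """Probability of displacement ``x`` (0 outside the support)."""
        r = self.radius
        if abs(x) > r:
            return 0.0
        return float(self.probs[x + r])

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)


@dataclass(frozen=True)
class WaveMixture:
    """Equal-weight mixture of a signed kernel shifted to ``n_sources``
    contiguous starting patches 0..n_sources-1."""

    n_sources: int
    component: PIGParams
    support: np.ndarray
    probs: np.ndarray

    def prob(self, x: int) -> float:
        lo = int(self.support[0])
        if x < lo or x > int(self.support[-1]):
            return 0.0
        return float(self.probs[x - lo])

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)


def _validate_counts(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k)
    if k.size and (not np.issubdtype(k.dtype, np.number) or np.any(k != np.floor(k))):
        raise ValueError("counts must be integers")
    k = k.astype(np.int64, copy=False) if k.size else k.astype(np.int64)
    if k.size and k.min() < 0:
        raise ValueError("counts must be nonnegative")
    return k


def pig_logpmf_table(max_k: int, xi: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Log-pmf table ``log P(X=k)`` for ``k = 0..max_k``, vectorized over
    parameter vectors ``xi``/``omega`` (broadcast to a common shape).

    Uses the forward recursion (with ``L = xi*omega``, ``z^2 = omega^2 +
    2*xi*omega``)::

        p0      = exp(omega * (1 - sqrt(1 + 2 xi / omega)))
        p1      = (L / z) * p0
        p_{k+1} = [ L (2k-1) p_k + L^2 p_{k-1} / k ] / (z^2 (k+1))

    carried in log space with ``logaddexp``; all recursion coefficients are
    positive for ``k >= 1`` so no cancellation occurs.
    """
    xi = np.asarray(xi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    xi, omega = np.broadcast_arrays(xi, omega)
    if np.any(xi <= 0) or np.any(omega <= 0):
        raise ValueError("xi and omega must be positive")
    L = xi * omega
    z2 = omega * omega + 2.0 * L
    logL = np.log(L)
    logz2 = np.log(z2)

    out = np.empty((max_k + 1,) + xi.shape, dtype=float)
    # log p0 = omega (1 - sqrt(1 + 2 xi/omega)); write sqrt(z2) = omega*sqrt(1+2xi/omega)
    out[0] = omega - np.sqrt(z2)
    if max_k >= 1:
        out[1] = logL - 0.5 * logz2 + out[0]
    for k in range(1, max_k):
        a = logL + np.log(2.0 * k - 1.0) - logz2 - np.log(k + 1.0) + out[k]
        b = 2.0 * logL - np.log(float(k)) - logz2 - np.log(k + 1.0) + out[k - 1]
        out[k + 1] = np.logaddexp(a, b)
    return out


def pig_logpmf(k, params: PIGParams):
    """Log pmf of the PIG distribution at integer count(s) ``k``."""
    scalar = np.isscalar(k)
    karr = _validate_counts(np.atleast_1d(k))
    if karr.size == 0:
        return np.empty(0)
    table = pig_logpmf_table(int(karr.max()), np.float64(params.xi), np.float64(params.omega))
    res = table[karr]
    return float(res[0]) if scalar else res


def pig_pmf(k, params: PIGParams):
    """Pmf of the PIG distribution at integer count(s) ``k``."""
    return np.exp(pig_logpmf(k, params))


def pig_loglik(data, params: PIGParams) -> float:
    """Total log-likelihood of integer counts under a PIG distribution."""
    data = _validate_counts(np.asarray(data))
    if data.size == 0:
        raise ValueError("data must be non-empty")
    return float(np.sum(pig_logpmf(data, params)))


def pig_sample(n: int, params: PIGParams, rng) -> np.ndarray:
    """Draw ``n`` i.i.d. PIG counts via the Poisson/inverse-Gaussian mixture.

    The mixing density is inverse-Gaussian with mean ``xi`` and IG shape
    ``xi * omega``, which yields exactly mean ``xi`` and variance
    ``xi (1 + xi/omega)`` for the counts.

    ``rng`` is a :class:`numpy.random.Generator` or a seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n == 0:
        return np.empty(0, dtype=np.int64)
    lam = rng.wald(params.xi, params.xi * params.omega, size=n)
    return rng.poisson(lam).astype(np.int64)


def _adaptive_radius(params: PIGParams) -> int:
    """Smallest radius whose truncated right-tail mass is below TAIL_TOL."""
    block = max(32, int(8 * (params.xi + np.sqrt(params.variance))))
    r = block
    while r <= MAX_SUPPORT_RADIUS:
        table = np.exp(pig_logpmf_table(r, np.float64(params.xi), np.float64(params.omega)))
        cum = np.cumsum(table)
        idx = np.searchsorted(cum, 1.0 - TAIL_TOL)
        if idx < r:
            return int(idx) + 1
        r *= 2
    raise TruncationError(
        f"tail mass exceeds {TAIL_TOL} within radius {MAX_SUPPORT_RADIUS} for {params}"
    )


def symmetric_kernel(params: PIGParams, support_radius: int | None = None) -> SignedKernel:
    """The symmetric signed dispersal kernel ``K``.

    ``K(0) = PIG(0)`` and ``K(x) = PIG(|x|)/2`` for ``x != 0`` — the halving
    spreads each positive count equally over the two directions while the
    zero class, which has no direction, is counted once, so the kernel sums
    to one. The stored finite support (tail mass below ``1e-9``) is
    renormalized so the stored probabilities sum to 1 exactly.

    Raises :class:`TruncationError` if an explicit ``support_radius`` leaves
    more than ``1e-9`` tail mass.
    """
    if support_radius is None:
        r = _adaptive_radius(params)
    else:
        r = int(support_radius)
        if r < 0:
            raise ValueError("support_radius must be >= 0")
    pm = np.exp(pig_logpmf_table(r, np.float64(params.xi), np.float64(params.omega)))
    tail = 1.0 - pm.sum()
    if tail > TAIL_TOL:
        raise TruncationError(
            f"support_radius={r} leaves tail mass {tail:.3g} > {TAIL_TOL}"
        )
    probs = np.concatenate([pm[:0:-1] / 2.0, [pm[0]], pm[1:] / 2.0])
    probs /= probs.sum()
    support = np.arange(-r, r + 1)
    return SignedKernel(support=support, probs=probs)


def wave_mixture(params: PIGParams, n_sources: int) -> WaveMixture:
    """Equal-weight mixture ``M(x) = (1/N) sum_s K(x - s)`` over sources
    ``s = 0..N-1`` (contiguous starting patches)."""
    n_sources = int(n_sources)
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    K = symmetric_kernel(params)
    r = K.radius
    width = 2 * r + n_sources
    probs = np.zeros(width)
    for s in range(n_sources):
        probs[s : s + 2 * r + 1] += K.probs
    probs /= n_sources
    support = np.arange(-r, r + n_sources)
    return WaveMixture(n_sources=n_sources, component=params, support=support, probs=probs)
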