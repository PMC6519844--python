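"""Truncated linear operators for the chain-length population hierarchies.

Each rate-based variant (base, escape, q_model, force) is a linear ODE
system dN/dt = M N on the vector N = (n_1, n_2, ...) of mean counts of
free bacteria (n_1) and linear chains of length i (n_i).  The fixed-time
variant instead advances the population one division interval at a time,
N(t + tau) = T N(t), through a nonnegative transfer matrix built from
within-interval fragmentation survival probabilities.

The infinite hierarchy is truncated at ``n_max``: growth of a chain past
the truncation boundary is dropped, i.e. such chains are treated as lost
to complex clusters.  Lengths are 1-based; matrix row/column k represents
chains of length k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln

from .params import ModelParams, TruncationSpec

__all__ = [
    "RateMatrix",
    "TransferMatrix",
    "build_base_matrix",
    "build_escape_matrix",
    "build_q_matrix",
    "build_force_matrix",
    "build_transfer_matrix",
    "build_operator",
    "per_link_breaking_rate",
    "link_offsets",
    "survival_prob",
    "free_yield",
    "max_safe_n_max",
]

# exp() overflows just above exp(709); stay clear of it
_EXP_GUARD = 700.0

# dense eigensolves lose the O(1) dominant eigenvalue once entries pass
# ~exp(250); the force-model eigenvector tail decays like exp(-beta i^3/24),
# so capping n_max well below the overflow guard costs nothing
_EIG_ACCURACY_GUARD = 250.0


@dataclass(frozen=True)
class RateMatrix:
    """Continuous-time generator M with dN/dt = M N (Metzler structure)."""

    entries: np.ndarray
    params: ModelParams
    n_max: int

    @property
    def shape(self):
        return self.entries.shape


@dataclass(frozen=True)
class TransferMatrix:
    """Per-division-interval map T with N(t + tau) = T N(t) (nonnegative)."""

    entries: np.ndarray
    params: ModelParams
    n_max: int

    @property
    def shape(self):
        return self.entries.shape


def _check_trunc(trunc: TruncationSpec) -> int:
    if trunc.n_max < 2:
        raise ValueError("n_max must be >= 2")
    return trunc.n_max


def build_base_matrix(params: ModelParams, trunc: TruncationSpec) -> RateMatrix:
    """Rate matrix of the base model.

    Entry (i, j) couples chains of length j into chains of length i:
    replication feeds i from i-1 at rate r(i-1); a chain of length i
    loses probability flux at rate i r (replication) plus (i-1) alpha
    (link breaking); an outermost break of a chain of length i+1 feeds
    back one chain of length i and one free bacterium, and a length-2
    chain releases two free bacteria, so row 1 collects 2 alpha from
    every chain length >= 2.
    """
    if params.variant != "base":
        raise ValueError(f"expected base variant, got {params.variant!r}")
    n = _check_trunc(trunc)
    r, a = params.r, params.alpha
    m = np.zeros((n, n))
    i = np.arange(1, n + 1)
    m[np.arange(n), np.arange(n)] = -i * r - (i - 1) * a
    m[np.arange(1, n), np.arange(n - 1)] = r * i[:-1]  # (i, i-1) = r(i-1)
    m[np.arange(n - 1), np.arange(1, n)] += 2.0 * a  # (i, i+1) = 2 alpha
    m[0, 2:] += 2.0 * a  # breaks of chains >= 3 also free one bacterium
    return RateMatrix(m, params, n)


def build_escape_matrix(params: ModelParams, trunc: TruncationSpec) -> RateMatrix:
    """Rate matrix of the escape variant.

    On top of the base dynamics: a replicating free bacterium yields two
    free bacteria with probability delta; the outward daughter at a chain
    tip escapes with probability delta_prime (feeding row 1 at rate
    2 r delta' per chain); an interior daughter pair fails to bond with
    probability delta_dprime, clipping the chain (both halves absorbed
    into complex clusters, as inner breaks are); free bacteria and chains
    are lost at rates c and c_prime.
    """
    if params.variant != "escape":
        raise ValueError(f"expected escape variant, got {params.variant!r}")
    n = _check_trunc(trunc)
    r, a = params.r, params.alpha
    d, dp, dpp = params.delta, params.delta_prime, params.delta_dprime
    c, cp = params.c, params.c_prime
    m = np.zeros((n, n))
    # free bacteria
    m[0, 0] = r * (-1.0 + 2.0 * d) - c
    m[0, 1:] = 2.0 * r * dp + 2.0 * a
    # chains of length 2
    m[1, 0] = r * (1.0 - d)
    m[1, 1] = -2.0 * r * (1.0 - dp) - a - cp
    if n >= 3:
        m[1, 2] = 2.0 * a
    # chains of length i >= 3
    for i in range(3, n + 1):
        m[i - 1, i - 1] = r * (2.0 * dp - i) - (i - 1) * a - cp
        m[i - 1, i - 2] = r * (i - 1 - 2.0 * dp + 3.0 * dpp - i * dpp)
        if i < n:
            m[i - 1, i] = 2.0 * a
    return RateMatrix(m, params, n)


def build_q_matrix(params: ModelParams, trunc: TruncationSpec) -> RateMatrix:
    """Rate matrix of the subchain-escape variant.

    An inner break of a chain of length j at interior link position
    produces two independent chains with probability q; summing over the
    interior links, a chain of length i gains influx 2 alpha q from every
    chain of length i + 2 or longer, on top of the base-model terms.
    """
    if params.variant != "q_model":
        raise ValueError(f"expected q_model variant, got {params.variant!r}")
    n = _check_trunc(trunc)
    r, a, q = params.r, params.alpha, params.q
    m = np.zeros((n, n))
    i = np.arange(1, n + 1)
    m[np.arange(n), np.arange(n)] = -i * r - (i - 1) * a
    m[np.arange(1, n), np.arange(n - 1)] = r * i[:-1]
    m[np.arange(n - 1), np.arange(1, n)] += 2.0 * a
    m[0, 0] = -r
    m[0, 1:] = 2.0 * a
    # tail influx: row i >= 2 gains 2 alpha q from columns i+2, i+3, ...
    for row in range(2, n + 1):
        m[row - 1, row + 1:] += 2.0 * a * q
    return RateMatrix(m, params, n)


def link_offsets(chain_length: int) -> np.ndarray:
    """Signed distances of the links from the chain centre.

    A chain of length L has L-1 links; measured from the centre they sit
    at integer offsets for even L (0, +/-1, ..., +/-(L/2 - 1)) and at
    half-integer offsets for odd L (+/-1/2, ..., +/-(L/2 - 1)).
    """
    if chain_length < 2:
        raise ValueError("a chain needs length >= 2 to have links")
    L = chain_length
    half = L / 2.0 - 1.0
    if L % 2 == 0:
        return np.arange(-half, half + 0.5)
    return np.arange(-half, half + 0.5)  # half-integers: -half is x.5


def per_link_breaking_rate(
    chain_length: int, link_offset: float, params: ModelParams
) -> float:
    """Force-dependent breaking rate of one link.

    In shear flow the tension on a link at signed offset x from the centre
    of a chain of length L scales like (L/2)^2 - x^2, and the breaking
    rate grows exponentially with the force:
    alpha * exp(beta ((L/2)^2 - x^2) / 2).
    """
    if params.variant != "force":
        raise ValueError(f"expected force variant, got {params.variant!r}")
    if params.beta < 0:
        raise ValueError("beta must be >= 0")
    L = chain_length
    if L < 2:
        raise ValueError("chain_length must be >= 2")
    x = link_offset
    # parity: offsets are integers for even L, half-integers for odd L
    doubled = 2.0 * x
    if abs(doubled - round(doubled)) > 1e-9 or (round(doubled) % 2 == 0) != (
        L % 2 == 0
    ):
        raise ValueError(f"offset {x} inconsistent with chain length {L}")
    if abs(x) > L / 2.0 - 1.0 + 1e-9:
        raise ValueError(f"offset {x} out of range for chain length {L}")
    return params.alpha * math.exp(params.beta * ((L / 2.0) ** 2 - x * x) / 2.0)


def total_breaking_rate(chain_length: int, params: ModelParams) -> float:
    """Sum of the per-link force-dependent rates over all links."""
    return float(
        sum(
            per_link_breaking_rate(chain_length, x, params)
            for x in link_offsets(chain_length)
        )
    )


def max_safe_n_max(beta: float) -> int:
    """Largest n_max whose central-link rate stays below exp overflow."""
    if beta <= 0:
        return 10**9
    return int(math.floor(math.sqrt(8.0 * _EXP_GUARD / beta)))


def max_accurate_n_max(beta: float) -> int:
    """Largest force-model n_max at which dense eigensolves stay accurate.

    Beyond entries of ~exp(250) the QR algorithm can no longer resolve
    the O(1) dominant eigenvalue against the graded tail of the spectrum.
    """
    if beta <= 0:
        return 10**9
    return max(2, int(math.floor(math.sqrt(8.0 * _EIG_ACCURACY_GUARD / beta))))


def build_force_matrix(params: ModelParams, trunc: TruncationSpec) -> RateMatrix:
    """Rate matrix of the force-dependent-breaking variant.

    Row 1 collects 2 alpha exp(beta (j-1)/2) from every chain length
    j >= 2 (outermost links carry the lowest tension); the diagonal of
    row i carries the replication loss i r plus the summed per-link
    breaking rate of a length-i chain; an outermost break of a chain of
    length i+1 feeds row i at 2 alpha exp(beta i / 2).  beta -> 0
    recovers the base model.
    """
    if params.variant != "force":
        raise ValueError(f"expected force variant, got {params.variant!r}")
    n = _check_trunc(trunc)
    r, a, b = params.r, params.alpha, params.beta
    if b * n * n / 8.0 > _EXP_GUARD:
        raise OverflowError(
            f"beta*n_max^2/8 = {b * n * n / 8.0:.1f} exceeds the overflow "
            f"guard; the largest safe n_max for beta={b} is {max_safe_n_max(b)}"
        )
    m = np.zeros((n, n))
    m[0, 0] = -r
    for j in range(2, n + 1):
        m[0, j - 1] = 2.0 * a * math.exp(b * (j - 1) / 2.0)
    for i in range(2, n + 1):
        m[i - 1, i - 1] = -i * r - total_breaking_rate(i, params)
        m[i - 1, i - 2] = r * (i - 1)
        if i < n:
            m[i - 1, i] = 2.0 * a * math.exp(b * i / 2.0)
    return RateMatrix(m, params, n)


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(exp(x) - 1), stable for large and small x > 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):  # unselected where-branch may hit log(0)
        out = np.where(
            x > 30.0,
            x + np.log1p(-np.exp(-np.minimum(x, 700.0))),
            np.log(np.expm1(x)),
        )
    return out


def survival_prob(n: int, i: int, t: float, alpha: float) -> float:
    """Probability that a chain born at length n is at length n - i at t.

    Pure fragmentation with q = 0: only outermost breaks leave a linear
    chain behind, each shaving one bacterium off an end.  The probability
    of having lost exactly i bacteria by time t is
    (2^i / i!) exp(-alpha t (n-1)) (exp(alpha t) - 1)^i.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 <= i <= n - 2:
        raise ValueError(f"i must be in [0, {n - 2}], got {i}")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 1.0 if i == 0 else 0.0
    at = alpha * t
    log_l = (
        i * math.log(2.0)
        - gammaln(i + 1)
        - at * (n - 1)
        + i * float(_log_expm1(at))
    )
    return float(math.exp(log_l))


def _survival_profile(n: int, t: float, alpha: float) -> np.ndarray:
    """Vector of survival_prob(n, i, t) for i = 0 .. n-2 (log-space)."""
    if t == 0.0:
        out = np.zeros(n - 1)
        out[0] = 1.0
        return out
    i = np.arange(n - 1)
    at = alpha * t
    log_l = i * math.log(2.0) - gammaln(i + 1) - at * (n - 1) + i * _log_expm1(at)
    return np.exp(log_l)


def free_yield(n: int, tau: float, alpha: float, method: str = "recurrence") -> float:
    """Mean number of free bacteria released by a length-n chain within tau.

    Each surviving linear chain emits free bacteria at rate 2 alpha
    (two outermost links, or both members of a length-2 chain), so the
    yield is 2 alpha sum_i int_0^tau l(n, i, t) dt.  The time integrals
    I(n, i) obey the stable recurrence

        I(n, i) = (2 alpha I(n, i-1) + [i = 0] - l(n, i, tau)) / (alpha (n-1-i))

    obtained by integrating the fragmentation ODE; ``method="quadrature"``
    evaluates the integrals adaptively instead (cross-check path).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if method == "quadrature":
        total = 0.0
        for i in range(n - 1):
            val, _ = quad(
                lambda t, i=i: survival_prob(n, i, t, alpha),
                0.0,
                tau,
                epsabs=1e-10,
                limit=200,
            )
            total += val
        return 2.0 * alpha * total
    if method != "recurrence":
        raise ValueError(f"unknown method {method!r}")
    if n == 2:
        return 2.0 * (1.0 - math.exp(-alpha * tau))
    l_tau = _survival_profile(n, tau, alpha)
    total = 0.0
    prev = 0.0
    for i in range(n - 1):
        source = 1.0 if i == 0 else 0.0
        cur = (2.0 * alpha * prev + source - l_tau[i]) / (alpha * (n - 1 - i))
        total += cur
        prev = cur
    return 2.0 * alpha * total


def build_transfer_matrix(params: ModelParams, trunc: TruncationSpec) -> TransferMatrix:
    """Per-interval transfer matrix of the fixed-replication-time variant.

    A chain of length j just before a division becomes length 2j upon it,
    then fragments for tau.  Column j therefore holds the free-bacteria
    yield of a 2j-chain in row 1 and the survival probabilities
    l(2j, 2j - k, tau) in rows 2 <= k <= 2j.  The matrix is cut to
    n_max x n_max; shrinkage products of chains whose doubled length
    exceeds n_max are still counted at lengths <= n_max.
    """
    if params.variant != "fixed_time":
        raise ValueError(f"expected fixed_time variant, got {params.variant!r}")
    n = _check_trunc(trunc)
    tau, a = params.tau, params.alpha
    t = np.zeros((n, n))
    for j in range(1, n + 1):
        born = 2 * j
        t[0, j - 1] = free_yield(born, tau, a)
        profile = _survival_profile(born, tau, a)  # index i = bacteria lost
        for k in range(2, min(born, n) + 1):
            t[k - 1, j - 1] = profile[born - k]
    return TransferMatrix(t, params, n)


_BUILDERS = {
    "base": build_base_matrix,
    "escape": build_escape_matrix,
    "q_model": build_q_matrix,
    "force": build_force_matrix,
    "fixed_time": build_transfer_matrix,
}


def build_operator(params: ModelParams, trunc: TruncationSpec):
    """Build the variant-appropriate operator (rate or transfer matrix)."""
    return _BUILDERS[params.variant](params, trunc)
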