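"""Closed-form distributions, growth-rate approximations and estimates.

These are the analytically tractable limits of the chain models: the
geometric stationary distributions of the base/escape variants, the exact
q = 1 solution, the large-i growth-rate approximation of the q-model, the
rough fixed-time distribution, the force-model distribution, and the
back-of-envelope count of sIgA molecules per bacterium in gut content.

They serve both as user-facing formulas and as oracles for the numerical
eigen-solutions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

__all__ = [
    "base_distribution",
    "escape_distribution",
    "q1_distribution",
    "q1_mean_length",
    "q_growth_rate_approx",
    "free_fraction_decay",
    "fixed_time_distribution",
    "force_constants",
    "force_distribution",
    "siga_per_bacterium",
]

AVOGADRO = 6.02214076e23  # 1/mol


def base_distribution(r: float, alpha: float, k) -> np.ndarray | float:
    """Stationary proportion of chains of length k in the base model.

    Geometric with ratio r/(r+alpha), normalised over k >= 1:
    p_k = (1 - r/(r+alpha)) (r/(r+alpha))^(k-1).  Large-length
    approximation; most accurate at small r/alpha.
    """
    if r < 0 or alpha <= 0:
        raise ValueError("need r >= 0 and alpha > 0")
    g = r / (r + alpha)
    k = np.asarray(k)
    out = (1.0 - g) * g ** (k - 1)
    return out if out.ndim else float(out)


def escape_distribution(r: float, alpha: float, delta_dprime: float, k):
    """Stationary chain-length proportions with interior-escape clipping.

    Geometric with ratio (1 - delta'') r/(r+alpha); reduces to the base
    distribution at delta'' = 0.  The tip and free-bacterium escape
    probabilities do not enter this large-length form.
    """
    if not 0.0 <= delta_dprime <= 1.0:
        raise ValueError("delta_dprime must be in [0, 1]")
    g = (1.0 - delta_dprime) * r / (r + alpha)
    k = np.asarray(k)
    out = (1.0 - g) * g ** (k - 1)
    return out if out.ndim else float(out)


def q1_distribution(r: float, alpha: float, k):
    """Exact stationary distribution when subchains always escape (q = 1).

    The hierarchy closes exactly: n_k(t) = C exp(r t) (r/(alpha+r))^k, so
    the normalised proportions form a geometric distribution with ratio
    r/(alpha+r).  This coincides with the base model's approximation but
    is exact here.
    """
    if r <= 0 or alpha <= 0:
        raise ValueError("need r > 0 and alpha > 0")
    g = r / (alpha + r)
    k = np.asarray(k)
    out = (1.0 - g) * g ** (k - 1)
    return out if out.ndim else float(out)


def q1_mean_length(r: float, alpha: float) -> float:
    """Mean chain length 1 + r/alpha of the exact q = 1 solution."""
    if r < 0 or alpha <= 0:
        raise ValueError("need r >= 0 and alpha > 0")
    return 1.0 + r / alpha


def q_growth_rate_approx(r: float, alpha: float, q: float) -> float:
    """Approximate growth rate r (alpha + (2q - 1) r)/(alpha + r).

    Valid for q close to 1 (exact at q = 1, where it returns r); known to
    fail for q < 0.5, where the true lambda(r) has an interior maximum.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return r * (alpha + (2.0 * q - 1.0) * r) / (alpha + r)


def free_fraction_decay(r: float, alpha: float, q: float, t: float) -> float:
    """Long-time proportion of bacteria that are free, exp(-2 r^2 t (1-q)/(r+alpha)).

    Derived from exp((lambda - r) t) with the q-model growth-rate
    approximation; equals 1 for all t at q = 1 (no trapping).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return math.exp(-2.0 * r * r * t * (1.0 - q) / (r + alpha))


def fixed_time_distribution(alpha_tau: float, i) -> np.ndarray | float:
    """Rough fixed-time stationary proportions relative to p_1.

    For division interval tau and breaking rate alpha, the core of the
    distribution follows p_i/p_1 ~ i^(alpha tau/log 2 - 1) exp(-2 alpha
    tau (i - 1)), anchored so the ratio is exactly 1 at i = 1.  Derived
    for i a power of two and with the per-interval multiplier set to its
    large-(alpha tau) limit of 2; use as an order-of-magnitude shape only.
    """
    if alpha_tau <= 0:
        raise ValueError("alpha_tau must be > 0")
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise ValueError("lengths must be >= 1")
    expo = alpha_tau / math.log(2.0) - 1.0
    out = i**expo * np.exp(-2.0 * alpha_tau * (i - 1.0))
    return out if out.ndim else float(out)


def force_constants(beta: float, tol: float = 1e-16) -> tuple[float, float]:
    """Lattice sums Y = 1 + 2 sum exp(-beta j^2/2), Z = 2 sum exp(-beta (j-1/2)^2/2).

    The series are truncated once a term drops below ``tol``; both
    decrease toward (1, 0) as beta grows.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    y = 1.0
    j = 1
    while True:
        term = 2.0 * math.exp(-beta * j * j / 2.0)
        if term < tol:
            break
        y += term
        j += 1
    z = 0.0
    j = 1
    while True:
        term = 2.0 * math.exp(-beta * (j - 0.5) ** 2 / 2.0)
        if term < tol:
            break
        z += term
        j += 1
    return y, z


def force_distribution(
    r: float, alpha: float, beta: float, i, normalize: bool = False
):
    """Approximate stationary proportions of the force-breaking model.

    Balancing the replication influx r (i-1) p_{i-1} against the total
    breaking rate D_i = alpha exp(beta i^2/8) (Y or Z for even/odd i)
    of a length-i chain gives

    p_i ~ (r/alpha)^(i-1) (i-1)! Y^-floor(i/2) Z^-floor((i-1)/2)
          * exp(-(beta/8)(-1 + (i + 3 i^2 + 2 i^3)/6)),

    with Y, Z the force lattice sums (the exponent collects
    sum_{j=2..i} j^2/8).  The i^3 term makes the tail decay
    super-geometrically.  Returned unnormalised (p_1 = 1) unless
    ``normalize`` is set, in which case the values are renormalised over
    the supplied lengths.  Works well except at small beta.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    y, z = force_constants(beta)
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise ValueError("lengths must be >= 1")
    log_p = (
        (i - 1.0) * math.log(r / alpha)
        + gammaln(i)
        - np.floor(i / 2.0) * math.log(y)
        - np.floor((i - 1.0) / 2.0) * math.log(z)
        - (beta / 8.0) * (-1.0 + (i + 3.0 * i**2 + 2.0 * i**3) / 6.0)
    )
    out = np.exp(log_p)
    if normalize:
        out = out / out.sum()
    return out if out.ndim else float(out)


def siga_per_bacterium(
    siga_mass_per_gram: float = 50e-6,
    molecular_mass_da: float = 385e3,
    bacteria_per_gram: float = 1e11,
    rounded: bool = True,
) -> float:
    """Back-of-envelope sIgA molecules available per bacterium.

    A gram of digestive content holds at most ~1e11 bacteria and
    typically >= 50 micrograms of secretory IgA of molecular mass
    ~385 kDa; dividing molecule count by bacterial count gives roughly
    800 sIgA per bacterium (782 before rounding to one significant
    figure).

    Masses in grams, molecular mass in daltons (g/mol).
    """
    if min(siga_mass_per_gram, molecular_mass_da, bacteria_per_gram) <= 0:
        raise ValueError("all inputs must be > 0")
    count = siga_mass_per_gram / molecular_mass_da * AVOGADRO / bacteria_per_gram
    if not rounded:
        return count
    if count <= 0:
        return 0.0
    mag = 10 ** math.floor(math.log10(count))
    return round(count / mag) * mag
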