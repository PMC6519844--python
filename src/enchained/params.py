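"""Parameter containers for the chain growth-fragmentation models.

A bacterial population under secretory-IgA enchainment is described as a
collection of free bacteria (length-1 "chains") and linear chains of
pole-to-pole linked bacteria.  Five model variants share a common parameter
set:

``base``
    Fixed replication rate ``r`` per bacterium, fixed breaking rate
    ``alpha`` per link, perfect enchainment on replication, inner breaks
    always absorbed into complex clusters (q = 0).
``escape``
    Adds escape probabilities on replication (``delta`` for free bacteria,
    ``delta_prime`` at chain tips, ``delta_dprime`` inside chains) and loss
    rates ``c`` (free bacteria) and ``c_prime`` (chains).
``fixed_time``
    Bacteria divide synchronously every ``tau``; fragmentation acts between
    divisions.  The effective replication rate is r_eff = log(2)/tau.
``q_model``
    After an inner link breaks, the two subchains escape as independent
    linear chains with probability ``q`` (q = 0 recovers the base model,
    q = 1 has an exact geometric solution).
``force``
    Hydrodynamic shear makes links break faster near the chain centre and
    in longer chains; ``beta`` couples force to the breaking rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

VARIANTS = ("base", "escape", "fixed_time", "q_model", "force")

# parameters that may deviate from their defaults, per variant
_ALLOWED_EXTRAS = {
    "base": set(),
    "escape": {"delta", "delta_prime", "delta_dprime", "c", "c_prime"},
    "fixed_time": {"tau"},
    "q_model": {"q"},
    "force": {"beta"},
}


@dataclass(frozen=True)
class ModelParams:
    """Rates and probabilities for one model variant.

    Parameters
    ----------
    variant
        One of ``base``, ``escape``, ``fixed_time``, ``q_model``, ``force``.
    r
        Bacterial replication rate (per unit time).  Ignored by
        ``fixed_time``, which uses ``tau`` instead.
    alpha
        Breaking rate of a single inter-bacterial link (per unit time).
    tau
        Division interval of the ``fixed_time`` variant.
    delta, delta_prime, delta_dprime
        Escape probabilities on replication (``escape`` variant): of the
        daughter of a free bacterium, of the outward daughter at a chain
        tip, and of an interior daughter pair failing to bond (which clips
        the chain in two).
    c, c_prime
        Loss rates of free bacteria and of chains (``escape`` variant).
    q
        Probability that the two subchains from an inner-link break persist
        as independent linear chains (``q_model``).
    beta
        Force-coupling constant of the ``force`` variant (dimensionless).
    """

    variant: str = "base"
    r: float = 1.0
    alpha: float = 1.0
    tau: float = math.log(2.0)
    delta: float = 0.0
    delta_prime: float = 0.0
    delta_dprime: float = 0.0
    c: float = 0.0
    c_prime: float = 0.0
    q: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        for name in ("r", "alpha", "tau", "c", "c_prime", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.variant == "fixed_time" and self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        for name in ("delta", "delta_prime", "delta_dprime", "q"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        self._check_extras()

    def _check_extras(self) -> None:
        defaults = {
            "delta": 0.0,
            "delta_prime": 0.0,
            "delta_dprime": 0.0,
            "c": 0.0,
            "c_prime": 0.0,
            "q": 0.0,
            "beta": 0.0,
        }
        allowed = _ALLOWED_EXTRAS[self.variant]
        for name, default in defaults.items():
            if getattr(self, name) != default and name not in allowed:
                raise ValueError(
                    f"parameter {name!r} is not part of the {self.variant!r} variant"
                )

    @property
    def r_eff(self) -> float:
        """Effective replication rate log(2)/tau of the fixed-time variant."""
        return math.log(2.0) / self.tau

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class TruncationSpec:
    """Finite truncation of the infinite chain-length hierarchy.

    Chains longer than ``n_max`` are treated as lost to complex clusters:
    flux past the truncation boundary is dropped.  ``convergence_tol`` is
    the relative change in the dominant eigenvalue, under doubling of
    ``n_max``, below which the truncation is declared adequate.
    """

    n_max: int = 40
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


#: default truncation sizes per variant (adequate for moderate r/alpha;
#: raised automatically when the convergence check fails)
DEFAULT_N_MAX = {
    "base": 40,
    "escape": 40,
    "fixed_time": 32,
    "q_model": 200,
    "force": 15,
}


def default_truncation(variant: str, beta: float = 0.0) -> TruncationSpec:
    """Variant-appropriate default truncation.

    The force model needs smaller ``n_max`` at large ``beta`` because the
    central-link breaking rate grows like exp(beta n^2 / 8); long chains
    are then so short-lived that they never matter.
    """
    n = DEFAULT_N_MAX[variant]
    if variant == "force" and beta >= 2.0:
        n = 10
    return TruncationSpec(n_max=n)
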