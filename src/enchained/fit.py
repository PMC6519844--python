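"""Maximum-likelihood fitting of a model variant to a chain-length histogram.

A stationary chain-length shape has a single identifiable parameter: the
ratio of replication to breaking rate (r_eff/alpha for the fixed-time
variant, r/alpha for the rate variants) -- alpha and r separately only
set the time scale.  The observed histogram of linear chains of length
>= 2 is treated as a multinomial draw from the model's dominant
eigenvector conditioned on length >= 2, which is how experimental
microscopy counts are normalised (free-bacteria counts from images are
unreliable).

The modelling interface follows the Model/Results convention: build a
:class:`ChainLengthModel` from a histogram, call :meth:`fit`, and read
the estimate, profile-likelihood confidence interval and diagnostics off
the returned :class:`ChainLengthFitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .matrices import build_operator
from .params import ModelParams, TruncationSpec
from .simulate import ChainLengthHistogram, sample_histogram
from .spectral import dominant_eigenpair

__all__ = [
    "ChainLengthModel",
    "ChainLengthFitResult",
    "conditional_model_distribution",
    "fit_ratio",
    "goodness_of_fit",
    "GoodnessOfFit",
]


def _ratio_params(variant: str, ratio: float, extras: dict | None = None) -> ModelParams:
    """Parameters at unit breaking rate realising the requested ratio."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    extras = extras or {}
    if variant == "fixed_time":
        return ModelParams(
            "fixed_time", alpha=1.0, tau=math.log(2.0) / ratio, **extras
        )
    return ModelParams(variant, r=ratio, alpha=1.0, **extras)


@lru_cache(maxsize=4096)
def _cached_distribution(
    variant: str, ratio: float, n_max: int, extras: tuple = ()
) -> tuple:
    # fixed truncation during fitting: the window is conditioned and
    # renormalised, so adequacy comes from n_max >= 4x the longest
    # observed chain, not from the doubling check (which fails at the
    # extreme ratios a bounded optimiser probes)
    op = build_operator(
        _ratio_params(variant, ratio, dict(extras)), TruncationSpec(n_max=n_max)
    )
    res = dominant_eigenpair(op, check_convergence=False)
    return tuple(res.distribution[:n_max])


def conditional_model_distribution(
    variant: str,
    ratio: float,
    min_length: int = 2,
    max_length: int | None = None,
    n_max: int = 64,
    variant_params: dict | None = None,
) -> np.ndarray:
    """Stationary proportions restricted to [min_length, max_length].

    The dominant eigenvector is computed at the requested ratio, cut to
    the observation window and renormalised to sum to one -- the model's
    prediction conditional on seeing a linear chain in that window.
    """
    if max_length is None:
        max_length = n_max
    if not 1 <= min_length <= max_length <= n_max:
        raise ValueError(
            f"need 1 <= min_length <= max_length <= n_max, got "
            f"[{min_length}, {max_length}] with n_max={n_max}"
        )
    extras = tuple(sorted((variant_params or {}).items()))
    p = np.asarray(_cached_distribution(variant, float(ratio), int(n_max), extras))
    window = p[min_length - 1 : max_length]
    total = window.sum()
    if total <= 0:
        raise ValueError("model puts no mass on the requested length window")
    return window / total


@dataclass(frozen=True)
class ChainLengthFitResult:
    """MLE of the replication-to-breaking ratio with profile-likelihood CI."""

    estimate: float
    ci_low: float
    ci_high: float
    loglik: float
    n_chains_used: int
    length_range_used: tuple[int, int]
    model_variant: str
    flat_likelihood: bool = False
    model: "ChainLengthModel | None" = field(default=None, compare=False, repr=False)

    def to_dict(self) -> dict:
        return {
            "variant": self.model_variant,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "loglik": self.loglik,
            "n_chains_used": self.n_chains_used,
            "length_range_used": list(self.length_range_used),
            "flat_likelihood": self.flat_likelihood,
        }

    def summary(self) -> str:
        name = "r_eff/alpha" if self.model_variant == "fixed_time" else "r/alpha"
        lines = [
            "Chain-length distribution fit",
            "=" * 45,
            f"variant:            {self.model_variant}",
            f"{name + ':':<19} {self.estimate:.3f}",
            f"95% CI:             [{self.ci_low:.3f}, {self.ci_high:.3f}]",
            f"log-likelihood:     {self.loglik:.3f}",
            f"chains used:        {self.n_chains_used}",
            f"length range:       {self.length_range_used[0]}"
            f"-{self.length_range_used[1]}",
        ]
        if self.flat_likelihood:
            lines.append("warning: flat likelihood; CI spans the search interval")
        return "\n".join(lines)


class ChainLengthModel:
    """One-parameter chain-length model over an observed histogram.

    Parameters
    ----------
    histogram
        Observed chain-length counts; lengths below ``min_length``
        (free bacteria by default) are ignored.
    variant
        Which model family supplies the stationary shape
        (default ``fixed_time``, the realistic division rule).
    min_length
        Smallest length included in the conditioning window (default 2).
    n_max
        Truncation of the underlying operator; defaults to four times
        the longest observed chain so that the fitted support is
        effectively open-ended.
    """

    def __init__(
        self,
        histogram: ChainLengthHistogram,
        variant: str = "fixed_time",
        min_length: int = 2,
        n_max: int | None = None,
        variant_params: dict | None = None,
    ) -> None:
        obs = {k: c for k, c in histogram.counts.items() if k >= min_length and c > 0}
        if not obs:
            raise ValueError(
                f"histogram has no chains of length >= {min_length}"
            )
        self.histogram = histogram
        self.variant = variant
        self.min_length = min_length
        self.lengths = np.array(sorted(obs))
        self.counts = np.array([obs[k] for k in self.lengths])
        self.n_obs = int(self.counts.sum())
        if n_max is None:
            n_max = max(4 * int(self.lengths.max()), 16)
        self.n_max = n_max
        self.variant_params = variant_params

    @classmethod
    def from_file(cls, path, **kwargs) -> "ChainLengthModel":
        from .io import read_histogram

        return cls(read_histogram(path), **kwargs)

    def distribution(self, ratio: float) -> np.ndarray:
        """Conditioned model proportions over lengths min_length..n_max."""
        return conditional_model_distribution(
            self.variant, ratio, self.min_length, self.n_max, self.n_max,
            self.variant_params,
        )

    def loglike(self, ratio: float) -> float:
        """Multinomial log-likelihood of the observed counts at ``ratio``."""
        p = self.distribution(ratio)
        idx = self.lengths - self.min_length
        pk = p[idx]
        if np.any(pk <= 0):
            return -math.inf
        return float(np.sum(self.counts * np.log(pk)))

    def fit(
        self,
        bounds: tuple[float, float] = (0.05, 50.0),
        ci_level: float = 0.95,
        xatol: float = 1e-4,
    ) -> ChainLengthFitResult:
        """Maximise the likelihood and profile a confidence interval.

        The CI collects ratios whose log-likelihood is within half the
        chi-square(1) quantile of the maximum (1.92 at 95%); when the
        likelihood is flat (all mass at one length), the CI is the full
        search interval and a warning flag is set.
        """
        lo, hi = bounds
        opt = minimize_scalar(
            lambda x: -self.loglike(x), bounds=(lo, hi), method="bounded",
            options={"xatol": xatol},
        )
        if not opt.success:
            raise RuntimeError(f"likelihood optimisation failed: {opt.message}")
        mle, lmax = float(opt.x), float(-opt.fun)
        drop = float(chi2.ppf(ci_level, df=1)) / 2.0

        def deficit(x: float) -> float:
            return self.loglike(x) - (lmax - drop)

        flat = False
        if deficit(lo) > 0 and deficit(hi) > 0:
            # likelihood flat over the whole interval
            ci_lo, ci_hi, flat = lo, hi, True
        else:
            ci_lo = lo if deficit(lo) > 0 else brentq(deficit, lo, mle, xtol=xatol)
            ci_hi = hi if deficit(hi) > 0 else brentq(deficit, mle, hi, xtol=xatol)
            flat = bool(deficit(lo) > 0 or deficit(hi) > 0)
        return ChainLengthFitResult(
            estimate=mle,
            ci_low=float(ci_lo),
            ci_high=float(ci_hi),
            loglik=lmax,
            n_chains_used=self.n_obs,
            length_range_used=(int(self.lengths.min()), int(self.lengths.max())),
            model_variant=self.variant,
            flat_likelihood=flat,
            model=self,
        )


def fit_ratio(
    histogram: ChainLengthHistogram,
    variant: str = "fixed_time",
    **options,
) -> ChainLengthFitResult:
    """Convenience wrapper: build the model and fit in one call."""
    fit_kwargs = {
        k: options.pop(k) for k in ("bounds", "ci_level", "xatol") if k in options
    }
    return ChainLengthModel(histogram, variant=variant, **options).fit(**fit_kwargs)


@dataclass(frozen=True)
class GoodnessOfFit:
    """Likelihood-ratio statistic against the saturated multinomial."""

    statistic: float
    tail_prob: float
    n_boot: int


def goodness_of_fit(
    histogram: ChainLengthHistogram,
    variant: str,
    fit: ChainLengthFitResult,
    n_boot: int = 99,
    seed: int | None = None,
) -> GoodnessOfFit:
    """Parametric-bootstrap test of the fitted shape.

    The statistic is the likelihood-ratio deviance of the fitted model
    against the saturated multinomial; its null distribution is obtained
    by refitting histograms sampled from the fitted model itself.
    """
    model = ChainLengthModel(histogram, variant=variant)
    if model.lengths.size < 2:
        raise ValueError("goodness of fit needs at least two occupied lengths")

    def deviance(m: ChainLengthModel, res: ChainLengthFitResult) -> float:
        p = m.distribution(res.estimate)
        idx = m.lengths - m.min_length
        expected = m.n_obs * p[idx]
        return float(2.0 * np.sum(m.counts * np.log(m.counts / expected)))

    g_obs = deviance(model, fit)
    p_fit = model.distribution(fit.estimate)
    lengths = np.arange(model.min_length, model.n_max + 1)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        h = sample_histogram(
            p_fit, model.n_obs, seed=int(rng.integers(2**31)), lengths=lengths
        )
        m_b = ChainLengthModel(h, variant=variant, n_max=model.n_max)
        res_b = m_b.fit()
        if deviance(m_b, res_b) >= g_obs:
            exceed += 1
    return GoodnessOfFit(g_obs, (1 + exceed) / (n_boot + 1), n_boot)
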