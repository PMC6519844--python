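"""Event-driven stochastic simulation of the chain models.

The mean-field operators describe expected counts; this module simulates
the underlying stochastic rules directly (Gillespie's direct method for
the rate-based variants, synchronous doubling plus exponential-clock
fragmentation for the fixed-time variant).  Chains of equal length are
statistically exchangeable in every variant -- the force model's per-link
rates depend only on length and position, and positions are determined by
length -- so the state is kept as a counter of chain lengths.

The simulator serves as an independent check on the eigenvalue analysis
and as the generator of synthetic chain-length histograms for fitting
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrices import link_offsets, per_link_breaking_rate
from .params import ModelParams

__all__ = [
    "SimState",
    "ChainLengthHistogram",
    "SimResult",
    "simulate_rates",
    "simulate_fixed_tau",
    "sample_histogram",
]


@dataclass
class ChainLengthHistogram:
    """Integer counts of linear chains by length (length 1 = free)."""

    counts: dict[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.counts.items():
            if length < 1 or count < 0 or count != int(count):
                raise ValueError(
                    f"invalid histogram entry: length {length}, count {count}"
                )
        self.counts = {int(k): int(v) for k, v in sorted(self.counts.items())}

    @property
    def total_chains(self) -> int:
        return sum(self.counts.values())

    @property
    def total_bacteria(self) -> int:
        return sum(k * v for k, v in self.counts.items())

    @property
    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def as_vector(self, n_max: int) -> np.ndarray:
        """Counts as a dense vector over lengths 1..n_max."""
        v = np.zeros(n_max)
        for k, c in self.counts.items():
            if k <= n_max:
                v[k - 1] = c
        return v


@dataclass
class SimState:
    """One stochastic realisation: chain-length counter plus bookkeeping."""

    chains: dict[int, int] = field(default_factory=lambda: {1: 1})
    complex_cluster_bacteria: int = 0
    time: float = 0.0
    rng_seed: int | None = None
    truncated: bool = False  # set when the population cap stopped the run

    @property
    def total_bacteria(self) -> int:
        return sum(k * v for k, v in self.chains.items())

    @property
    def total_chains(self) -> int:
        return sum(self.chains.values())

    def histogram(self, **metadata) -> ChainLengthHistogram:
        meta = {"time": self.time, "seed": self.rng_seed, **metadata}
        return ChainLengthHistogram(
            {k: v for k, v in self.chains.items() if v > 0}, meta
        )


@dataclass
class SimResult:
    """Final state, its histogram, and optional checkpoint snapshots."""

    state: SimState
    histogram: ChainLengthHistogram
    checkpoints: list[tuple[float, dict[int, int]]] = field(default_factory=list)


def _chain_propensities(m: int, params: ModelParams) -> tuple[float, float, float]:
    """(replication, breaking, loss) propensities of one chain of length m."""
    rep = m * params.r
    if m == 1:
        return rep, 0.0, params.c
    if params.variant == "force":
        brk = sum(
            per_link_breaking_rate(m, x, params) for x in link_offsets(m)
        )
    else:
        brk = (m - 1) * params.alpha
    return rep, brk, params.c_prime


def _apply_replication(state: SimState, m: int, params: ModelParams, rng) -> None:
    counts = state.chains
    counts[m] -= 1
    if m == 1:
        if params.delta > 0 and rng.random() < params.delta:
            counts[1] = counts.get(1, 0) + 2  # both daughters free
        else:
            counts[2] = counts.get(2, 0) + 1
        return
    # replicating bacterium uniform over the chain: tip with prob 2/m
    if rng.random() < 2.0 / m:
        if params.delta_prime > 0 and rng.random() < params.delta_prime:
            counts[1] = counts.get(1, 0) + 1  # outward daughter escapes
            counts[m] = counts.get(m, 0) + 1
        else:
            counts[m + 1] = counts.get(m + 1, 0) + 1
    else:
        if params.delta_dprime > 0 and rng.random() < params.delta_dprime:
            # interior daughters fail to bond; with q = 0 semantics both
            # clipped halves collide into a complex cluster
            state.complex_cluster_bacteria += m + 1
        else:
            counts[m + 1] = counts.get(m + 1, 0) + 1


def _apply_break(state: SimState, m: int, params: ModelParams, rng) -> None:
    counts = state.chains
    counts[m] -= 1
    if m == 2:
        counts[1] = counts.get(1, 0) + 2
        return
    # choose the breaking link: uniform, or weighted by per-link rate
    if params.variant == "force":
        offs = link_offsets(m)
        w = np.array([per_link_breaking_rate(m, x, params) for x in offs])
        link = int(rng.choice(m - 1, p=w / w.sum())) + 1  # 1-based position
    else:
        link = int(rng.integers(1, m))  # link between bacteria link, link+1
    left, right = link, m - link
    if left == 1 or right == 1:
        # outermost break: the single bacterium always escapes
        counts[1] = counts.get(1, 0) + 1
        counts[m - 1] = counts.get(m - 1, 0) + 1
    elif params.q > 0 and rng.random() < params.q:
        counts[left] = counts.get(left, 0) + 1
        counts[right] = counts.get(right, 0) + 1
    else:
        state.complex_cluster_bacteria += m


def simulate_rates(
    params: ModelParams,
    initial: SimState | None = None,
    t_end: float = 5.0,
    seed: int | None = None,
    population_cap: int = 10**6,
    checkpoint_times: np.ndarray | None = None,
) -> SimResult:
    """Gillespie simulation of a rate-based variant up to ``t_end``.

    Each chain of length m carries replication propensity m r, total
    breaking propensity (m-1) alpha (force-weighted per link in the force
    variant) and a loss propensity c or c_prime.  Outermost breaks always
    free the single bacterium; inner breaks release two independent
    chains with probability q and otherwise absorb both halves into
    complex clusters.  Exceeding ``population_cap`` bacteria stops the
    run with the ``truncated`` flag set.
    """
    if params.variant == "fixed_time":
        raise ValueError("use simulate_fixed_tau for the fixed_time variant")
    rng = np.random.default_rng(seed)
    state = SimState(rng_seed=seed) if initial is None else initial
    state.rng_seed = seed
    checkpoints: list[tuple[float, dict[int, int]]] = []
    pending = (
        [] if checkpoint_times is None
        else sorted(float(t) for t in checkpoint_times)
    )

    while True:
        classes = [(m, c) for m, c in state.chains.items() if c > 0]
        props = []
        for m, c in classes:
            rep, brk, loss = _chain_propensities(m, params)
            props.append((c * rep, c * brk, c * loss))
        total = float(sum(sum(p) for p in props))
        if total <= 0.0:
            state.time = t_end
            break
        dt = rng.exponential(1.0 / total)
        t_next = state.time + dt
        while pending and pending[0] <= min(t_next, t_end):
            checkpoints.append((pending[0], dict(state.chains)))
            pending.pop(0)
        if t_next >= t_end:
            state.time = t_end
            break
        state.time = t_next
        # pick the event class and type
        u = rng.random() * total
        for (m, _c), (a_rep, a_brk, a_loss) in zip(classes, props):
            if u < a_rep:
                _apply_replication(state, m, params, rng)
                break
            u -= a_rep
            if u < a_brk:
                _apply_break(state, m, params, rng)
                break
            u -= a_brk
            if u < a_loss:
                state.chains[m] -= 1  # washed out of the system
                break
            u -= a_loss
        if state.total_bacteria > population_cap:
            state.truncated = True
            break
    for t in pending:
        if t <= state.time:
            checkpoints.append((t, dict(state.chains)))
    hist = state.histogram(variant=params.variant, truncated=state.truncated)
    return SimResult(state, hist, checkpoints)


def _fragment_one(
    m: int, tau: float, alpha: float, rng
) -> tuple[int, int, int]:
    """Fragment one chain of length m for time tau (q = 0 rules).

    Returns (surviving_length, free_released, absorbed_bacteria);
    surviving_length 0 means the chain was absorbed into a complex
    cluster (or fully dissolved into free bacteria when it reached 2).
    """
    t = 0.0
    freed = 0
    while m >= 2:
        rate = (m - 1) * alpha
        t += rng.exponential(1.0 / rate)
        if t >= tau:
            return m, freed, 0
        if m == 2:
            return 0, freed + 2, 0
        link = int(rng.integers(1, m))
        if link == 1 or link == m - 1:
            freed += 1
            m -= 1
        else:
            return 0, freed, m
    return m, freed, 0


def simulate_fixed_tau(
    params: ModelParams,
    initial: SimState | None = None,
    n_generations: int = 8,
    seed: int | None = None,
    population_cap: int = 10**6,
) -> SimResult:
    """Stochastic fixed-replication-time dynamics over whole divisions.

    Every chain doubles its length synchronously at each division, then
    fragments for ``tau`` with an exponential clock per link (outermost
    breaks free one bacterium, inner breaks absorb the whole chain into a
    complex cluster).  The population is recorded just before divisions,
    and freed bacteria participate as length-1 chains from the next
    division on.  Checkpoints hold the chain counter before each
    division.
    """
    if params.variant != "fixed_time":
        raise ValueError(f"expected fixed_time variant, got {params.variant!r}")
    rng = np.random.default_rng(seed)
    state = SimState(rng_seed=seed) if initial is None else initial
    state.rng_seed = seed
    checkpoints: list[tuple[float, dict[int, int]]] = []
    for gen in range(n_generations):
        new_counts: dict[int, int] = {}
        for m, c in state.chains.items():
            born = 2 * m
            for _ in range(c):
                survives, freed, absorbed = _fragment_one(
                    born, params.tau, params.alpha, rng
                )
                if survives:
                    new_counts[survives] = new_counts.get(survives, 0) + 1
                if freed:
                    new_counts[1] = new_counts.get(1, 0) + freed
                state.complex_cluster_bacteria += absorbed
        state.chains = new_counts
        state.time += params.tau
        checkpoints.append((state.time, dict(state.chains)))
        if state.total_bacteria > population_cap:
            state.truncated = True
            break
    hist = state.histogram(variant="fixed_time", truncated=state.truncated)
    return SimResult(state, hist, checkpoints)


def sample_histogram(
    distribution: np.ndarray,
    n_chains: int,
    seed: int | None = None,
    lengths: np.ndarray | None = None,
) -> ChainLengthHistogram:
    """Multinomial sample of ``n_chains`` chain lengths from proportions.

    ``distribution`` must be normalised; ``lengths`` defaults to
    1..len(distribution).
    """
    distribution = np.asarray(distribution, dtype=float)
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if np.any(distribution < 0) or abs(distribution.sum() - 1.0) > 1e-8:
        raise ValueError("distribution must be nonnegative and sum to 1")
    if lengths is None:
        lengths = np.arange(1, distribution.size + 1)
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size != distribution.size:
        raise ValueError("lengths and distribution must have equal size")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_chains, distribution / distribution.sum())
    counts = {int(l): int(c) for l, c in zip(lengths, draws) if c > 0}
    return ChainLengthHistogram(counts, {"seed": seed, "n_chains": n_chains})
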