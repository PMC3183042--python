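"""Monte Carlo oracle for the two-lineage chain and synthetic-pattern generator.

The simulator replays the generative model directly: each generation,
backward in time, each of the two lineages migrates with its per-lineage
Bernoulli probability (migration sampled before coalescence), and a pair
cohabiting a population afterwards coalesces with the locus's pairwise
Bernoulli probability.  Unlike the transition-matrix computation it does
not drop simultaneous events, so it is an independent check on the
first-order chain (the discrepancy is second order in the per-generation
probabilities).

Because the two populations are exchangeable, only whether the lineages
cohabit matters: a pair in different populations is rejoined when exactly
one lineage migrates, with per-generation probability
``q = 2*m*(1-m)``, and a cohabiting pair is likewise separated with
probability ``q`` before the coalescence draw.  The default engine
exploits this to jump between events with exact geometric waiting times —
a faithful, much faster realization of the same per-generation process.
A literal generation-by-generation engine is kept for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import Branch, ObservedPattern, PatternRecord
from .markers import (
    ConventionConfig,
    DemographicScenario,
    MarkerClass,
    chain_params_for,
)

__all__ = [
    "SimulationConfig",
    "simulate_two_lineages",
    "simulate_pattern",
]


@dataclass(frozen=True)
class SimulationConfig:
    scenario: DemographicScenario
    conventions: ConventionConfig = ConventionConfig()
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _short_outcomes_events(
    mig_prob: float, coal_prob: float, n_gen: int, n_rep: int,
    rng: np.random.Generator, rule: str,
) -> np.ndarray:
    """Event-driven exact simulation; returns a boolean short-branch array."""
    q = 2.0 * mig_prob * (1.0 - mig_prob)  # per-generation cohabitation toggle
    # states: 0 coalesced, 1 different pops, 2 same pop
    state = np.ones(n_rep, dtype=np.int8)
    t = np.zeros(n_rep, dtype=np.int64)
    active = np.ones(n_rep, dtype=bool)
    if q == 0.0:
        active[:] = False  # isolated pair never rejoins
    while np.any(active):
        diff = active & (state == 1)
        if np.any(diff):
            wait = rng.geometric(q, size=int(diff.sum()))
            tt = t[diff] + wait
            landed = tt <= n_gen
            idx = np.flatnonzero(diff)
            t[idx] = np.minimum(tt, n_gen)
            # migration precedes coalescence within a generation, so a pair
            # rejoined at generation tt already faces a coalescence draw there
            idx_landed = idx[landed]
            arrive_coal = rng.random(idx_landed.size) < coal_prob
            state[idx_landed[arrive_coal]] = 0
            active[idx_landed[arrive_coal]] = False
            state[idx_landed[~arrive_coal]] = 2
            active[idx[~landed]] = False
        same = active & (state == 2)
        if np.any(same):
            r = q + (1.0 - q) * coal_prob  # any event in a cohabiting generation
            n_same = int(same.sum())
            wait = rng.geometric(r, size=n_same)
            tt = t[same] + wait
            landed = tt <= n_gen
            is_coal = rng.random(n_same) < (1.0 - q) * coal_prob / r
            idx = np.flatnonzero(same)
            t[idx] = np.minimum(tt, n_gen)
            state[idx[landed & is_coal]] = 0
            active[idx[landed & is_coal]] = False
            state[idx[landed & ~is_coal]] = 1
            active[idx[~landed]] = False
    if rule == "coalesced_or_same_pop":
        return state != 1
    return state == 0


def _short_outcomes_generations(
    mig_prob: float, coal_prob: float, n_gen: int, n_rep: int,
    rng: np.random.Generator, rule: str,
) -> np.ndarray:
    """Literal per-generation engine: two Bernoulli migration draws per
    generation then a coalescence draw when cohabiting.  O(n_gen) per
    replicate; used to validate the event-driven engine at small sizes."""
    coalesced = np.zeros(n_rep, dtype=bool)
    same_pop = np.zeros(n_rep, dtype=bool)
    for _ in range(n_gen):
        open_pairs = ~coalesced
        moved_a = rng.random(n_rep) < mig_prob
        moved_b = rng.random(n_rep) < mig_prob
        toggle = open_pairs & (moved_a ^ moved_b)
        same_pop ^= toggle
        coal_draw = rng.random(n_rep) < coal_prob
        newly = open_pairs & same_pop & coal_draw
        coalesced |= newly
        same_pop &= ~newly
    if rule == "coalesced_or_same_pop":
        return coalesced | same_pop
    return coalesced


def simulate_two_lineages(
    marker: MarkerClass,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    engine: str = "events",
) -> np.ndarray:
    """Simulate branch outcomes for independent loci of one marker class.

    Returns an array of :class:`Branch` values of length
    ``config.n_replicates``.  Reproducible given ``config.seed`` (or an
    explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = chain_params_for(marker, config.scenario, config.conventions)
    engines = {"events": _short_outcomes_events, "generations": _short_outcomes_generations}
    try:
        fn = engines[engine]
    except KeyError:
        raise ValueError(f"unknown engine {engine!r}") from None
    short = fn(
        params.mig_prob,
        params.coal_prob,
        params.n_generations,
        config.n_replicates,
        rng,
        config.conventions.short_branch_rule,
    )
    return np.where(short, Branch.SHORT, Branch.LONG)


def simulate_pattern(
    counts: dict[MarkerClass, int],
    config: SimulationConfig,
) -> tuple[ObservedPattern, dict]:
    """Draw a synthetic incongruence pattern of independent unlinked loci.

    ``counts`` gives the number of loci per marker class.  Each marker's
    loci are drawn from an independent substream spawned from the root
    seed, so per-marker results do not depend on dict order.  Returns the
    pattern plus a provenance dict recording the true parameters, seed and
    conventions.
    """
    for marker, n in counts.items():
        if n < 0:
            raise ValueError(f"negative locus count for {marker}")
    # fixed spawn order by marker class, independent of dict order
    ordered = [m for m in MarkerClass if counts.get(m, 0) > 0]
    if not ordered:
        raise ValueError("pattern must contain at least one locus")
    streams = np.random.SeedSequence(config.seed).spawn(len(MarkerClass))
    stream_by_marker = dict(zip(MarkerClass, streams))
    records = []
    for marker in ordered:
        n = counts[marker]
        sub = SimulationConfig(
            scenario=config.scenario,
            conventions=config.conventions,
            n_replicates=n,
            seed=config.seed,
        )
        outcomes = simulate_two_lineages(
            marker, sub, rng=np.random.default_rng(stream_by_marker[marker])
        )
        n_short = int(np.sum(outcomes == Branch.SHORT))
        if n_short:
            records.append(PatternRecord(marker, Branch.SHORT, n_short))
        if n - n_short:
            records.append(PatternRecord(marker, Branch.LONG, n - n_short))
    provenance = {
        "true_scaled_total_mig": config.scenario.scaled_total_mig,
        "true_female_fraction": config.scenario.female_fraction,
        "duration": config.scenario.duration,
        "N": config.scenario.N,
        "seed": config.seed,
        "conventions": {
            "ne_convention": config.conventions.ne_convention,
            "short_branch_rule": config.conventions.short_branch_rule,
        },
        "counts": {m.value: int(counts.get(m, 0)) for m in MarkerClass},
    }
    return ObservedPattern(tuple(records)), provenance
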