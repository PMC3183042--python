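"""Two-lineage structured-coalescent Markov chain with symmetric migration.

Tracks one sampled lineage per population backward in time through a window
of secondary contact between two populations of diploid size ``N``.  The
pair of lineages is always in one of three states: already coalesced,
in different populations, or cohabiting the same population.  Per
generation each lineage migrates with a small probability and a cohabiting
pair coalesces with probability ``1/(2*Ne)`` for the locus; probabilities of
two simultaneous events are dropped (first-order chain).

The module provides the discrete per-generation transition matrix, its
iteration (by matrix power), and the continuous-time limit of the chain as
an independent analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.linalg import expm

__all__ = [
    "LineageState",
    "StateDistribution",
    "ChainParams",
    "build_transition_matrix",
    "evolve",
    "evolve_stepwise",
    "matrix_power_batch",
    "ctmc_rate_matrix",
    "ctmc_oracle",
]

_NORM_TOL = 1e-12


class LineageState(IntEnum):
    """The three states of a pair of sampled lineages."""

    COALESCED = 0
    DIFFERENT_POPS = 1
    SAME_POP = 2


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector over the three lineage states at a given generation.

    Parameters
    ----------
    probs:
        Length-3 array indexed by :class:`LineageState`; entries in [0, 1]
        summing to 1 within 1e-12.
    generation:
        Backward-counted generation index (0 = end of the contact window).
    """

    probs: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (3,):
            raise ValueError(f"state distribution must have 3 entries, got shape {probs.shape}")
        if np.any(probs < -_NORM_TOL) or np.any(probs > 1 + _NORM_TOL):
            raise ValueError(f"state probabilities outside [0, 1]: {probs}")
        if abs(probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"state probabilities sum to {probs.sum()!r}, not 1")
        if self.generation < 0:
            raise ValueError("generation must be nonnegative")
        object.__setattr__(self, "probs", probs)

    def __getitem__(self, state: LineageState) -> float:
        return float(self.probs[state])


@dataclass(frozen=True)
class ChainParams:
    """Per-generation parameters of the two-lineage chain.

    Parameters
    ----------
    coal_prob:
        Probability that a cohabiting pair coalesces in one generation,
        ``1/(2*Ne)`` for the locus; in (0, 1).
    mig_prob:
        Per-lineage per-generation migration probability; in [0, 1).
    n_generations:
        Number of generations in the contact window (``2*N*T`` after
        discretization); at least 1.
    """

    coal_prob: float
    mig_prob: float
    n_generations: int

    def __post_init__(self) -> None:
        if not 0.0 < self.coal_prob < 1.0:
            raise ValueError(f"coal_prob must be in (0, 1), got {self.coal_prob}")
        if not 0.0 <= self.mig_prob < 1.0:
            raise ValueError(f"mig_prob must be in [0, 1), got {self.mig_prob}")
        if self.coal_prob + 2.0 * self.mig_prob >= 1.0:
            raise ValueError(
                "coal_prob + 2*mig_prob >= 1: discretization too coarse; increase N"
            )
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


def build_transition_matrix(params: ChainParams) -> np.ndarray:
    """Per-generation transition matrix of the two-lineage chain.

    Rows are from-states, columns to-states, ordered as
    (COALESCED, DIFFERENT_POPS, SAME_POP).  COALESCED is absorbing; a pair in
    different populations is rejoined when either lineage migrates
    (probability ``2*mig_prob``); a cohabiting pair coalesces with
    ``coal_prob`` or is separated by a single migration; simultaneous events
    are ignored (first-order chain).
    """
    c, m2 = params.coal_prob, 2.0 * params.mig_prob
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0 - m2, m2],
            [c, m2, 1.0 - m2 - c],
        ]
    )


def matrix_power_batch(mats: np.ndarray, n: int) -> np.ndarray:
    """``mats[i] ** n`` for a stack of square matrices, by repeated squaring.

    ``mats`` has shape (..., k, k); ``n`` is a nonnegative integer shared by
    the whole stack.
    """
    if n < 0:
        raise ValueError("power must be nonnegative")
    k = mats.shape[-1]
    result = np.broadcast_to(np.eye(k), mats.shape).copy()
    base = np.array(mats, dtype=float)
    while n:
        if n & 1:
            result = result @ base
        n >>= 1
        if n:
            base = base @ base
    return result


def evolve(
    initial: StateDistribution, matrix: np.ndarray, n_generations: int
) -> StateDistribution:
    """Advance a state distribution ``n_generations`` steps through the chain.

    Computed as a row-vector times matrix power (exponentiation by squaring);
    algebraically identical to iterated left-multiplication.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be nonnegative")
    probs = initial.probs @ matrix_power_batch(matrix, n_generations)
    # many squaring steps accumulate float round-off in the row sums;
    # renormalize it away, but refuse anything beyond round-off scale
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"matrix power lost normalization: sum={total!r}")
    return StateDistribution(probs / total, generation=initial.generation + n_generations)


def evolve_stepwise(
    initial: StateDistribution, matrix: np.ndarray, n_generations: int
) -> StateDistribution:
    """Plain one-generation-at-a-time iteration; debug path for `evolve`."""
    probs = initial.probs.copy()
    for _ in range(n_generations):
        probs = probs @ matrix
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"iteration lost normalization: sum={total!r}")
    return StateDistribution(probs / total, generation=initial.generation + n_generations)


def ctmc_rate_matrix(scaled_mig: float, scaled_coal: float) -> np.ndarray:
    """Rate matrix of the continuum limit, time in units of 2N generations.

    ``scaled_mig`` is the per-lineage migration rate ``2N*mig_prob`` and
    ``scaled_coal`` the pairwise coalescence rate ``2N*coal_prob``.
    """
    M2, c = 2.0 * scaled_mig, scaled_coal
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, -M2, M2],
            [c, M2, -M2 - c],
        ]
    )


def ctmc_oracle(
    scaled_mig: float, scaled_coal: float, duration: float
) -> StateDistribution:
    """Exact state distribution of the continuous-time chain.

    Starts from DIFFERENT_POPS and runs for ``duration`` units of 2N
    generations; solved by matrix exponential of the rate matrix, so it is
    independent of any discretization ``N``.  Serves as an analytic oracle
    for :func:`evolve`.
    """
    if scaled_mig < 0:
        raise ValueError("scaled_mig must be >= 0")
    if scaled_coal <= 0:
        raise ValueError("scaled_coal must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    Q = ctmc_rate_matrix(scaled_mig, scaled_coal)
    probs = np.array([0.0, 1.0, 0.0]) @ expm(Q * duration)
    # expm can leave tiny negative round-off in absorbing-state problems
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum()
    return StateDistribution(probs, generation=0)
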