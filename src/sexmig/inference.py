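"""Multi-locus likelihood surfaces and the equal-migration-rate test.

An observed incongruence pattern — counts of unlinked loci per marker class
showing a short (introgressed) or long branch — is treated as a product of
independent Bernoulli observations.  Its log-likelihood is scanned over a
grid of (2Nm, p) where 2Nm is the scaled total migration rate and
p = m_F/(m_F+m_M) the female fraction of migrants.  The maximum-likelihood
estimate is the grid argmax; the 95% confidence region is the set of grid
points whose likelihood ratio against the maximum falls below the
chi-square(1 df) quantile; and the sexually-equal-migration null (p = 1/2)
is tested by the profile likelihood ratio along the p = 1/2 grid line,
which rejects exactly when the confidence region excludes that line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.stats import chi2

from .chain import matrix_power_batch
from .markers import (
    ConventionConfig,
    MarkerClass,
    coal_prob_for,
    migration_weight,
)

__all__ = [
    "Branch",
    "PatternRecord",
    "ObservedPattern",
    "ParameterGrid",
    "LikelihoodSurface",
    "TestResult",
    "MinLociResult",
    "DegeneratePatternError",
    "branch_probability_grid",
    "pattern_loglik",
    "likelihood_surface",
    "test_equal_migration",
    "min_loci_to_reject",
]


class Branch(str, Enum):
    SHORT = "short"
    LONG = "long"

    @classmethod
    def parse(cls, text: str) -> "Branch":
        token = str(text).strip().lower()
        if token in ("short", "s"):
            return cls.SHORT
        if token in ("long", "l"):
            return cls.LONG
        raise ValueError(f"unknown branch type {text!r} (use short or long)")


class DegeneratePatternError(ValueError):
    """The pattern has zero probability at every grid point."""


@dataclass(frozen=True)
class PatternRecord:
    marker: MarkerClass
    branch: Branch
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("record count must be >= 1")


@dataclass(frozen=True)
class ObservedPattern:
    """Counts of unlinked loci per (marker class, branch type)."""

    records: tuple[PatternRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("pattern must contain at least one record")
        keys = [(r.marker, r.branch) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("at most one record per (marker, branch) pair")
        object.__setattr__(self, "records", tuple(self.records))

    @classmethod
    def from_counts(cls, records: list[tuple[str, str, int]]) -> "ObservedPattern":
        """Build from (marker, branch, count) triples of strings/ints."""
        return cls(
            tuple(
                PatternRecord(MarkerClass.parse(m), Branch.parse(b), int(n))
                for m, b, n in records
            )
        )

    def with_record(self, marker: MarkerClass, branch: Branch, count: int) -> "ObservedPattern":
        """Copy of this pattern with one record added (or its count replaced)."""
        kept = tuple(
            r for r in self.records if not (r.marker == marker and r.branch == branch)
        )
        return ObservedPattern(kept + (PatternRecord(marker, branch, count),))


@dataclass(frozen=True)
class ParameterGrid:
    """Scan grid over (2Nm, p).

    Defaults: 201 log-spaced migration values on [0.01, 10] and p from 0 to
    1 in steps of 0.005 — fine enough that grid resolution does not move
    the test decision, and containing p = 0.5 exactly so the equal-rate
    line is a grid line.
    """

    mig_values: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.01, 10.0, 201)
    )
    p_values: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 201))

    def __post_init__(self) -> None:
        mig = np.asarray(self.mig_values, dtype=float)
        p = np.asarray(self.p_values, dtype=float)
        if mig.ndim != 1 or np.any(np.diff(mig) <= 0) or np.any(mig <= 0):
            raise ValueError("mig_values must be strictly increasing and > 0")
        if p.ndim != 1 or np.any(np.diff(p) <= 0) or p[0] < 0 or p[-1] > 1:
            raise ValueError("p_values must be strictly increasing within [0, 1]")
        if not np.any(p == 0.5):
            raise ValueError("p_values must contain 0.5 exactly (the null line)")
        object.__setattr__(self, "mig_values", mig)
        object.__setattr__(self, "p_values", p)

    @property
    def equal_rate_index(self) -> int:
        return int(np.flatnonzero(self.p_values == 0.5)[0])

    def _key(self) -> tuple:
        return (tuple(self.mig_values.tolist()), tuple(self.p_values.tolist()))


@lru_cache(maxsize=64)
def _short_prob_grid_cached(
    marker: MarkerClass,
    mig_key: tuple,
    p_key: tuple,
    duration: float,
    N: int,
    conventions: ConventionConfig,
) -> np.ndarray:
    mig = np.array(mig_key)[:, None]  # (n_mig, 1)
    p = np.array(p_key)[None, :]  # (1, n_p)
    m = mig / (2.0 * N)
    m_F, m_M = 2.0 * m * p, 2.0 * m * (1.0 - p)
    mig_prob = migration_weight(marker, m_F, m_M)  # broadcasts to (n_mig, n_p)
    mig_prob = np.broadcast_to(mig_prob, (mig.size, p.size))
    coal = coal_prob_for(marker, N, conventions)
    if np.any(coal + 2.0 * mig_prob >= 1.0):
        raise ValueError(
            "coal_prob + 2*mig_prob >= 1 somewhere on the grid; increase N"
        )
    n_gen = int(round(2.0 * N * duration))
    mats = np.zeros((mig.size, p.size, 3, 3))
    mats[..., 0, 0] = 1.0
    mats[..., 1, 1] = 1.0 - 2.0 * mig_prob
    mats[..., 1, 2] = 2.0 * mig_prob
    mats[..., 2, 0] = coal
    mats[..., 2, 1] = 2.0 * mig_prob
    mats[..., 2, 2] = 1.0 - 2.0 * mig_prob - coal
    powered = matrix_power_batch(mats, n_gen)
    # start state is DIFFERENT_POPS: the relevant row of the matrix power
    p_short = powered[..., 1, 0]
    if conventions.short_branch_rule == "coalesced_or_same_pop":
        p_short = p_short + powered[..., 1, 2]
    p_short = np.clip(p_short, 0.0, 1.0)
    p_short.setflags(write=False)
    return p_short


def branch_probability_grid(
    marker: MarkerClass,
    grid: ParameterGrid,
    duration: float = 1.0,
    N: int = 1000,
    conventions: ConventionConfig = ConventionConfig(),
) -> np.ndarray:
    """P(short branch) for one marker over the whole (2Nm, p) grid.

    Shape (len(mig_values), len(p_values)).  Cached: surfaces for many
    patterns on the same grid reuse the same marker grids.
    """
    mig_key, p_key = grid._key()
    return _short_prob_grid_cached(marker, mig_key, p_key, float(duration), int(N), conventions)


def _record_loglik_grid(record: PatternRecord, grid, duration, N, conventions) -> np.ndarray:
    p_short = branch_probability_grid(record.marker, grid, duration, N, conventions)
    prob = p_short if record.branch is Branch.SHORT else 1.0 - p_short
    with np.errstate(divide="ignore"):
        return record.count * np.log(prob)


def pattern_loglik(
    pattern: ObservedPattern,
    scenario,
    conventions: ConventionConfig = ConventionConfig(),
) -> float:
    """Log-probability of a pattern at one point in parameter space.

    Loci are unlinked, hence independent: the log-likelihood is the sum
    over records of count * log(branch probability).  Returns -inf when any
    record is impossible (a value, not an error).
    """
    from .markers import branch_probabilities

    total = 0.0
    for rec in pattern.records:
        bp = branch_probabilities(rec.marker, scenario, conventions)
        prob = bp.p_short if rec.branch is Branch.SHORT else bp.p_long
        with np.errstate(divide="ignore"):
            total += rec.count * float(np.log(prob))
    return total


@dataclass(frozen=True)
class LikelihoodSurface:
    """Log-likelihood of a pattern over the grid, with MLE and CI region."""

    grid: ParameterGrid
    loglik: np.ndarray
    alpha: float
    critical_value: float

    @property
    def max_loglik(self) -> float:
        return float(np.max(self.loglik))

    @property
    def mle_indices(self) -> list[tuple[int, int]]:
        """All argmax grid points (ties reported, not broken)."""
        ii, jj = np.nonzero(self.loglik == self.max_loglik)
        return list(zip(ii.tolist(), jj.tolist()))

    @property
    def mle(self) -> list[tuple[float, float]]:
        """(2Nm, p) coordinates of every argmax point."""
        return [
            (float(self.grid.mig_values[i]), float(self.grid.p_values[j]))
            for i, j in self.mle_indices
        ]

    @property
    def ci_mask(self) -> np.ndarray:
        """Grid points inside the (1-alpha) likelihood-ratio region."""
        with np.errstate(invalid="ignore"):
            return 2.0 * (self.max_loglik - self.loglik) <= self.critical_value

    @property
    def lr_statistic_equal_rates(self) -> float:
        """Profile LR statistic against the p = 1/2 line."""
        profile = np.max(self.loglik[:, self.grid.equal_rate_index])
        return float(2.0 * (self.max_loglik - profile))

    @property
    def touches_boundary(self) -> bool:
        """Whether the MLE or CI region touches the migration-grid edge."""
        mask = self.ci_mask
        return bool(mask[0, :].any() or mask[-1, :].any())


@dataclass(frozen=True)
class TestResult:
    """Outcome of the test of sexually equal migration rates (p = 1/2)."""

    reject_equal_rates: bool
    lr_statistic: float
    critical_value: float
    alpha: float
    mle: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "reject_equal_rates": self.reject_equal_rates,
            "lr_statistic": self.lr_statistic,
            "critical_value": self.critical_value,
            "alpha": self.alpha,
            "mle": [list(pt) for pt in self.mle],
        }


def likelihood_surface(
    pattern: ObservedPattern,
    grid: ParameterGrid | None = None,
    duration: float = 1.0,
    N: int = 1000,
    conventions: ConventionConfig = ConventionConfig(),
    alpha: float = 0.05,
) -> LikelihoodSurface:
    """Scan the pattern's log-likelihood over the whole grid.

    Raises :class:`DegeneratePatternError` if the pattern is impossible at
    every grid point; warns if the CI region touches the migration-grid
    boundary (the scan range may be truncating it).
    """
    grid = grid if grid is not None else ParameterGrid()
    loglik = np.zeros((grid.mig_values.size, grid.p_values.size))
    for rec in pattern.records:
        rec_ll = _record_loglik_grid(rec, grid, duration, N, conventions)
        if np.all(np.isneginf(rec_ll)):
            raise DegeneratePatternError(
                f"record ({rec.marker.value}, {rec.branch.value}, x{rec.count}) "
                "has zero probability at every grid point"
            )
        loglik = loglik + rec_ll
    if np.all(np.isneginf(loglik)):
        raise DegeneratePatternError("pattern has zero probability at every grid point")
    surface = LikelihoodSurface(
        grid=grid,
        loglik=loglik,
        alpha=alpha,
        critical_value=float(chi2.ppf(1.0 - alpha, df=1)),
    )
    if surface.touches_boundary:
        warnings.warn(
            "95% CI region touches the 2Nm grid boundary; consider widening "
            "the migration scan range",
            stacklevel=2,
        )
    return surface


def _result_from_surface(surface: LikelihoodSurface) -> TestResult:
    lr = surface.lr_statistic_equal_rates
    return TestResult(
        reject_equal_rates=bool(lr > surface.critical_value),
        lr_statistic=lr,
        critical_value=surface.critical_value,
        alpha=surface.alpha,
        mle=surface.mle,
    )


def test_equal_migration(
    pattern: ObservedPattern,
    grid: ParameterGrid | None = None,
    duration: float = 1.0,
    N: int = 1000,
    conventions: ConventionConfig = ConventionConfig(),
    alpha: float = 0.05,
) -> TestResult:
    """Profile likelihood-ratio test of sexually equal migration (p = 1/2).

    Rejects exactly when the (1-alpha) confidence region contains no grid
    point on the p = 1/2 line.
    """
    surface = likelihood_surface(pattern, grid, duration, N, conventions, alpha)
    return _result_from_surface(surface)


@dataclass(frozen=True)
class MinLociResult:
    """Result of scanning the count of one record upward until rejection."""

    min_count: int | None
    max_n: int
    lr_trajectory: list[float]

    def __str__(self) -> str:
        if self.min_count is None:
            return f"none <= {self.max_n}"
        return str(self.min_count)


def min_loci_to_reject(
    base: ObservedPattern | None,
    increment: tuple[MarkerClass, Branch],
    grid: ParameterGrid | None = None,
    duration: float = 1.0,
    N: int = 1000,
    conventions: ConventionConfig = ConventionConfig(),
    alpha: float = 0.05,
    max_n: int = 100,
) -> MinLociResult:
    """Smallest count of the incremented record at which the null is rejected.

    Log-likelihood is linear in per-record counts, so the base surface and
    the single-locus increment surface are computed once and each candidate
    count only re-reduces their weighted sum.  Returns ``min_count=None``
    if no count up to ``max_n`` rejects.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    grid = grid if grid is not None else ParameterGrid()
    marker, branch = increment
    critical = float(chi2.ppf(1.0 - alpha, df=1))

    base_ll = np.zeros((grid.mig_values.size, grid.p_values.size))
    if base is not None:
        for rec in base.records:
            if rec.marker == marker and rec.branch == branch:
                raise ValueError("incremented record must not appear in the base pattern")
            base_ll = base_ll + _record_loglik_grid(rec, grid, duration, N, conventions)
    inc_ll = _record_loglik_grid(
        PatternRecord(marker, branch, 1), grid, duration, N, conventions
    )

    eq_col = grid.equal_rate_index
    trajectory: list[float] = []
    min_count = None
    for k in range(1, max_n + 1):
        ll = base_ll + k * inc_ll
        lr = float(2.0 * (np.max(ll) - np.max(ll[:, eq_col])))
        trajectory.append(lr)
        if min_count is None and lr > critical:
            min_count = k
            break
    return MinLociResult(min_count=min_count, max_n=max_n, lr_trajectory=trajectory)
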