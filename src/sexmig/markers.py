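"""Marker classes and their demographic parameterization.

Maps the four mammalian inheritance systems — autosomal, X-linked, Y-linked
and mitochondrial — onto the two-lineage chain.  Each marker class differs
in two ways: its effective population size (which sets the per-generation
coalescence probability) and which sex's migration moves its copies (which
sets the per-lineage migration probability as a function of the female and
male per-capita migration rates m_F and m_M).

Conventions
-----------
Two points are genuinely ambiguous in the underlying model and are exposed
as explicit configuration rather than silently chosen:

* ``ne_convention`` — the mito/Y coalescence probability.  A diploid
  population of size N with equal sex ratio carries N/2 transmitting
  mitochondrial or Y copies, so two cohabiting lineages coalesce with
  probability 2/N per generation (``copy_count``, the default; this is the
  convention under which the reference decision thresholds reproduce).
  Reading "effective size N/2" through the diploid formula 1/(2*Ne)
  instead gives 1/N (``paper_literal``).  The X chromosome has 3N/2
  copies, i.e. Ne = 3N/4 and coalescence probability 2/(3N), identical
  under both readings.
* ``short_branch_rule`` — how the end state of the contact window maps to
  an observed branch length.  ``coalesced_or_same_pop`` (default) counts a
  pair that ends cohabiting as introgressed, since with a long subsequent
  isolation it must coalesce through the migrant lineage;
  ``coalesced_only`` is the conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .chain import ChainParams, LineageState, StateDistribution, build_transition_matrix, evolve

__all__ = [
    "MarkerClass",
    "DemographicScenario",
    "ConventionConfig",
    "BranchProbabilities",
    "NE_SCALE",
    "migration_weight",
    "coal_prob_for",
    "chain_params_for",
    "branch_probabilities",
    "effective_rates_from_f1_viability",
]


class MarkerClass(str, Enum):
    """Inheritance system of a locus."""

    AUTOSOME = "A"
    X = "X"
    Y = "Y"
    MITO = "MT"

    @classmethod
    def parse(cls, text: str) -> "MarkerClass":
        token = str(text).strip().upper()
        aliases = {
            "A": cls.AUTOSOME, "AUTOSOME": cls.AUTOSOME, "AUT": cls.AUTOSOME,
            "X": cls.X, "Y": cls.Y,
            "MT": cls.MITO, "MITO": cls.MITO, "MTDNA": cls.MITO, "M": cls.MITO,
        }
        try:
            return aliases[token]
        except KeyError:
            raise ValueError(f"unknown marker class {text!r} (use A, X, Y or MT)") from None


#: Marker effective size as a multiple of the diploid population size N,
#: under the paper_literal convention.
NE_SCALE = {
    MarkerClass.AUTOSOME: 1.0,
    MarkerClass.X: 0.75,
    MarkerClass.Y: 0.5,
    MarkerClass.MITO: 0.5,
}


@dataclass(frozen=True)
class DemographicScenario:
    """Secondary-contact scenario between two populations of diploid size N.

    Parameters
    ----------
    scaled_total_mig:
        2Nm with m = (m_F + m_M)/2 the sex-averaged per-capita migration
        rate; the expected number of migrant autosomal copies per
        generation. >= 0.
    female_fraction:
        p = m_F / (m_F + m_M), in [0, 1]; 0.5 is the sexually equal null.
    duration:
        T, length of the contact window in units of 2N generations.
    N:
        Diploid per-population size used to discretize the chain.
    """

    scaled_total_mig: float
    female_fraction: float = 0.5
    duration: float = 1.0
    N: int = 1000

    def __post_init__(self) -> None:
        if self.scaled_total_mig < 0:
            raise ValueError("scaled_total_mig (2Nm) must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.N < 1:
            raise ValueError("N must be a positive integer")

    @property
    def m(self) -> float:
        """Sex-averaged per-capita per-generation migration rate."""
        return self.scaled_total_mig / (2.0 * self.N)

    @property
    def m_female(self) -> float:
        return 2.0 * self.m * self.female_fraction

    @property
    def m_male(self) -> float:
        return 2.0 * self.m * (1.0 - self.female_fraction)

    @property
    def n_generations(self) -> int:
        return int(round(2.0 * self.N * self.duration))


@dataclass(frozen=True)
class ConventionConfig:
    """Resolution of the two model ambiguities (see module docstring)."""

    ne_convention: str = "copy_count"
    short_branch_rule: str = "coalesced_or_same_pop"

    _NE_CHOICES = ("paper_literal", "copy_count")
    _RULE_CHOICES = ("coalesced_or_same_pop", "coalesced_only")

    def __post_init__(self) -> None:
        if self.ne_convention not in self._NE_CHOICES:
            raise ValueError(f"ne_convention must be one of {self._NE_CHOICES}")
        if self.short_branch_rule not in self._RULE_CHOICES:
            raise ValueError(f"short_branch_rule must be one of {self._RULE_CHOICES}")


@dataclass(frozen=True)
class BranchProbabilities:
    """Probability of observing a short (introgressed) vs long branch."""

    p_short: float
    p_long: float

    def __post_init__(self) -> None:
        if abs(self.p_short + self.p_long - 1.0) > 1e-12:
            raise ValueError("p_short + p_long must equal 1")


def migration_weight(marker: MarkerClass, m_F: float, m_M: float) -> float:
    """Per-copy migration rate of a marker given sex-specific rates.

    One migrating female carries two X copies, one mitochondrial genome and
    no Y; one migrating male carries one X, one Y and no mitochondria; each
    carries two autosomal copies.
    """
    if marker is MarkerClass.AUTOSOME:
        return (m_F + m_M) / 2.0
    if marker is MarkerClass.MITO:
        return m_F
    if marker is MarkerClass.Y:
        return m_M
    if marker is MarkerClass.X:
        return (2.0 * m_F + m_M) / 3.0
    raise ValueError(f"unknown marker {marker!r}")


def coal_prob_for(marker: MarkerClass, N: int, conventions: ConventionConfig) -> float:
    """Per-generation coalescence probability 1/(2*Ne) for a cohabiting pair."""
    if conventions.ne_convention == "copy_count" and marker in (
        MarkerClass.Y,
        MarkerClass.MITO,
    ):
        # N/2 transmitting haploid copies -> pairwise coalescence prob 2/N
        return 2.0 / N
    return 1.0 / (2.0 * NE_SCALE[marker] * N)


def chain_params_for(
    marker: MarkerClass,
    scenario: DemographicScenario,
    conventions: ConventionConfig = ConventionConfig(),
) -> ChainParams:
    """Discretized chain parameters for one marker under one scenario."""
    return ChainParams(
        coal_prob=coal_prob_for(marker, scenario.N, conventions),
        mig_prob=migration_weight(marker, scenario.m_female, scenario.m_male),
        n_generations=scenario.n_generations,
    )


def branch_probabilities(
    marker: MarkerClass,
    scenario: DemographicScenario,
    conventions: ConventionConfig = ConventionConfig(),
) -> BranchProbabilities:
    """Short/long branch probabilities for one locus of a marker class.

    Runs the chain from both lineages in different populations through the
    whole contact window and classifies the end state by the active
    ``short_branch_rule``.
    """
    params = chain_params_for(marker, scenario, conventions)
    initial = StateDistribution([0.0, 1.0, 0.0])
    final = evolve(initial, build_transition_matrix(params), params.n_generations)
    p_short = final[LineageState.COALESCED]
    if conventions.short_branch_rule == "coalesced_or_same_pop":
        p_short += final[LineageState.SAME_POP]
    p_short = min(max(p_short, 0.0), 1.0)
    return BranchProbabilities(p_short=p_short, p_long=1.0 - p_short)


def effective_rates_from_f1_viability(
    m_F: float, m_M: float, female_survival: float, male_survival: float
) -> dict[MarkerClass, float]:
    """Effective per-marker migration rates under sex-specific F1 hybrid loss.

    A hybrid-incompatibility filter that kills or sterilizes a fraction of
    F1 hybrids of one sex (Haldane's rule, e.g. heterogametic females in
    birds and butterflies) is equivalent to a sex-biased migration model:
    only the surviving fraction of each sex transmits its copies.  With
    survivals ``s_F`` and ``s_M`` the effective rates are
    mito: s_F*m_F; Y: s_M*m_M; autosome: (s_F*m_F + s_M*m_M)/2;
    X: (2*s_F*m_F + s_M*m_M)/3.
    """
    if not 0.0 <= female_survival <= 1.0 or not 0.0 <= male_survival <= 1.0:
        raise ValueError("survival fractions must be in [0, 1]")
    eff_F, eff_M = female_survival * m_F, male_survival * m_M
    return {
        MarkerClass.MITO: eff_F,
        MarkerClass.Y: eff_M,
        MarkerClass.AUTOSOME: (eff_F + eff_M) / 2.0,
        MarkerClass.X: (2.0 * eff_F + eff_M) / 3.0,
    }
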