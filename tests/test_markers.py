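"""Marker parameterization: migration weights, coalescence conventions,
branch probabilities and their symmetries."""

import numpy as np
import pytest

from sexmig.markers import (
    ConventionConfig,
    DemographicScenario,
    MarkerClass,
    branch_probabilities,
    chain_params_for,
    coal_prob_for,
    effective_rates_from_f1_viability,
    migration_weight,
)

ALL_MARKERS = list(MarkerClass)


class TestChainParamsFor:
    def test_equal_sex_rates_give_identical_migration(self):
        sc = DemographicScenario(1.0, 0.5, 1.0, 1000)
        probs = {mk: chain_params_for(mk, sc).mig_prob for mk in ALL_MARKERS}
        assert len({round(v, 15) for v in probs.values()}) == 1
        assert probs[MarkerClass.AUTOSOME] == pytest.approx(sc.m)

    def test_all_female_migration_moves_no_y(self):
        sc = DemographicScenario(1.0, 1.0, 1.0, 1000)
        assert chain_params_for(MarkerClass.MITO, sc).mig_prob == pytest.approx(2 * sc.m)
        assert chain_params_for(MarkerClass.Y, sc).mig_prob == 0.0

    def test_female_migration_twice_the_effect_on_x(self):
        """One migrating female carries two X copies, a male one."""
        females = DemographicScenario(1.0, 1.0, 1.0, 1000)
        males = DemographicScenario(1.0, 0.0, 1.0, 1000)
        ratio = (
            chain_params_for(MarkerClass.X, females).mig_prob
            / chain_params_for(MarkerClass.X, males).mig_prob
        )
        assert ratio == pytest.approx(2.0, abs=1e-12)

    def test_generations_round_2NT(self):
        sc = DemographicScenario(1.0, 0.5, 1.5, 500)
        assert chain_params_for(MarkerClass.AUTOSOME, sc).n_generations == 1500

    @pytest.mark.parametrize(
        "marker,literal,copies",
        [
            (MarkerClass.AUTOSOME, 1 / 2000, 1 / 2000),
            (MarkerClass.X, 2 / 3000, 2 / 3000),
            (MarkerClass.Y, 1 / 1000, 2 / 1000),
            (MarkerClass.MITO, 1 / 1000, 2 / 1000),
        ],
    )
    def test_coalescence_conventions(self, marker, literal, copies):
        assert coal_prob_for(marker, 1000, ConventionConfig("paper_literal")) == pytest.approx(literal)
        assert coal_prob_for(marker, 1000, ConventionConfig("copy_count")) == pytest.approx(copies)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            ConventionConfig(ne_convention="folk")
        with pytest.raises(ValueError):
            ConventionConfig(short_branch_rule="whatever")


class TestBranchProbabilities:
    def test_no_migration_means_long_branch(self):
        sc = DemographicScenario(0.0, 0.5, 1.0, 1000)
        for mk in ALL_MARKERS:
            for rule in ("coalesced_or_same_pop", "coalesced_only"):
                bp = branch_probabilities(mk, sc, ConventionConfig(short_branch_rule=rule))
                assert bp.p_short == 0.0
                assert bp.p_long == 1.0

    def test_strong_migration_limit(self):
        """With 2Nm >> 1 the pair cohabits half the time, so coalescence
        proceeds at rate c/2 and P(coalesced by T=1) -> 1 - exp(-1/2)."""
        sc = DemographicScenario(500.0, 0.5, 1.0, 1000)
        bp = branch_probabilities(
            MarkerClass.AUTOSOME, sc, ConventionConfig(short_branch_rule="coalesced_only")
        )
        assert bp.p_short == pytest.approx(1 - np.exp(-0.5), abs=1e-3)

    def test_mirror_symmetry_swaps_mito_and_y(self, default_conventions):
        for two_nm in (0.2, 1.0, 3.0):
            for p in (0.0, 0.15, 0.7, 1.0):
                a = DemographicScenario(two_nm, p, 1.0, 1000)
                b = DemographicScenario(two_nm, 1.0 - p, 1.0, 1000)
                assert branch_probabilities(MarkerClass.MITO, a, default_conventions).p_short == pytest.approx(
                    branch_probabilities(MarkerClass.Y, b, default_conventions).p_short, abs=1e-12
                )
                assert branch_probabilities(MarkerClass.AUTOSOME, a, default_conventions).p_short == pytest.approx(
                    branch_probabilities(MarkerClass.AUTOSOME, b, default_conventions).p_short, abs=1e-12
                )

    def test_p_short_monotone_in_migration(self, default_conventions):
        grid = [0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
        for mk in ALL_MARKERS:
            for rule in ("coalesced_or_same_pop", "coalesced_only"):
                conv = ConventionConfig(default_conventions.ne_convention, rule)
                vals = [
                    branch_probabilities(mk, DemographicScenario(g, 0.7, 1.0, 1000), conv).p_short
                    for g in grid
                ]
                assert np.all(np.diff(vals) >= -1e-12), (mk, rule, vals)

    def test_p_short_monotone_in_female_fraction(self, default_conventions):
        ps = np.linspace(0.0, 1.0, 11)
        mito = [
            branch_probabilities(MarkerClass.MITO, DemographicScenario(1.0, p, 1.0, 1000), default_conventions).p_short
            for p in ps
        ]
        y = [
            branch_probabilities(MarkerClass.Y, DemographicScenario(1.0, p, 1.0, 1000), default_conventions).p_short
            for p in ps
        ]
        assert np.all(np.diff(mito) >= -1e-12)
        assert np.all(np.diff(y) <= 1e-12)

    def test_mito_equals_y_at_equal_rates(self, default_conventions):
        """With equal sex migration the two uniparental systems have the same
        effective size and migration, hence identical branch probabilities."""
        sc = DemographicScenario(1.7, 0.5, 1.0, 1000)
        assert branch_probabilities(MarkerClass.MITO, sc, default_conventions) == branch_probabilities(
            MarkerClass.Y, sc, default_conventions
        )


class TestF1ViabilityMapping:
    def test_full_survival_is_identity(self):
        rates = effective_rates_from_f1_viability(0.003, 0.001, 1.0, 1.0)
        assert rates[MarkerClass.MITO] == 0.003
        assert rates[MarkerClass.Y] == 0.001
        assert rates[MarkerClass.AUTOSOME] == pytest.approx(0.002)
        assert rates[MarkerClass.X] == pytest.approx(7 / 3000)

    def test_half_female_loss_gives_half_and_three_quarters(self):
        """Losing half the F1 females scales the mito rate by exactly 1/2
        and the autosomal rate by exactly 3/4."""
        m = 0.004
        rates = effective_rates_from_f1_viability(m, m, 0.5, 1.0)
        assert rates[MarkerClass.MITO] == m / 2
        assert rates[MarkerClass.AUTOSOME] == 3 * m / 4

    def test_equivalence_with_two_to_one_migration_ratio(self):
        """Half-viable F1 females with equal sex migration m is the same
        model as male:female migration 2:1 at total rate 3m/2."""
        m = 0.004
        filtered = effective_rates_from_f1_viability(m, m, 0.5, 1.0)
        m_F, m_M = m / 2, m
        direct = {mk: migration_weight(mk, m_F, m_M) for mk in ALL_MARKERS}
        for mk in ALL_MARKERS:
            assert filtered[mk] == pytest.approx(direct[mk], abs=1e-15)

    def test_survival_bounds_enforced(self):
        with pytest.raises(ValueError):
            effective_rates_from_f1_viability(0.001, 0.001, 1.5, 1.0)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scaled_total_mig": -1.0},
            {"scaled_total_mig": 1.0, "female_fraction": 1.2},
            {"scaled_total_mig": 1.0, "duration": 0.0},
            {"scaled_total_mig": 1.0, "N": 0},
        ],
    )
    def test_invalid_scenarios(self, kwargs):
        with pytest.raises(ValueError):
            DemographicScenario(**kwargs)
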