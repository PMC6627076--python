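"""Closed-form expectations and replication-round arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtburden import (
    BurdenModelConfig,
    ConfigurationError,
    TurnoverParams,
    UnsupportedConfigurationError,
    birth_burden_range,
    body_copy_estimate,
    config_for_age,
    default_config,
    divisions_to_cell_count,
    expected_burden,
    fixed,
    hsc_extra_rounds,
    log10_uniform,
    per_division_mutation_count,
    printed_integer,
    turnover_rounds,
    uniform,
)
from dataclasses import replace


class TestParamDistribution:
    def test_means(self):
        assert fixed(3.0).mean() == 3.0
        assert uniform(10.0, 80.0).mean() == 45.0
        assert log10_uniform(2.0, 4.0).mean() == 3.0  # mean of the exponent

    def test_geometric_mean(self):
        assert log10_uniform(2.0, 4.0).geometric_mean() == pytest.approx(1000.0)
        assert fixed(250.0).geometric_mean() == 250.0
        with pytest.raises(UnsupportedConfigurationError):
            uniform(100.0, 10_000.0).geometric_mean()

    def test_arithmetic_mean_of_log_uniform_exceeds_geometric(self):
        d = log10_uniform(2.0, 4.0)
        # E[10^L] = (10^4 - 10^2) / (2 ln 10)
        assert d.arithmetic_mean_natural() == pytest.approx(
            (1e4 - 1e2) / (2 * math.log(10))
        )
        assert d.arithmetic_mean_natural() > d.geometric_mean()

    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            uniform(5.0, 1.0)
        with pytest.raises(ConfigurationError):
            fixed(None)

    def test_samples_respect_support(self):
        rng = np.random.default_rng(0)
        v = log10_uniform(2.0, 4.0).sample(rng, 1000)
        assert v.min() >= 100.0 and v.max() <= 10_000.0


class TestExpectedBurden:
    def test_reference_proliferating_value(self):
        eb = expected_burden(default_config(True))
        assert eb == pytest.approx(16_569 * 1000 * 1.47e-7 * 416)
        assert printed_integer(eb) == 1013

    def test_mu_fixed_at_bounds(self):
        cfg = default_config(True)
        low = replace(cfg, polg_error_rate=fixed(2.8e-8))
        high = replace(cfg, polg_error_rate=fixed(5.6e-7))
        assert expected_burden(low) == pytest.approx(96.4979, abs=1e-3)
        assert printed_integer(expected_burden(low)) == 97
        assert printed_integer(expected_burden(high)) == 1930

    def test_non_proliferating_reference(self):
        # oracle: direct arithmetic, 16,569 * 1000 * 1.47e-7 * (45 + 280)
        eb = expected_burden(default_config(False))
        assert eb == pytest.approx(16_569 * 1000 * 1.47e-7 * 325)
        assert printed_integer(eb) == 792

    def test_zero_rounds_zero_burden(self):
        cfg = BurdenModelConfig(x1=fixed(0.0), x2=fixed(0.0), x3=fixed(0.0))
        assert expected_burden(cfg) == 0.0

    def test_uniform_copy_number_unsupported(self):
        cfg = replace(default_config(), copy_number=uniform(100.0, 10_000.0))
        with pytest.raises(UnsupportedConfigurationError):
            expected_burden(cfg)

    def test_proliferation_gap_is_x3_term(self):
        cfg = default_config(True)
        gap = expected_burden(cfg) - expected_burden(default_config(False))
        z = cfg.copy_number.geometric_mean()
        mu_eff = cfg.polg_error_rate.mean() / cfg.halving_factor
        assert gap == pytest.approx(cfg.genome_length_bp * z * mu_eff * 91.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(c=st.floats(0.1, 10.0))
    def test_linearity_in_each_factor(self, c):
        cfg = default_config(True)
        base = expected_burden(cfg)
        mu = cfg.polg_error_rate
        scaled_mu = replace(cfg, polg_error_rate=uniform(mu.lower * c, mu.upper * c))
        assert expected_burden(scaled_mu) == pytest.approx(c * base)
        scaled_z = replace(
            cfg, copy_number=log10_uniform(2.0 + math.log10(c), 4.0 + math.log10(c))
        )
        assert expected_burden(scaled_z) == pytest.approx(c * base)
        x1 = cfg.x1
        scaled_x1 = replace(cfg, x1=uniform(x1.lower * c, x1.upper * c))
        expected = base + (c - 1) * 45.0 / 416.0 * base
        assert expected_burden(scaled_x1) == pytest.approx(expected)


class TestReplicationRounds:
    @pytest.mark.parametrize(
        "age, half_life, expect",
        [
            (70.0, 91.3125, 280),   # 3-month half-life
            (70.0, 12.0, 2131),     # 12-day half-life
            (70.0, 365.25, 70),     # 12-month half-life
            (0.0, 91.3125, 0),
        ],
    )
    def test_turnover_rounds(self, age, half_life, expect):
        assert printed_integer(turnover_rounds(age, half_life)) == expect

    @pytest.mark.parametrize(
        "age, cycle, expect", [(70.0, 40.0, 91), (0.0, 40.0, 0), (40.0, 40.0, 52)]
    )
    def test_hsc_extra_rounds(self, age, cycle, expect):
        assert printed_integer(hsc_extra_rounds(age, cycle)) == expect

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            turnover_rounds(70.0, 0.0)
        with pytest.raises(ValueError):
            hsc_extra_rounds(70.0, -1.0)
        with pytest.raises(ValueError):
            turnover_rounds(-1.0, 91.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        age=st.floats(0.1, 120.0),
        extra=st.floats(0.1, 50.0),
        half_life=st.floats(1.0, 400.0),
    )
    def test_monotone_in_age_and_half_life(self, age, extra, half_life):
        assert turnover_rounds(age + extra, half_life) > turnover_rounds(
            age, half_life
        )
        assert turnover_rounds(age, half_life + 1.0) < turnover_rounds(
            age, half_life
        )
        assert hsc_extra_rounds(age + extra) > hsc_extra_rounds(age)


class TestDivisionsToCellCount:
    def test_adult_cell_census(self):
        assert divisions_to_cell_count(3.72e13) == 45

    def test_single_cell(self):
        assert divisions_to_cell_count(1) == 0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(k=st.integers(0, 60))
    def test_exact_powers_of_two(self, k):
        assert divisions_to_cell_count(2.0 ** k) == k

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(a=st.floats(1.0, 1e15), b=st.floats(1.0, 1e15))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert divisions_to_cell_count(lo) <= divisions_to_cell_count(hi)

    def test_below_one_cell_rejected(self):
        with pytest.raises(ValueError):
            divisions_to_cell_count(0.5)


class TestPerDivisionMutations:
    def test_polg_bounds(self):
        low = per_division_mutation_count(1000, 16_569, 2.8e-8)
        high = per_division_mutation_count(1000, 16_569, 5.6e-7)
        assert low == pytest.approx(0.46, abs=0.005)
        assert high == pytest.approx(9.28, abs=0.005)
        # the quoted one-decimal figures come from the exact fidelity
        # reciprocals, 1 error per 3.6e7 / 1.8e6 bases synthesized
        assert round(per_division_mutation_count(1000, 16_569, 1 / 3.6e7), 1) == 0.5
        assert round(per_division_mutation_count(1000, 16_569, 1 / 1.8e6), 1) == 9.2

    def test_perfect_polymerase(self):
        assert per_division_mutation_count(1000, 16_569, 0.0) == 0.0

    def test_bernoulli_brute_force_oracle(self):
        # mutations per division = sum of Z*G Bernoulli(mu) trials
        z, g, mu = 1000, 16_569, 5.6e-7
        rng = np.random.default_rng(42)
        draws = rng.binomial(z * g, mu, size=10_000)
        expected = per_division_mutation_count(z, g, mu)
        se = math.sqrt(expected / len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestBirthBurden:
    def test_one_decimal_mode_reproduces_quoted_range(self):
        assert birth_burden_range(divisions=45, rounding="one_decimal") == (22, 414)

    def test_raw_mode(self):
        lo, hi = birth_burden_range(divisions=45)
        assert lo == pytest.approx(20.71, abs=0.01)
        assert hi == pytest.approx(414.2, abs=0.05)
        # with the two-significant-figure error-rate bounds instead
        lo, hi = birth_burden_range(mu_low=2.8e-8, mu_high=5.6e-7, divisions=45)
        assert lo == pytest.approx(20.9, abs=0.05)
        assert hi == pytest.approx(417.5, abs=0.05)

    def test_zero_divisions(self):
        assert birth_burden_range(divisions=0) == (0.0, 0.0)
        assert birth_burden_range(divisions=0, rounding="one_decimal") == (0.0, 0.0)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            birth_burden_range(rounding="two_decimal")


class TestBodyCopies:
    def test_census_range(self):
        lo, hi = body_copy_estimate(3.72e13, 100.0, 1e4)
        assert lo == pytest.approx(3.72e15)
        assert hi == pytest.approx(3.72e17)

    def test_zero_cells(self):
        assert body_copy_estimate(0.0, 100.0, 1e4) == (0.0, 0.0)


class TestConfig:
    def test_non_proliferating_forces_x3_zero(self):
        cfg = BurdenModelConfig(proliferating=False)
        assert cfg.x3 == fixed(0.0)

    def test_invalid_fields_rejected(self):
        with pytest.raises(ConfigurationError):
            BurdenModelConfig(genome_length_bp=0)
        with pytest.raises(ConfigurationError):
            BurdenModelConfig(halving_factor=0.0)
        with pytest.raises(ConfigurationError):
            BurdenModelConfig(x1=uniform(-5.0, 10.0))
        with pytest.raises(ConfigurationError):
            TurnoverParams(half_life_days=-1.0)

    def test_config_for_age_reference_at_70(self):
        cfg = config_for_age(70.0)
        assert cfg.x2 == uniform(180.0, 380.0)
        assert cfg.x3 == uniform(81.0, 101.0)

    def test_config_for_age_scales_linearly(self):
        cfg = config_for_age(35.0)
        assert cfg.x2.mean() == pytest.approx(140.0)
        assert cfg.x3.mean() == pytest.approx(45.66, abs=0.01)
        # constant coefficient of variation: half-width scales with midpoint
        assert cfg.x2.upper - cfg.x2.lower == pytest.approx(100.0)

    def test_config_for_age_newborn(self):
        cfg = config_for_age(0.0)
        assert cfg.x2 == fixed(0.0)
        assert cfg.x3 == fixed(0.0)
        assert expected_burden(cfg) == pytest.approx(
            16_569 * 1000 * 1.47e-7 * 45
        )
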