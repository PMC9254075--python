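"""Cohort simulator: death-day sampling, serial correlation, reproducibility."""

import numpy as np
import pytest
from scipy.special import expit

from helpers import lag1_correlation
from paceshape.cohort import write_cohort
from paceshape.mortality import ParameterError
from paceshape.pace_shape import fecundity_shape_table, shape_mortality
from paceshape.simulate import (
    SimulationConfig,
    SpeciesParams,
    discrete_mean_lifespan,
    inverse_survival,
    markov_binary_series,
    paper_like_config,
    sample_death_day,
    simulate_cohort,
    simulate_reproduction,
)


class TestSampleDeathDay:
    def test_discretized_exponential_mean(self, rng):
        """ceil of an Exp(b) draw has mean 1/(1 - e^{-b})."""
        draws = sample_death_day("exponential", (0.1,), 1.0, rng, size=100_000)
        expected = 1.0 / -np.expm1(-0.1)  # ~10.508
        assert np.mean(draws) == pytest.approx(expected, abs=0.12)

    @pytest.mark.parametrize(
        "model, params",
        [
            ("exponential", (0.1,)),
            ("weibull", (0.001, 2.5)),
            ("gompertz", (0.01, 0.1)),
            ("logistic", (0.005, 0.2, 0.8)),
        ],
    )
    def test_all_draws_at_least_one_day(self, model, params, rng):
        draws = sample_death_day(model, params, 0.5, rng, size=2000)
        assert np.all(draws >= 1)

    def test_fixed_seed_reproduces_draw_sequence(self):
        a = sample_death_day(
            "gompertz", (0.01, 0.1), 1.0, np.random.default_rng(5), size=50
        )
        b = sample_death_day(
            "gompertz", (0.01, 0.1), 1.0, np.random.default_rng(5), size=50
        )
        assert np.array_equal(a, b)

    def test_pace_multiplier_scales_continuous_time(self):
        rng1, rng2 = np.random.default_rng(8), np.random.default_rng(8)
        d2 = sample_death_day("gompertz", (0.01, 0.15), 2.0, rng1, size=100)
        u = rng2.uniform(size=100)
        manual = np.maximum(
            1,
            np.ceil(2.0 * inverse_survival("gompertz", (0.01, 0.15), u)).astype(int),
        )
        assert np.array_equal(d2, manual)

    def test_invalid_multiplier_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_death_day("exponential", (0.1,), 0.0, rng)

    @pytest.mark.parametrize(
        "model, params",
        [
            ("weibull", (0.002, 2.0)),
            ("logistic", (0.004, 0.2, 0.6)),
        ],
    )
    def test_inverse_survival_inverts_survivorship(self, model, params):
        from paceshape.mortality import survivorship

        u = np.array([0.9, 0.5, 0.1])
        t = inverse_survival(model, params, u)
        assert np.allclose(survivorship(model, params, t), u, atol=1e-10)


class TestMarkovSeries:
    def test_zero_correlation_matches_marginals(self, rng):
        ages = np.arange(1, 11)
        p = expit(0.4 - 0.05 * ages)
        draws = np.array(
            [markov_binary_series(p, 0.0, rng)[0] for _ in range(20_000)]
        )
        assert np.allclose(draws.mean(axis=0), p, atol=0.015)

    def test_zero_correlation_gives_zero_lag1(self, rng):
        y, _ = markov_binary_series(np.full(100_000, 0.5), 0.0, rng)
        assert abs(lag1_correlation(y)) < 0.02

    def test_target_lag1_correlation_attained(self, rng):
        y, n_clip = markov_binary_series(np.full(100_000, 0.5), 0.3, rng)
        assert n_clip == 0
        assert lag1_correlation(y) == pytest.approx(0.3, abs=0.02)

    def test_negative_correlation(self, rng):
        y, _ = markov_binary_series(np.full(100_000, 0.5), -0.2, rng)
        assert lag1_correlation(y) == pytest.approx(-0.2, abs=0.02)


class TestSimulateReproduction:
    def _params(self, **kw):
        base = dict(
            mortality_model="exponential",
            mortality_params=(0.05,),
            repro_latency=2,
            repro_intercept=0.4,
            repro_slope=-0.03,
            serial_corr=0.0,
            twin_prob=0.0,
        )
        base.update(kw)
        return SpeciesParams(**base)

    def test_latency_days_never_reproduce(self, rng):
        sp = self._params(repro_intercept=8.0, repro_slope=0.0)
        counts, reproduced = simulate_reproduction(10, sp, rng)
        assert reproduced
        assert counts[:2] == [0, 0] and all(c == 1 for c in counts[2:])

    def test_truncation_never_lengthens_lifespan(self, rng):
        sp = self._params()
        for _ in range(200):
            death = int(rng.integers(1, 40))
            counts, reproduced = simulate_reproduction(death, sp, rng)
            assert len(counts) <= death

    def test_never_reproducing_frond_flagged(self, rng):
        sp = self._params(repro_intercept=-30.0, repro_slope=0.0)
        counts, reproduced = simulate_reproduction(8, sp, rng)
        assert not reproduced and counts == [0] * 8

    def test_twin_rate_matches_configured_probability(self, rng):
        sp = self._params(repro_intercept=8.0, repro_slope=0.0, twin_prob=0.4)
        twins = days = 0
        for _ in range(500):
            counts, _ = simulate_reproduction(10, sp, rng)
            reproducing = [c for c in counts if c > 0]
            days += len(reproducing)
            twins += sum(c == 2 for c in reproducing)
        assert twins / days == pytest.approx(0.4, abs=0.03)

    def test_invalid_death_day(self, rng):
        with pytest.raises(ParameterError):
            simulate_reproduction(0, self._params(), rng)


class TestSimulateCohort:
    def test_paper_like_design_has_initial_n_444(self, paper_cohort):
        assert len(paper_cohort) == 444  # 3 species x 4 blocks x 37

    def test_no_loss_and_guaranteed_reproduction_excludes_nothing(self):
        sp = SpeciesParams(
            "exponential", (0.1,), repro_latency=0, repro_intercept=9.0,
            repro_slope=0.0,
        )
        cfg = SimulationConfig(
            species_params={"S": sp}, blocks={"B1": 1.0}, n_per_cell=50,
            loss_prob=0.0, seed=1,
        )
        cohort = simulate_cohort(cfg)
        assert sum(f.excluded for f in cohort.fronds) == 0

    def test_mean_lifespan_matches_numerical_summation_oracle(self):
        """Simulated logistic death days average to sum_k S(k)."""
        params = (0.004, 0.2, 0.6)
        rng = np.random.default_rng(3)
        draws = sample_death_day("logistic", params, 1.0, rng, size=10_000)
        oracle = discrete_mean_lifespan("logistic", params)
        se = np.std(draws) / np.sqrt(draws.size)
        assert np.mean(draws) == pytest.approx(oracle, abs=4 * se)

    def test_seed_fixes_emitted_csv_byte_for_byte(self, tmp_path):
        cfg = paper_like_config(seed=42, n_per_cell=5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(simulate_cohort(cfg), p1)
        write_cohort(simulate_cohort(paper_like_config(seed=42, n_per_cell=5)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_exponential_mortality_gives_near_zero_shape(self):
        """CV of an exponential lifespan law is 1, so shape ~ 0."""
        rng = np.random.default_rng(9)
        draws = sample_death_day("exponential", (0.04,), 1.0, rng, size=100_000)
        assert abs(shape_mortality(draws)) < 0.05


class TestPaperLikeConfig:
    def test_config_passes_invariants(self):
        cfg = paper_like_config(seed=0)
        assert set(cfg.blocks) == {"B1", "B2", "B3", "B4"}
        assert cfg.n_per_cell == 37
        assert len(cfg.species_params) == 3

    def test_simulated_mean_lifespans_in_plausible_range(self, paper_cohort):
        from paceshape.cohort import lifespans

        for sp in paper_cohort.species:
            mean = np.mean(lifespans(paper_cohort, species=sp))
            assert 20 <= mean <= 32

    def test_fecundity_shape_ordering_matches_configured_slopes(self):
        """Steeper configured reproduction decline => lower mean slope.

        Species order by configured logit slope is LG < LM < LT; the mean
        per-frond standardized-fecundity slope must follow.  A larger
        cohort keeps sampling noise below the configured separation.
        """
        cohort = simulate_cohort(paper_like_config(seed=5, n_per_cell=150))
        table = fecundity_shape_table(cohort)
        means = table[table["defined"]].groupby("species")["shape_fecundity"].mean()
        assert means["LG"] < means["LM"] < means["LT"]


class TestConfigValidation:
    def test_serial_corr_domain(self):
        with pytest.raises(ParameterError):
            SpeciesParams("exponential", (0.1,), serial_corr=1.0)

    def test_loss_prob_domain(self):
        sp = SpeciesParams("exponential", (0.1,))
        with pytest.raises(ParameterError):
            SimulationConfig(species_params={"S": sp}, blocks={"B": 1.0}, loss_prob=1.0)

    def test_round_trip_dict(self):
        cfg = paper_like_config(seed=7)
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()
        assert again.config_hash() == cfg.config_hash()
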