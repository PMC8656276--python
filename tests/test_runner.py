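"""Experiment orchestration: replicates, summaries, determinism."""

import numpy as np
import pandas as pd
import pytest

from ptsdsim.media import BASELINE_HOURS, HoursDistribution, MediaPreferenceParams
from ptsdsim.risk import RiskParams, calibrate_params, expected_prevalence
from ptsdsim.runner import (
    ExperimentConfig,
    nearest_rank_percentile,
    read_summary,
    replicate_seed,
    run_experiment,
    run_replicate,
    write_summary,
)
from ptsdsim.scenarios import ScenarioSpec, scenario_weights


@pytest.fixture(scope="module")
def small_config():
    """20k-agent config for fast Monte Carlo checks."""
    return ExperimentConfig(size=20_000, replicates=8, master_seed=3)


class TestRunReplicate:
    def test_prevalence_near_analytic_expectation(self, small_config):
        params, f = calibrate_params()
        expected = expected_prevalence(BASELINE_HOURS, params, f)
        n_tertiary = small_config.size - 930 - 4725
        se = np.sqrt(expected * (1 - expected) / n_tertiary)
        prev = run_replicate(small_config, ScenarioSpec(), seed=101)
        assert abs(prev - expected) < 4 * se

    def test_zero_risk_gives_zero_prevalence(self, small_config):
        cfg = ExperimentConfig(
            size=small_config.size, risk=RiskParams(p=(0, 0, 0, 0)), replicates=1
        )
        assert run_replicate(cfg, ScenarioSpec(), seed=0) == 0.0

    def test_certain_risk_gives_unit_prevalence(self, small_config):
        cfg = ExperimentConfig(
            size=small_config.size,
            media=MediaPreferenceParams(1.0),
            hours=HoursDistribution((1.0, 0, 0, 0)),
            risk=RiskParams(p=(1.0, 1.0, 1.0, 1.0)),
            replicates=1,
        )
        assert run_replicate(cfg, ScenarioSpec(), seed=0) == 1.0

    def test_pure_function_of_config_and_seed(self, small_config):
        a = run_replicate(small_config, ScenarioSpec(), seed=55)
        b = run_replicate(small_config, ScenarioSpec(), seed=55)
        assert a == b


class TestSeeds:
    def test_distinct_per_condition_and_replicate(self):
        seeds = {
            replicate_seed(1, ScenarioSpec(s, e), r)
            for s in ("baseline", "s1_under4")
            for e in ("none", "video")
            for r in range(10)
        }
        assert len(seeds) == 40
        assert all(0 <= s < 2**31 for s in seeds)

    def test_stable_scheme(self):
        assert replicate_seed(1, ScenarioSpec(), 0) == replicate_seed(
            1, ScenarioSpec(), 0
        )


class TestNearestRank:
    def test_order_statistics_for_fifty(self):
        vals = np.arange(1, 51, dtype=float)  # 1..50
        assert nearest_rank_percentile(vals, 2.5) == 2.0  # 2nd order stat
        assert nearest_rank_percentile(vals, 97.5) == 49.0  # 49th order stat
        assert nearest_rank_percentile(vals, 50) == 25.0

    def test_single_value(self):
        assert nearest_rank_percentile(np.array([0.7]), 2.5) == 0.7
        assert nearest_rank_percentile(np.array([0.7]), 97.5) == 0.7


class TestRunExperiment:
    def test_summary_band_contains_mean(self, small_config):
        out = run_experiment(small_config)
        row = out.summary.iloc[0]
        assert row["p2_5"] <= row["mean"] <= row["p97_5"]
        assert row["replicates"] == small_config.replicates
        assert len(out.replicates) == small_config.replicates

    def test_single_replicate_collapses_band(self):
        cfg = ExperimentConfig(size=10_000, replicates=1)
        out = run_experiment(cfg)
        row = out.summary.iloc[0]
        assert row["mean"] == row["p2_5"] == row["p97_5"]

    def test_replicates_below_one_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(replicates=0)

    def test_undersized_population_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(size=5_000)  # smaller than 930 + 4,725

    def test_byte_identical_outputs_for_fixed_seed(self, small_config, tmp_path):
        """Full determinism: same config + master seed -> identical CSVs."""
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_summary(run_experiment(small_config), d1)
        write_summary(run_experiment(small_config), d2)
        for name in ("replicates.csv", "summary.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_summary_round_trip(self, small_config, tmp_path):
        out = run_experiment(small_config)
        write_summary(out, tmp_path)
        assert read_summary(tmp_path) == out

    def test_multi_condition_summary_rows(self, tmp_path):
        cfg = ExperimentConfig(
            size=10_000,
            replicates=2,
            scenarios=(
                ScenarioSpec("baseline"),
                ScenarioSpec("s1_under4"),
                ScenarioSpec("baseline", "video"),
            ),
        )
        out = run_experiment(cfg)
        assert len(out.summary) == 3
        assert len(out.replicates) == 6

    def test_replicate_serial_independence(self, small_config):
        """Runs test finds no serial correlation across replicate prevalences."""
        from statsmodels.sandbox.stats.runs import runstest_1samp

        cfg = ExperimentConfig(size=10_000, replicates=50, master_seed=17)
        out = run_experiment(cfg)
        _, pvalue = runstest_1samp(out.replicates["prevalence"].to_numpy())
        assert pvalue > 0.01

    def test_monte_carlo_mean_matches_oracle(self):
        """MC mean within 3 SE of the closed-form expectation per scenario."""
        params, f = calibrate_params()
        cfg = ExperimentConfig(size=20_000, replicates=6, master_seed=9)
        for sid in ("baseline", "s2_lower_half", "s3_upper_half"):
            spec = ScenarioSpec(sid)
            prevs = [
                run_replicate(cfg, spec, replicate_seed(cfg.master_seed, spec, r))
                for r in range(cfg.replicates)
            ]
            q = expected_prevalence(scenario_weights(BASELINE_HOURS, spec), params, f)
            n_tertiary = cfg.size - 930 - 4725
            se = np.sqrt(q * (1 - q) / n_tertiary) / np.sqrt(cfg.replicates)
            assert abs(np.mean(prevs) - q) < 3 * se, sid

    def test_smaller_population_widens_spread(self):
        """Halving population size leaves the mean unbiased but increases
        replicate-to-replicate spread."""
        reps = 16
        small = run_experiment(
            ExperimentConfig(size=8_000, replicates=reps, master_seed=21)
        )
        large = run_experiment(
            ExperimentConfig(size=32_000, replicates=reps, master_seed=21)
        )
        assert small.replicates["prevalence"].std() > large.replicates[
            "prevalence"
        ].std()
        params, f = calibrate_params()
        q = expected_prevalence(BASELINE_HOURS, params, f)
        for out, size in ((small, 8_000), (large, 32_000)):
            n_tert = size - 930 - 4725
            se = np.sqrt(q * (1 - q) / n_tert) / np.sqrt(reps)
            assert abs(out.summary["mean"].iloc[0] - q) < 4 * se
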