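"""End-to-end Monte Carlo experiment orchestration.

A replicate rebuilds the whole world from a single seed: population →
exposure tiers → media profiles → scenario transform → risk probabilities →
Bernoulli PTSD draws, then reports the PTSD-positive share of the tertiary
tier (the media-exposed community).  An experiment runs a configurable
number of independent replicates per scenario (50 by default, matching the
reported protocol) and summarizes each scenario with the mean prevalence
and the nearest-rank 2.5th/97.5th percentiles.

Seeding: the master seed spawns one child seed per (scenario, engagement,
replicate) through ``numpy.random.SeedSequence([master, scenario_index,
engagement_index, replicate])``; each child is recorded in the output so any
single replicate can be re-run in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exposure import ExposureConfig, assign_tiers
from .media import (
    BASELINE_HOURS,
    ENGAGEMENT_LEVELS,
    HoursDistribution,
    MediaPreferenceParams,
    assign_engagement,
    assign_tv_hours,
    assign_tv_preference,
)
from .risk import RiskParams, assign_probabilities, draw_ptsd
from .scenarios import SCENARIO_IDS, ScenarioSpec, apply_scenario
from .synthpop import MarginalTable, default_marginals, generate_population

__all__ = [
    "ExperimentConfig",
    "ExperimentSummary",
    "replicate_seed",
    "simulate_replicate",
    "run_replicate",
    "run_experiment",
    "write_summary",
    "read_summary",
    "nearest_rank_percentile",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a reproducible experiment needs."""

    size: int = 118_000
    marginals: MarginalTable = field(default_factory=default_marginals, repr=False)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    media: MediaPreferenceParams = field(default_factory=MediaPreferenceParams)
    hours: HoursDistribution = BASELINE_HOURS
    risk: RiskParams = field(default_factory=RiskParams)
    scenarios: tuple[ScenarioSpec, ...] = (ScenarioSpec(),)
    replicates: int = 50
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.size < self.exposure.n_primary + self.exposure.n_secondary_target:
            raise ValueError("population smaller than primary + secondary tiers")


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-scenario mean prevalence with 2.5th/97.5th percentile band, plus
    the underlying per-replicate prevalences."""

    replicates: pd.DataFrame  # scenario, engagement, replicate, seed, prevalence
    summary: pd.DataFrame  # scenario, engagement, mean, p2_5, p97_5, replicates

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentSummary):
            return NotImplemented
        return self.replicates.equals(other.replicates) and self.summary.equals(
            other.summary
        )


def replicate_seed(master_seed: int, spec: ScenarioSpec, replicate: int) -> int:
    """Deterministic child seed for one (scenario, engagement, replicate)."""
    seq = np.random.SeedSequence(
        [
            int(master_seed),
            SCENARIO_IDS.index(spec.id),
            ENGAGEMENT_LEVELS.index(spec.engagement),
            int(replicate),
        ]
    )
    return int(seq.generate_state(1)[0] % 2**31)


def simulate_replicate(
    config: ExperimentConfig, spec: ScenarioSpec, seed: int
) -> pd.DataFrame:
    """Run one full replicate and return the final agent table (with
    ``exposure_tier``, media profile, ``ptsd_prob`` and ``ptsd`` columns)."""
    stages = np.random.SeedSequence(int(seed)).spawn(5)
    s_pop, s_tier, s_pref, s_hours, s_draw = (
        int(s.generate_state(1)[0] % 2**31) for s in stages
    )
    pop = generate_population(config.marginals, config.size, s_pop)
    assign_tiers(pop, config.exposure, s_tier)
    assign_tv_preference(pop, config.media, s_pref)
    assign_tv_hours(pop, config.hours, s_hours)
    apply_scenario(pop, spec)
    assign_engagement(pop, spec.engagement)
    assign_probabilities(pop, config.risk)
    draw_ptsd(pop, s_draw)
    return pop


def run_replicate(config: ExperimentConfig, spec: ScenarioSpec, seed: int) -> float:
    """One replicate's PTSD prevalence: positives / tertiary-tier size."""
    pop = simulate_replicate(config, spec, seed)
    tertiary = pop["exposure_tier"] == "tertiary"
    return float(pop.loc[tertiary, "ptsd"].sum() / int(tertiary.sum()))


def run_experiment(config: ExperimentConfig) -> ExperimentSummary:
    """Run all configured scenarios x replicates and summarize."""
    rows = []
    for spec in config.scenarios:
        for rep in range(config.replicates):
            seed = replicate_seed(config.master_seed, spec, rep)
            prev = run_replicate(config, spec, seed)
            rows.append((spec.id, spec.engagement, rep, seed, prev))
    reps = pd.DataFrame(
        rows, columns=["scenario", "engagement", "replicate", "seed", "prevalence"]
    )
    return ExperimentSummary(replicates=reps, summary=summarize(reps))


def summarize(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean and nearest-rank 2.5/97.5 percentiles per scenario condition."""
    rows = []
    for (scen, eng), grp in replicates.groupby(
        ["scenario", "engagement"], sort=False, observed=True
    ):
        vals = grp["prevalence"].to_numpy()
        rows.append(
            (
                scen,
                eng,
                float(vals.mean()),
                nearest_rank_percentile(vals, 2.5),
                nearest_rank_percentile(vals, 97.5),
                len(vals),
            )
        )
    return pd.DataFrame(
        rows, columns=["scenario", "engagement", "mean", "p2_5", "p97_5", "replicates"]
    )


def percent_round(fraction: float, ndigits: int = 1) -> float:
    """Report a prevalence fraction as a percentage rounded half-up, the
    convention used when comparing against published one-decimal values."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(
        Decimal(repr(float(fraction) * 100)).quantize(q, rounding=ROUND_HALF_UP)
    )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the order statistic at ceil(q/100 * n).
    With 50 replicates the 2.5th/97.5th are the 2nd and 49th values."""
    vals = np.sort(np.asarray(values, dtype=float))
    if len(vals) == 0:
        raise ValueError("no values")
    rank = max(1, math.ceil(q / 100.0 * len(vals)))
    return float(vals[rank - 1])


def write_summary(summary: ExperimentSummary, outdir) -> tuple[str, str]:
    """Write per-replicate and summary CSVs; returns their paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep_path = outdir / "replicates.csv"
    sum_path = outdir / "summary.csv"
    # %.17g guarantees lossless float round-trip through the reader
    summary.replicates.to_csv(rep_path, index=False, float_format="%.17g")
    summary.summary.to_csv(sum_path, index=False, float_format="%.17g")
    return str(rep_path), str(sum_path)


def read_summary(outdir) -> ExperimentSummary:
    """Round-trip reader for :func:`write_summary` output."""
    from pathlib import Path

    outdir = Path(outdir)
    reps = pd.read_csv(outdir / "replicates.csv", float_precision="round_trip")
    summ = pd.read_csv(outdir / "summary.csv", float_precision="round_trip")
    return ExperimentSummary(replicates=reps, summary=summ)


def scenario_condition(id: str, engagement: str = "none") -> ScenarioSpec:
    """Convenience constructor accepting short ids (s1/s2/s3)."""
    return ScenarioSpec(id=id, engagement=engagement)


def with_scenarios(
    config: ExperimentConfig, specs: list[ScenarioSpec]
) -> ExperimentConfig:
    return replace(config, scenarios=tuple(specs))
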