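"""Media profiles for tertiary (community) agents.

Each tertiary agent prefers TV as its news source with probability ``f``
(optionally stratified by age band).  TV-preferring agents are assigned a
daily hours-of-coverage category from a four-bin distribution
(<4, 4-7, 8-11, 12+ h) and, scenario-wide, a social-media engagement level
on top of TV watching (none, casual post-viewing, or video sharing).
Agents in the primary and secondary tiers receive no media profile: only
the media-mediated pathway of the tertiary community carries risk here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MediaPreferenceParams",
    "HoursDistribution",
    "BASELINE_HOURS",
    "HOURS_LABELS",
    "ENGAGEMENT_LEVELS",
    "assign_tv_preference",
    "assign_tv_hours",
    "assign_engagement",
]

#: Category labels for the four TV-hours bins, ascending exposure.
HOURS_LABELS = ("<4", "4-7", "8-11", "12+")
ENGAGEMENT_LEVELS = ("none", "casual", "video")


@dataclass(frozen=True)
class MediaPreferenceParams:
    """Probability that an agent prefers TV news.

    ``tv_preference_fraction`` is the scalar default (calibrated ≈ 0.3969);
    ``by_age`` optionally overrides it per age band, restoring the
    age-stratified structure of survey-derived preferences.
    """

    tv_preference_fraction: float = 0.3968667089390426
    by_age: dict[str, float] | None = None

    def __post_init__(self) -> None:
        fractions = [self.tv_preference_fraction]
        if self.by_age:
            fractions += list(self.by_age.values())
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("TV-preference fractions must lie in [0, 1]")

    def fraction_for(self, age_band: str) -> float:
        if self.by_age and age_band in self.by_age:
            return self.by_age[age_band]
        return self.tv_preference_fraction


@dataclass(frozen=True)
class HoursDistribution:
    """Weights over the four TV-hours categories; must sum to 1."""

    weights: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise ValueError("exactly four hours-category weights required")
        if (w < 0).any():
            raise ValueError("hours weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"hours weights sum to {w.sum():.12f}, not 1")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


#: Baseline community distribution of daily hours of event TV coverage.
BASELINE_HOURS = HoursDistribution((0.112, 0.131, 0.108, 0.649))


def _tertiary_mask(population: pd.DataFrame) -> np.ndarray:
    if "exposure_tier" not in population.columns:
        raise ValueError("exposure tiers must be assigned before media profiles")
    return (population["exposure_tier"] == "tertiary").to_numpy()


def assign_tv_preference(
    population: pd.DataFrame, params: MediaPreferenceParams, seed: int
) -> pd.DataFrame:
    """Bernoulli TV-preference draw for every tertiary agent.

    Non-tertiary agents keep a missing ``prefers_tv`` (no media profile).
    Mutates and returns ``population``.
    """
    rng = np.random.default_rng(seed)
    tertiary = _tertiary_mask(population)
    u = rng.random(len(population))
    if params.by_age:
        f = np.array(
            [params.fraction_for(b) for b in population["age_band"].astype(str)]
        )
    else:
        f = params.tv_preference_fraction
    prefers = pd.array(u < f, dtype="boolean")
    prefers[~tertiary] = pd.NA
    population["prefers_tv"] = prefers
    return population


def assign_tv_hours(
    population: pd.DataFrame, dist: HoursDistribution, seed: int
) -> pd.DataFrame:
    """Sample an hours category (1..4) for each TV-preferring agent; all
    other agents get a missing category.  Mutates and returns ``population``."""
    if "prefers_tv" not in population.columns:
        raise ValueError("TV preference must be assigned before hours")
    rng = np.random.default_rng(seed)
    watches = population["prefers_tv"].fillna(False).to_numpy(dtype=bool)
    cats = rng.choice(4, size=int(watches.sum()), p=dist.as_array()) + 1
    col = pd.array(np.zeros(len(population), dtype=np.int64), dtype="Int64")
    col[:] = pd.NA
    col[np.flatnonzero(watches)] = cats
    population["hours_category"] = col
    return population


def assign_engagement(population: pd.DataFrame, level: str) -> pd.DataFrame:
    """Set the scenario-wide social-media engagement level for all
    TV-preferring agents.  Mutates and returns ``population``."""
    if level not in ENGAGEMENT_LEVELS:
        raise ValueError(f"unknown engagement level {level!r}; use {ENGAGEMENT_LEVELS}")
    if "prefers_tv" not in population.columns:
        raise ValueError("TV preference must be assigned before engagement")
    watches = population["prefers_tv"].fillna(False).to_numpy(dtype=bool)
    col = pd.Categorical([None] * len(population), categories=ENGAGEMENT_LEVELS)
    eng = pd.Series(col)
    eng[watches] = level
    population["engagement"] = pd.Categorical(eng, categories=ENGAGEMENT_LEVELS)
    return population
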