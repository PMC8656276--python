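"""Trauma-exposure tiers: primary, secondary, tertiary.

Primary agents were present at the event site (students plus adults).  An
internal social network connects each primary agent to family / close
friends drawn from the rest of the population; those contacts form the
secondary tier.  Everyone else is tertiary — the community at large, exposed
only through media coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthpop import UNDER_20

__all__ = [
    "ExposureConfig",
    "SocialNetwork",
    "assign_primary",
    "build_secondary_network",
    "assign_tertiary",
    "assign_tiers",
]

TIER_CATEGORIES = ("primary", "secondary", "tertiary", "none")


@dataclass(frozen=True)
class ExposureConfig:
    """Tier sizes.  Defaults reproduce the modeled shooting: 900 students and
    30 adults directly exposed, 4,725 family/close-friend contacts."""

    n_primary_students: int = 900
    n_primary_adults: int = 30
    n_secondary_target: int = 4725

    def __post_init__(self) -> None:
        if min(self.n_primary_students, self.n_primary_adults, self.n_secondary_target) < 0:
            raise ValueError("tier sizes must be non-negative")

    @property
    def n_primary(self) -> int:
        return self.n_primary_students + self.n_primary_adults

    @property
    def contacts_per_primary(self) -> float:
        """Mean secondary contacts per primary agent (≈ 5.081 at defaults)."""
        if self.n_primary == 0:
            return 0.0
        return self.n_secondary_target / self.n_primary


@dataclass(frozen=True)
class SocialNetwork:
    """Edge list linking each primary agent to its secondary contacts."""

    edges: np.ndarray  # shape (n_secondary, 2): (primary_id, contact_id)
    secondary_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.edges.size and len(np.unique(self.edges[:, 1])) != len(self.edges):
            raise ValueError("a contact appears in more than one edge")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["primary_id", "contact_id"])


def assign_primary(
    population: pd.DataFrame, config: ExposureConfig, seed: int
) -> np.ndarray:
    """Select primary-tier agent ids: students uniformly from the under-20
    band, adults uniformly from the 20+ bands.  Marks ``exposure_tier``."""
    rng = np.random.default_rng(seed)
    is_under20 = (population["age_band"] == UNDER_20).to_numpy()
    under20_ids = population.loc[is_under20, "id"].to_numpy()
    adult_ids = population.loc[~is_under20, "id"].to_numpy()
    if len(under20_ids) < config.n_primary_students:
        raise ValueError(
            f"need {config.n_primary_students} under-20 agents, "
            f"have {len(under20_ids)}"
        )
    if len(adult_ids) < config.n_primary_adults:
        raise ValueError(
            f"need {config.n_primary_adults} adult agents, have {len(adult_ids)}"
        )
    students = rng.choice(under20_ids, size=config.n_primary_students, replace=False)
    adults = rng.choice(adult_ids, size=config.n_primary_adults, replace=False)
    primary = np.sort(np.concatenate([students, adults]))
    _ensure_tier_column(population)
    population.loc[population["id"].isin(primary), "exposure_tier"] = "primary"
    return primary


def build_secondary_network(
    population: pd.DataFrame,
    primary_ids: np.ndarray,
    config: ExposureConfig,
    seed: int,
) -> SocialNetwork:
    """Draw secondary contacts uniformly without replacement from non-primary
    agents until the secondary tier reaches its target size; contacts are
    linked to primary agents round-robin.  Marks ``exposure_tier``."""
    rng = np.random.default_rng(seed)
    n_target = config.n_secondary_target
    primary_set = np.asarray(primary_ids)
    if len(primary_set) == 0 or n_target == 0:
        empty = np.empty((0, 2), dtype=np.int64)
        return SocialNetwork(edges=empty, secondary_ids=np.empty(0, dtype=np.int64))
    pool = population.loc[~population["id"].isin(primary_set), "id"].to_numpy()
    if n_target > len(pool):
        raise ValueError(
            f"secondary target {n_target} exceeds {len(pool)} available agents"
        )
    contacts = rng.choice(pool, size=n_target, replace=False)
    owners = np.resize(np.sort(primary_set), n_target)  # round-robin cycling
    edges = np.column_stack([owners, contacts]).astype(np.int64)
    _ensure_tier_column(population)
    population.loc[population["id"].isin(contacts), "exposure_tier"] = "secondary"
    return SocialNetwork(edges=edges, secondary_ids=np.sort(contacts))


def assign_tertiary(population: pd.DataFrame) -> np.ndarray:
    """Mark every agent not already primary/secondary as tertiary; the three
    tiers then partition the population."""
    if "exposure_tier" not in population.columns:
        raise ValueError("primary and secondary tiers must be assigned first")
    mask = population["exposure_tier"] == "none"
    population.loc[mask, "exposure_tier"] = "tertiary"
    return population.loc[population["exposure_tier"] == "tertiary", "id"].to_numpy()


def assign_tiers(
    population: pd.DataFrame, config: ExposureConfig, seed: int
) -> SocialNetwork:
    """Full tier construction: primary, then the secondary network, then
    tertiary = remainder.  Asserts the partition property."""
    seq = np.random.SeedSequence([int(seed), 0x7E5])
    s_primary, s_secondary = (int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(2))
    primary = assign_primary(population, config, s_primary)
    network = build_secondary_network(population, primary, config, s_secondary)
    assign_tertiary(population)
    counts = population["exposure_tier"].value_counts()
    assert counts.get("none", 0) == 0 and counts.sum() == len(population)
    return network


def _ensure_tier_column(population: pd.DataFrame) -> None:
    if "exposure_tier" not in population.columns:
        population["exposure_tier"] = pd.Categorical(
            ["none"] * len(population), categories=TIER_CATEGORIES
        )
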