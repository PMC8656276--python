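"""Counterfactual TV-watching scenarios.

Each scenario remaps baseline per-agent hours categories:

* ``baseline`` — identity.
* ``s1_under4`` — every TV watcher moves to the <4 h bin.
* ``s2_lower_half`` — upper-half bins clamp to the nearest lower-half bin
  (8-11 → 4-7, 12+ → 4-7).
* ``s3_upper_half`` — lower-half bins clamp to the nearest upper-half bin
  (<4 → 8-11, 4-7 → 8-11).

Transformations act on agent-level assignments, so scenarios run from the
same seed are paired comparisons sharing randomness.  ``scenario_weights``
is the analytic pushforward of a category distribution under the same map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .media import ENGAGEMENT_LEVELS, HoursDistribution

__all__ = ["ScenarioSpec", "SCENARIO_IDS", "apply_scenario", "scenario_weights"]

SCENARIO_IDS = ("baseline", "s1_under4", "s2_lower_half", "s3_upper_half")

# category map per scenario: old category (1..4) -> new category
_MAPS: dict[str, dict[int, int]] = {
    "baseline": {1: 1, 2: 2, 3: 3, 4: 4},
    "s1_under4": {1: 1, 2: 1, 3: 1, 4: 1},
    "s2_lower_half": {1: 1, 2: 2, 3: 2, 4: 2},
    "s3_upper_half": {1: 3, 2: 3, 3: 3, 4: 4},
}

_SHORT = {"baseline": "baseline", "s1": "s1_under4", "s2": "s2_lower_half",
          "s3": "s3_upper_half"}


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual condition: hours-category remap plus a scenario-wide
    social-media engagement add-on."""

    id: str = "baseline"
    engagement: str = "none"

    def __post_init__(self) -> None:
        ident = _SHORT.get(self.id, self.id)
        if ident not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario id {self.id!r}; use {SCENARIO_IDS}")
        object.__setattr__(self, "id", ident)
        if self.engagement not in ENGAGEMENT_LEVELS:
            raise ValueError(
                f"unknown engagement {self.engagement!r}; use {ENGAGEMENT_LEVELS}"
            )

    @property
    def label(self) -> str:
        return f"{self.id}+{self.engagement}" if self.engagement != "none" else self.id


def apply_scenario(population: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Remap each TV watcher's ``hours_category`` under the scenario.
    Missing categories (non-watchers) are untouched.  Mutates and returns
    ``population``."""
    cmap = _MAPS[spec.id]
    hours = population["hours_category"]
    lut = np.array([0] + [cmap[i] for i in (1, 2, 3, 4)], dtype=np.int64)
    present = hours.notna().to_numpy()
    vals = hours.to_numpy(dtype="float64", na_value=0).astype(np.int64)
    out = pd.array(vals, dtype="Int64")
    out[present] = lut[vals[present]]
    out[~present] = pd.NA
    population["hours_category"] = out
    return population


def scenario_weights(
    baseline: HoursDistribution, spec: ScenarioSpec
) -> HoursDistribution:
    """Pushforward of the baseline category weights under the scenario map."""
    cmap = _MAPS[spec.id]
    w = baseline.as_array()
    out = np.zeros(4)
    for old, new in cmap.items():
        out[new - 1] += w[old - 1]
    return HoursDistribution(tuple(out))
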