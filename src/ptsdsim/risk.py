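"""Dose-response PTSD risk model and parameter calibration.

Risk is a categorical dose-response on daily hours of TV coverage watched:
P(PTSD | hours category i) = p_i for the four bins <4, 4-7, 8-11, 12+ h.
The endpoints p1 = 0.008 and p4 = 0.101 are the published post-9/11
conditional prevalences; social-media engagement multiplies the TV-based
risk (casual post-viewing or video sharing), capped at ``cap``.  Agents who
do not prefer TV news carry zero media-mediated risk.

The middle-category probabilities, the TV-preference fraction f, and the
engagement multipliers are not published; ``calibrate_params`` recovers them
from the reported population prevalences by solving the analytic
expected-prevalence equations — a system linear in (f, f·p2, f·p3) — and
taking the casual/video multipliers as prevalence ratios to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .media import BASELINE_HOURS, ENGAGEMENT_LEVELS, HoursDistribution

__all__ = [
    "RiskParams",
    "CalibrationTargets",
    "ptsd_probability",
    "assign_probabilities",
    "draw_ptsd",
    "expected_prevalence",
    "calibrate_params",
]


@dataclass(frozen=True)
class RiskParams:
    """Per-category PTSD probabilities and engagement multipliers.

    Defaults are the shipped calibration: p1/p4 published, p2/p3 and the
    multipliers solved from reported prevalences (see module docstring).
    """

    p: tuple[float, float, float, float] = (
        0.008,
        0.03587904259596509,
        0.06450660615441486,
        0.101,
    )
    m_casual: float = 1.0967741935483871
    m_video: float = 1.7096774193548387
    cap: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (4,):
            raise ValueError("exactly four hours-category probabilities required")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.all(np.diff(p) >= -1e-12):
            raise ValueError("dose-response must be monotone non-decreasing")
        if self.m_casual < 1 or self.m_video < 1:
            raise ValueError("engagement multipliers must be >= 1")
        if not 0 < self.cap <= 1:
            raise ValueError("cap must lie in (0, 1]")

    def multiplier(self, engagement: str) -> float:
        if engagement not in ENGAGEMENT_LEVELS:
            raise ValueError(f"unknown engagement level {engagement!r}")
        return {"none": 1.0, "casual": self.m_casual, "video": self.m_video}[engagement]


@dataclass(frozen=True)
class CalibrationTargets:
    """Reported population prevalences the calibration reproduces."""

    baseline: float = 0.031
    scenario1: float = 0.003
    scenario2: float = 0.013
    scenario3: float = 0.035
    casual: float = 0.034
    video: float = 0.053

    def __post_init__(self) -> None:
        vals = (self.baseline, self.scenario1, self.scenario2,
                self.scenario3, self.casual, self.video)
        if any(not 0 < v < 1 for v in vals):
            raise ValueError("all calibration targets must lie in (0, 1)")


def ptsd_probability(
    prefers_tv: bool, hours_category: int | None, engagement: str, params: RiskParams
) -> float:
    """Per-agent PTSD probability from a media profile.

    Zero for agents not preferring TV; otherwise p_{category} times the
    engagement multiplier, capped.
    """
    if not prefers_tv:
        if hours_category is not None:
            raise ValueError("hours category set on an agent not preferring TV")
        return 0.0
    if hours_category not in (1, 2, 3, 4):
        raise ValueError(f"hours_category must be 1..4, got {hours_category}")
    return min(params.cap, params.p[hours_category - 1] * params.multiplier(engagement))


def assign_probabilities(population: pd.DataFrame, params: RiskParams) -> pd.DataFrame:
    """Vectorized ``ptsd_probability`` over the agent table; adds column
    ``ptsd_prob``.  Mutates and returns ``population``."""
    watches = population["prefers_tv"].fillna(False).to_numpy(dtype=bool)
    prob = np.zeros(len(population))
    if watches.any():
        hours = population.loc[watches, "hours_category"].to_numpy(dtype=np.int64)
        mult = (
            population.loc[watches, "engagement"]
            .map({"none": 1.0, "casual": params.m_casual, "video": params.m_video})
            .to_numpy(dtype=float)
        )
        prob[watches] = np.minimum(
            params.cap, np.asarray(params.p)[hours - 1] * mult
        )
    population["ptsd_prob"] = prob
    return population


def draw_ptsd(population: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Independent Bernoulli PTSD draw per agent from ``ptsd_prob``."""
    prob = population["ptsd_prob"].to_numpy(dtype=float)
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("PTSD probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    population["ptsd"] = rng.random(len(population)) < prob
    return population


def expected_prevalence(
    weights: HoursDistribution,
    params: RiskParams,
    f: float,
    engagement: str = "none",
) -> float:
    """Closed-form expected PTSD prevalence among tertiary agents:
    f * sum_i w_i * min(cap, p_i * m).  The analytic oracle for the
    Monte Carlo engine."""
    if not 0 <= f <= 1:
        raise ValueError("TV-preference fraction must lie in [0, 1]")
    m = params.multiplier(engagement)
    risks = np.minimum(params.cap, np.asarray(params.p) * m)
    return float(f * np.dot(weights.as_array(), risks))


def calibrate_params(
    targets: CalibrationTargets = CalibrationTargets(),
    p1: float = 0.008,
    p4: float = 0.101,
    baseline: HoursDistribution = BASELINE_HOURS,
) -> tuple[RiskParams, float]:
    """Recover (p2, p3, f) and the engagement multipliers from reported
    prevalences.

    With the endpoints p1, p4 fixed, the expected-prevalence equations for
    the baseline, lower-half-clamp and upper-half-clamp conditions

        f (w1 p1 + w2 p2 + w3 p3 + w4 p4)  = baseline
        f (w1 p1 + (w2+w3+w4) p2)          = scenario2
        f ((w1+w2+w3) p3 + w4 p4)          = scenario3

    are linear in (f, x, y) with x = f p2, y = f p3; solved exactly with a
    3x3 linear solve.  Multipliers are prevalence ratios:
    m_casual = casual/baseline, m_video = video/baseline.  scenario1 is not
    used — it serves as an out-of-sample check (f·p1 ≈ scenario1).

    Raises ``ValueError`` for a singular system, f outside (0, 1], or a
    non-monotone dose-response.
    """
    w = baseline.as_array()
    lower = w[1] + w[2] + w[3]  # mass clamped into the 4-7 h bin
    upper = w[0] + w[1] + w[2]  # mass clamped into the 8-11 h bin
    A = np.array(
        [
            [w[0] * p1 + w[3] * p4, w[1], w[2]],
            [w[0] * p1, lower, 0.0],
            [w[3] * p4, 0.0, upper],
        ]
    )
    b = np.array([targets.baseline, targets.scenario2, targets.scenario3])
    try:
        f, x, y = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"calibration system is singular: {err}") from err
    if not 0 < f <= 1:
        raise ValueError(f"calibrated TV-preference fraction f={f:.6f} not in (0, 1]")
    p2, p3 = x / f, y / f
    if not p1 <= p2 <= p3 <= p4:
        raise ValueError(
            f"calibrated dose-response not monotone: "
            f"({p1:.4f}, {p2:.4f}, {p3:.4f}, {p4:.4f})"
        )
    params = RiskParams(
        p=(p1, float(p2), float(p3), p4),
        m_casual=targets.casual / targets.baseline,
        m_video=targets.video / targets.baseline,
    )
    return params, float(f)
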