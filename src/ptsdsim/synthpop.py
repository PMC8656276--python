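"""Synthetic agent population generated from census marginal distributions.

The community population is synthesized from American Community Survey (ACS)
marginal tables: for each demographic attribute (sex, age band,
race/ethnicity, education) agents are sampled independently from the
attribute's categorical distribution.  Only marginals are matched — no joint
census microdata enters the model, so attributes are independent by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarginalTable",
    "load_marginals",
    "default_marginals",
    "generate_population",
    "marginal_report",
    "AGE_BANDS",
    "UNDER_20",
]

#: Age-band category labels, youngest first.
AGE_BANDS = ("under_20", "20_44", "45_64", "65_plus")
UNDER_20 = "under_20"

_REQUIRED_COLUMNS = ("attribute", "category", "proportion")
#: Attribute sums may deviate from 1 by at most this relative amount before
#: loading fails; smaller deviations are renormalized.
_SUM_TOLERANCE = 0.005
_EXACT_TOLERANCE = 1e-6


@dataclass(frozen=True)
class MarginalTable:
    """Target categorical distribution for each demographic attribute.

    ``table`` holds one row per (attribute, category) with a target
    proportion; proportions within each attribute sum to 1.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"marginal table missing columns: {missing}")
        if df.empty:
            raise ValueError("marginal table has no rows")
        if ((df["proportion"] < 0) | (df["proportion"] > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")
        for attr, grp in df.groupby("attribute", sort=False):
            if grp["category"].duplicated().any():
                raise ValueError(f"duplicate category labels in attribute {attr!r}")
            total = grp["proportion"].sum()
            if abs(total - 1.0) > _EXACT_TOLERANCE:
                raise ValueError(
                    f"proportions for attribute {attr!r} sum to {total:.6f}, not 1"
                )

    @property
    def attributes(self) -> list[str]:
        return list(dict.fromkeys(self.table["attribute"]))

    def categories(self, attribute: str) -> list[str]:
        sub = self.table[self.table["attribute"] == attribute]
        if sub.empty:
            raise KeyError(attribute)
        return list(sub["category"])

    def proportions(self, attribute: str) -> np.ndarray:
        sub = self.table[self.table["attribute"] == attribute]
        if sub.empty:
            raise KeyError(attribute)
        return sub["proportion"].to_numpy(dtype=float)


def load_marginals(path: str | Path) -> MarginalTable:
    """Read a marginal table from CSV (columns ``attribute,category,proportion``).

    Attribute proportions that sum to within 0.5% of 1 (e.g. printed
    percentages that lost a trailing digit) are renormalized; larger
    deviations raise ``ValueError``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marginal CSV {path} missing columns: {missing}")
    df = df[list(_REQUIRED_COLUMNS)].copy()
    df["proportion"] = df["proportion"].astype(float)
    if ((df["proportion"] < 0) | (df["proportion"] > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    for attr, grp in df.groupby("attribute", sort=False):
        total = grp["proportion"].sum()
        if abs(total - 1.0) > _SUM_TOLERANCE:
            raise ValueError(
                f"proportions for attribute {attr!r} sum to {total:.4f}; "
                f"more than 0.5% from 1"
            )
        df.loc[grp.index, "proportion"] = grp["proportion"] / total
    return MarginalTable(df.reset_index(drop=True))


def default_marginals(which: str = "acs") -> MarginalTable:
    """Packaged Table-1 marginals: ``acs`` targets or the published
    synthetic-population ``model`` column (regression reference)."""
    name = {"acs": "table1_acs.csv", "model": "table1_model.csv"}[which]
    with resources.as_file(resources.files("ptsdsim.data") / name) as p:
        return load_marginals(p)


def generate_population(
    marginals: MarginalTable, size: int, seed: int
) -> pd.DataFrame:
    """Sample ``size`` agents, each attribute independently from its marginal.

    Returns a DataFrame with an ``id`` column (0..size-1) and one categorical
    column per attribute.  Deterministic for a fixed seed.
    """
    if size < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {"id": np.arange(size, dtype=np.int64)}
    for attr in marginals.attributes:
        cats = marginals.categories(attr)
        probs = marginals.proportions(attr)
        codes = rng.choice(len(cats), size=size, p=probs / probs.sum())
        data[attr] = pd.Categorical.from_codes(codes, categories=cats)
    return pd.DataFrame(data)


def marginal_report(population: pd.DataFrame) -> pd.DataFrame:
    """Realized proportion of each category per attribute.

    Returns a DataFrame with columns ``attribute, category, proportion``;
    proportions within each attribute sum to 1.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    rows = []
    n = len(population)
    for col in population.columns:
        if col == "id" or not isinstance(population[col].dtype, pd.CategoricalDtype):
            continue
        counts = population[col].value_counts(sort=False)
        for cat, cnt in counts.items():
            rows.append((col, cat, cnt / n))
    return pd.DataFrame(rows, columns=["attribute", "category", "proportion"])


def write_population(population: pd.DataFrame, path: str | Path) -> None:
    """Export agents as CSV, one row per agent."""
    population.to_csv(path, index=False)
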