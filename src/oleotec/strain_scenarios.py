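"""Strain-performance literature table and derived productivity scenarios.

The packaged table collects published lipid titers (g/L), volumetric
productivities (g/L/hr), and mass yields (g/g) for oleaginous yeasts and
other lipid-producing microbes, one row per reported condition.  From the
titer distribution per carbon source, four named scenarios are derived:

* ``current_tech_high`` — the highest reported titer (state of the art),
* ``current_tech_base_case`` — the third quartile,
* ``current_tech_low`` — the mean,
* ``future_tech_high`` — the state-of-the-art titer extrapolated to the
  stoichiometric yield ceiling.

The published scenario numbers are not recoverable from the abridged table
as a whole (the selection behind them is not stated), so the selection
policy is an explicit parameter and the default ``authors_published`` rule
returns the published values directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .assumptions import (
    PUBLISHED_SCENARIO_TITERS,
    SCENARIO_YIELD_FRACTIONS,
    THEORETICAL_YIELDS,
    ProductivityScenario,
)

SCENARIO_ORDER = (
    "current_tech_low",
    "current_tech_base_case",
    "current_tech_high",
    "future_tech_high",
)


@dataclass(frozen=True)
class StrainRecord:
    """One published fermentation result."""

    strain: str
    titer_g_per_l: float
    feed: str
    productivity_g_per_l_per_hr: Optional[float] = None
    yield_g_per_g: Optional[float] = None
    source: str = ""


@dataclass(frozen=True)
class StrainSummary:
    """Average performance of one strain across its records.

    Missing fields are excluded from that field's mean, never imputed; a
    mean is None when no record reports the field.
    """

    strain: str
    mean_titer: float
    mean_productivity: Optional[float]
    mean_yield: Optional[float]
    n_records: int


def load_strain_table(path: Union[str, Path, None] = None) -> List[StrainRecord]:
    """Read a strain table (CSV with header strain,titer,productivity,yield,
    feed,source; "N/A" parsed as missing).  Without a path, the packaged
    literature table is loaded."""
    if path is None:
        ref = resources.files("oleotec.data").joinpath("strain_table.csv")
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, na_values=["N/A"])
    else:
        df = pd.read_csv(path, na_values=["N/A"])
    records = []
    for row in df.to_dict("records"):
        records.append(
            StrainRecord(
                strain=row["strain"],
                titer_g_per_l=float(row["titer"]),
                productivity_g_per_l_per_hr=(
                    None if pd.isna(row["productivity"]) else float(row["productivity"])
                ),
                yield_g_per_g=(
                    None if pd.isna(row["yield"]) else float(row["yield"])
                ),
                feed=row["feed"],
                source=str(row["source"]),
            )
        )
    return records


def summarize_by_strain(records: Sequence[StrainRecord]) -> List[StrainSummary]:
    """One summary per distinct strain, fields averaged over available data."""
    if not records:
        raise ValueError("empty record list")
    df = pd.DataFrame(
        {
            "strain": [r.strain for r in records],
            "titer": [r.titer_g_per_l for r in records],
            "productivity": pd.array(
                [r.productivity_g_per_l_per_hr for r in records], dtype="float64"
            ),
            "yield": pd.array(
                [r.yield_g_per_g for r in records], dtype="float64"
            ),
        }
    )
    # canonical row order makes float accumulation, and hence the summaries,
    # independent of the input record order
    df = df.sort_values(list(df.columns), na_position="last")
    out = []
    grouped = df.groupby("strain", sort=True)
    means = grouped.mean(numeric_only=True)
    counts = grouped.size()
    for strain, row in means.iterrows():
        out.append(
            StrainSummary(
                strain=strain,
                mean_titer=float(row["titer"]),
                mean_productivity=(
                    None if pd.isna(row["productivity"]) else float(row["productivity"])
                ),
                mean_yield=None if pd.isna(row["yield"]) else float(row["yield"]),
                n_records=int(counts[strain]),
            )
        )
    return out


def percent_theoretical_yield(
    yield_g_per_g: float, feed: str, theo: Dict[str, float]
) -> float:
    """Achieved fraction of the stoichiometric maximum yield for a feed."""
    if yield_g_per_g <= 0:
        raise ValueError("yield must be positive")
    if feed not in theo:
        raise KeyError(f"no theoretical yield for feed {feed!r}")
    frac = yield_g_per_g / theo[feed]
    if frac > 1:
        raise ValueError(
            f"yield {yield_g_per_g} g/g exceeds the theoretical maximum "
            f"{theo[feed]} g/g for {feed!r}: datum inconsistent with stoichiometry"
        )
    return frac


def derive_productivity_scenarios(
    records: Sequence[StrainRecord],
    theo: Dict[str, float] = THEORETICAL_YIELDS,
    subset_rule: str = "authors_published",
) -> List[ProductivityScenario]:
    """Derive the four named productivity scenarios.

    ``subset_rule="authors_published"`` bypasses computation and returns
    the published titers.  ``"all_records"`` computes from ``records``:
    high = max titer per feed, base = third quartile (linear interpolation
    between order statistics), low = mean, and future = high scaled by
    1 / (best observed fraction of theoretical yield) for that feed — the
    titer the best strain would reach at the stoichiometric ceiling.
    """
    if subset_rule == "authors_published":
        return [
            ProductivityScenario(
                name=name,
                titer_g_per_l=dict(PUBLISHED_SCENARIO_TITERS[name]),
                actual_yield_fraction=SCENARIO_YIELD_FRACTIONS[name],
            )
            for name in SCENARIO_ORDER
        ]
    if subset_rule != "all_records":
        raise ValueError(f"unknown subset_rule: {subset_rule!r}")

    titers: Dict[str, Dict[str, float]] = {name: {} for name in SCENARIO_ORDER}
    for feed in theo:
        feed_titers = [r.titer_g_per_l for r in records if r.feed == feed]
        if not feed_titers:
            raise ValueError(f"no records for feed {feed!r}")
        arr = np.sort(np.asarray(feed_titers, dtype=float))
        high = float(arr[-1])
        fractions = [
            percent_theoretical_yield(r.yield_g_per_g, feed, theo)
            for r in records
            if r.feed == feed and r.yield_g_per_g is not None
        ]
        best_fraction = max(fractions) if fractions else 1.0
        titers["current_tech_low"][feed] = float(arr.mean())
        titers["current_tech_base_case"][feed] = float(
            np.quantile(arr, 0.75, method="linear")
        )
        titers["current_tech_high"][feed] = high
        titers["future_tech_high"][feed] = high / best_fraction

    return [
        ProductivityScenario(
            name=name,
            titer_g_per_l=titers[name],
            actual_yield_fraction=SCENARIO_YIELD_FRACTIONS[name],
        )
        for name in SCENARIO_ORDER
    ]
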