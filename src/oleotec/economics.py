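"""Cost aggregation: COGS per kg, component shares, gross margins, and the
batch-vs-continuous cost delta.

Gross margin follows the commodity convention
``(revenue - COGS) / revenue * 100%`` on a per-tonne basis.  Results are
carried at full precision; rounding to display precision (costs to $1/MT
or $0.01/kg, margins to 0.1%) is left to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict

import pandas as pd

#: The closed cost-component vocabulary.
COMPONENT_KEYS = frozenset(
    {
        "raw_material",
        "preprocessing",
        "media",
        "labor",
        "depreciation",
        "facilities",
        "recovery",
        "consumables",
        "disposables",
        "waste",
        "other",
    }
)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-component annual USD costs plus the annual output they support."""

    components: Dict[str, float] = field(default_factory=dict)
    annual_output_mt: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.components) - COMPONENT_KEYS
        if unknown:
            raise ValueError(f"unknown cost components: {sorted(unknown)}")

    @property
    def total_usd_per_year(self) -> float:
        return sum(self.components.values())


def cogs_per_kg(b: CostBreakdown) -> float:
    """Cost of goods sold per kg: total annual cost over annual output."""
    if b.annual_output_mt <= 0:
        raise ZeroDivisionError("annual output must be positive")
    return b.total_usd_per_year / (b.annual_output_mt * 1000.0)


def cost_shares(b: CostBreakdown) -> Dict[str, float]:
    """Each component's fraction of total cost; fractions sum to 1."""
    total = b.total_usd_per_year
    if total <= 0:
        raise ZeroDivisionError("cost shares undefined for zero total cost")
    return {k: v / total for k, v in b.components.items()}


def gross_margin_pct(price_usd_per_mt: float, cogs_usd_per_mt: float) -> float:
    """Gross margin in percent: (price - COGS) / price * 100."""
    if price_usd_per_mt <= 0:
        raise ValueError("price must be positive")
    return (price_usd_per_mt - cogs_usd_per_mt) / price_usd_per_mt * 100.0


def mode_delta_pct(batch_cogs: float, continuous_cogs: float) -> float:
    """Percent cost decrease moving from batch to continuous operation."""
    if batch_cogs <= 0:
        raise ValueError("batch COGS must be positive")
    return (batch_cogs - continuous_cogs) / batch_cogs * 100.0


def load_commodity_scenario_table() -> pd.DataFrame:
    """Packaged commodity prices and per-scenario production costs (USD/MT).

    Columns: product, price_usd_per_mt, then one production-cost column per
    productivity scenario at the reference scale (SEA, 10 x 1.5M L, palm
    biomass feedstock).
    """
    with resources.files("oleotec.data").joinpath(
        "commodity_scenarios.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
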