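"""Annual operating-cost components.

Every component is linear in one driver quantity: raw material in feedstock
tonnage, preprocessing in raw tonnage, facilities in CapEx, media in liters
of media turned over, recovery in recovered lipid mass, waste handling in
feedstock tonnage.  Consumables and disposables are fixed annual charges.
Corporate tax is deliberately not a cost-of-goods component; it is reported
separately and is zero whenever the pre-tax margin is non-positive.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Dict

from pydantic import BaseModel, ConfigDict

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .assumptions import FeedstockProfile, PlantSpec
    from .fermentation import MassBalanceResult


class MiscOpexRates(BaseModel):
    """Unit costs for the smaller operating-cost lines.

    media is charged per liter of media per batch (continuous mode: per
    liter of media turned over at the dilution rate), recovery per kg of
    recovered lipid, waste handling per tonne of raw feedstock;
    consumables and disposables are flat annual charges.
    """

    model_config = ConfigDict(extra="forbid")

    media_usd_per_batch_l: float
    recovery_usd_per_kg_lipid: float
    consumables_usd_per_year: float
    disposables_usd_per_year: float
    waste_usd_per_mt_feedstock: float


def raw_material_cost(
    demand_mt: float, f: "FeedstockProfile", region: str
) -> float:
    """Annual feedstock purchase cost: tonnage x regional price."""
    if region not in f.regions_available:
        raise ValueError(
            f"feedstock {f.name!r} is not available in region {region!r}"
        )
    return demand_mt * f.price_usd_per_mt[region]


def preprocessing_cost(raw_mt: float, f: "FeedstockProfile") -> float:
    """Annual cost of converting raw feedstock to glucose; zero for direct sugars."""
    if f.category == "direct_sugar":
        return 0.0
    return raw_mt * f.preprocessing_cost_usd_per_mt


def facilities_cost(capex_usd: float, rate: float = 0.050) -> float:
    """Annual facilities expense (energy, waste treatment, maintenance).

    Modeled as a fixed fraction of capital expense, 5.0% by default.
    """
    if capex_usd <= 0:
        raise ValueError("capex_usd must be positive")
    return rate * capex_usd


def other_annual_cost(facilities_usd: float, rate: float = 0.169) -> float:
    """Other annual expenses (insurance, compliance, legal): 16.9% of facilities."""
    if facilities_usd < 0:
        raise ValueError("facilities_usd must be non-negative")
    return rate * facilities_usd


def misc_costs(
    mb: "MassBalanceResult", plant: "PlantSpec", rates: MiscOpexRates
) -> Dict[str, float]:
    """Media, recovery, consumables, disposables, and waste components (USD/yr).

    ``mb.batches_per_year`` counts media turnovers, so the media charge is
    comparable across batch and continuous operation.
    """
    return {
        "media": rates.media_usd_per_batch_l
        * plant.fermentation_capacity_l
        * mb.batches_per_year,
        "recovery": rates.recovery_usd_per_kg_lipid
        * mb.lipid_out_mt_per_year
        * 1000.0,
        "consumables": rates.consumables_usd_per_year,
        "disposables": rates.disposables_usd_per_year,
        "waste": rates.waste_usd_per_mt_feedstock
        * mb.raw_feedstock_demand_mt_per_year,
    }
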