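"""Input data model for the techno-economic engine.

An :class:`AssumptionSet` bundles everything one model run needs: regions
(salaries, tax rates), feedstocks (prices, preprocessing cost/efficiency,
yield drag, CapEx multiplier, availability), end products (commodity
prices, cost adjustment), strain-productivity scenarios (titer, yield
fractions), the CapEx/FTE scaling parameters, and the miscellaneous
operating-cost rates.

All monetary values are inflation-adjusted USD; no internal deflators are
applied.  The packaged default set (:func:`default_assumption_set`) carries
the published regional prices, preprocessing endpoints, facility/other
rates, scenario titers and capital multipliers; quantities the underlying
sources describe only qualitatively (salaries, misc OpEx unit rates,
preprocessing efficiencies, scenario yield fractions, default scaling
parameters) carry documented placeholder values and are listed in
``AssumptionSet.calibration_needed`` so downstream users know which numbers
to replace with plant-specific data.

Field-level structure is enforced at construction (unknown keys rejected);
domain rules (price positivity, the 3% yield-drag cap, referential
integrity, ...) are checked by :func:`validate_assumption_set`, which
returns violations as data so invalid sets can be inspected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .capex_labor import ScalingModel
from .opex import MiscOpexRates

SCHEMA_VERSION = 1

#: Stoichiometric maximum lipid yields, g lipid per g carbon source
#: (conversion to palmitic acid).
THEORETICAL_YIELDS = {"glucose": 0.35, "glycerol": 0.38}

FeedstockCategory = Literal["direct_sugar", "simple_waste", "lignocellulosic"]


class RegionProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    operator_salary_usd_per_year: float
    salary_multiplier: float = 2.0
    corporate_tax_rate: float


class FeedstockProfile(BaseModel):
    """A raw material: either a direct fermentation sugar or a waste stream
    converted to glucose during preprocessing."""

    model_config = ConfigDict(extra="forbid")

    name: str
    category: FeedstockCategory
    price_usd_per_mt: Dict[str, float]
    preprocessing_cost_usd_per_mt: float = 0.0
    preprocessing_efficiency_g_per_g: float = 1.0
    yield_drag_fraction: float = 0.0
    capex_multiplier: float = 1.0
    availability_cap_l: Optional[float] = None
    regions_available: List[str] = []

    @property
    def carbon_source(self) -> str:
        """The sugar actually fermented: the feedstock itself for direct
        sugars, glucose after preprocessing for everything else."""
        return self.name if self.category == "direct_sugar" else "glucose"


class ProductProfile(BaseModel):
    """An end market; price may be keyed by production region or carry a
    single ``all``-region entry."""

    model_config = ConfigDict(extra="forbid")

    name: str
    commodity_price_usd_per_mt: Dict[str, float]
    cost_adjustment_factor: float = 1.0

    def price(self, region: str) -> float:
        prices = self.commodity_price_usd_per_mt
        if region in prices:
            return prices[region]
        if "all" in prices:
            return prices["all"]
        raise KeyError(f"no price for product {self.name!r} in region {region!r}")


class ProductivityScenario(BaseModel):
    """A named strain-performance level: final titer per carbon source plus
    the achieved fraction of the stoichiometric yield."""

    model_config = ConfigDict(extra="forbid")

    name: str
    titer_g_per_l: Dict[str, float]
    actual_yield_fraction: float
    theoretical_yield_g_per_g: Dict[str, float] = dict(THEORETICAL_YIELDS)


class PlantSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fermentation_capacity_l: float
    n_reactors: int = 10
    region: str = "USA"
    feedstock: str = "glucose"
    mode: Literal["batch", "continuous"] = "batch"
    fermentation_days: float = 5.0
    turnaround_days: float = 1.0
    utilization_days_per_year: float = 330.0
    dilution_rate_per_day: float = 0.14
    recovery_yield_fraction: float = 0.95


class AssumptionSet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    regions: List[RegionProfile]
    feedstocks: List[FeedstockProfile]
    products: List[ProductProfile]
    scenarios: List[ProductivityScenario]
    capex_model_params: ScalingModel
    labor_model_params: ScalingModel
    misc_opex: MiscOpexRates
    facilities_rate: float = 0.050
    other_rate: float = 0.169
    depreciation_years: int = 20
    calibration_needed: List[str] = []

    # -- lookups ---------------------------------------------------------
    def region(self, name: str) -> RegionProfile:
        return _lookup(self.regions, name, "region")

    def feedstock(self, name: str) -> FeedstockProfile:
        return _lookup(self.feedstocks, name, "feedstock")

    def product(self, name: str) -> ProductProfile:
        return _lookup(self.products, name, "product")

    def scenario(self, name: str) -> ProductivityScenario:
        return _lookup(self.scenarios, name, "scenario")


def _lookup(items, name: str, kind: str):
    for it in items:
        if it.name == name:
            return it
    raise KeyError(f"unknown {kind}: {name!r}")


# ---------------------------------------------------------------------------
# Packaged default assumption set
# ---------------------------------------------------------------------------

#: Published scenario titers (g/L) by carbon source.
PUBLISHED_SCENARIO_TITERS = {
    "current_tech_low": {"glucose": 32.7, "glycerol": 7.86},
    "current_tech_base_case": {"glucose": 57.85, "glycerol": 13.73},
    "current_tech_high": {"glucose": 98.6, "glycerol": 23.6},
    "future_tech_high": {"glucose": 111.63, "glycerol": 26.88},
}

#: Achieved fraction of theoretical yield per scenario.  The future scenario
#: assumes 100% of stoichiometric yield; the current-technology fractions are
#: placeholder calibrations anchored on the spread of published g/g yields.
SCENARIO_YIELD_FRACTIONS = {
    "current_tech_low": 0.45,
    "current_tech_base_case": 0.66,
    "current_tech_high": 0.77,
    "future_tech_high": 1.0,
}


def _default_scenarios() -> List[ProductivityScenario]:
    return [
        ProductivityScenario(
            name=name,
            titer_g_per_l=dict(titers),
            actual_yield_fraction=SCENARIO_YIELD_FRACTIONS[name],
        )
        for name, titers in PUBLISHED_SCENARIO_TITERS.items()
    ]


def default_assumption_set() -> AssumptionSet:
    """The packaged default assumption set.

    Regional prices, preprocessing-cost endpoints, CapEx multipliers,
    facility/other rates, depreciation horizon, the bread-waste capacity
    cap and the four productivity scenarios are the published values.
    Bread-waste collection cost is a computed field: twice the palm-biomass
    (EFB) collection cost, reflecting the smaller aggregation scale of
    commercial bakeries versus palm mills.  Every placeholder is listed in
    ``calibration_needed``.
    """
    efb_price = 48.82
    return AssumptionSet(
        regions=[
            RegionProfile(
                name="USA", operator_salary_usd_per_year=45_000.0,
                corporate_tax_rate=0.26,
            ),
            RegionProfile(
                name="EU", operator_salary_usd_per_year=40_000.0,
                corporate_tax_rate=0.22,
            ),
            RegionProfile(
                name="SEA", operator_salary_usd_per_year=12_000.0,
                corporate_tax_rate=0.23,
            ),
        ],
        feedstocks=[
            FeedstockProfile(
                name="glucose", category="direct_sugar",
                price_usd_per_mt={"USA": 500.0, "EU": 500.0, "SEA": 400.0},
                capex_multiplier=0.86,
                regions_available=["USA", "EU", "SEA"],
            ),
            FeedstockProfile(
                name="glycerol", category="direct_sugar",
                price_usd_per_mt={"USA": 600.0, "EU": 600.0, "SEA": 500.0},
                capex_multiplier=0.86,
                regions_available=["USA", "EU", "SEA"],
            ),
            FeedstockProfile(
                name="corn_stover", category="lignocellulosic",
                price_usd_per_mt={"USA": 42.50},
                preprocessing_cost_usd_per_mt=80.34,
                preprocessing_efficiency_g_per_g=0.54,
                yield_drag_fraction=0.03,
                capex_multiplier=1.0,
                regions_available=["USA"],
            ),
            FeedstockProfile(
                name="sugar_beet", category="lignocellulosic",
                price_usd_per_mt={"EU": 52.70},
                preprocessing_cost_usd_per_mt=60.0,
                preprocessing_efficiency_g_per_g=0.16,
                yield_drag_fraction=0.02,
                capex_multiplier=1.0,
                regions_available=["EU"],
            ),
            FeedstockProfile(
                name="cassava", category="simple_waste",
                price_usd_per_mt={"SEA": 29.01},
                preprocessing_cost_usd_per_mt=45.0,
                preprocessing_efficiency_g_per_g=0.30,
                yield_drag_fraction=0.01,
                capex_multiplier=0.93,
                regions_available=["SEA"],
            ),
            FeedstockProfile(
                name="palm_biomass_efb", category="lignocellulosic",
                price_usd_per_mt={"SEA": efb_price},
                preprocessing_cost_usd_per_mt=65.0,
                preprocessing_efficiency_g_per_g=0.50,
                yield_drag_fraction=0.03,
                capex_multiplier=1.0,
                regions_available=["SEA"],
            ),
            FeedstockProfile(
                name="bread_waste", category="simple_waste",
                # computed rule: 2x the EFB collection cost
                price_usd_per_mt={r: 2 * efb_price for r in ("USA", "EU", "SEA")},
                preprocessing_cost_usd_per_mt=38.10,
                preprocessing_efficiency_g_per_g=0.72,
                yield_drag_fraction=0.01,
                capex_multiplier=0.93,
                availability_cap_l=4.5e6,
                regions_available=["USA", "EU", "SEA"],
            ),
        ],
        products=[
            ProductProfile(
                name="crude_palm_oil",
                commodity_price_usd_per_mt={"all": 875.0},
                cost_adjustment_factor=1.0,
            ),
            ProductProfile(
                name="high_oleic_oil",
                commodity_price_usd_per_mt={"all": 1006.0},
                cost_adjustment_factor=1.016,
            ),
            ProductProfile(
                name="low_ci_biofuel_oil",
                commodity_price_usd_per_mt={
                    "USA": 1389.0, "EU": 1307.0, "SEA": 1295.0
                },
                cost_adjustment_factor=0.999,
            ),
            ProductProfile(
                name="lauric_acid_75",
                commodity_price_usd_per_mt={"all": 1120.0},
                cost_adjustment_factor=1.071,
            ),
        ],
        scenarios=_default_scenarios(),
        # Placeholder power laws spanning the modeled 50k-15M L range:
        # CapEx ~= 700 * capacity^0.80 USD, FTEs ~= 0.3 * capacity^0.35.
        capex_model_params=ScalingModel(
            log_intercept=6.5511, exponent=0.80, r_squared=1.0, n_points=2
        ),
        labor_model_params=ScalingModel(
            log_intercept=-1.2040, exponent=0.35, r_squared=1.0, n_points=2
        ),
        misc_opex=MiscOpexRates(
            media_usd_per_batch_l=0.02,
            recovery_usd_per_kg_lipid=0.15,
            consumables_usd_per_year=200_000.0,
            disposables_usd_per_year=100_000.0,
            waste_usd_per_mt_feedstock=5.0,
        ),
        facilities_rate=0.050,
        other_rate=0.169,
        depreciation_years=20,
        calibration_needed=[
            "regions.*.operator_salary_usd_per_year",
            "regions.*.corporate_tax_rate",
            "feedstocks.*.preprocessing_efficiency_g_per_g",
            "feedstocks.sugar_beet.preprocessing_cost_usd_per_mt",
            "feedstocks.cassava.preprocessing_cost_usd_per_mt",
            "feedstocks.palm_biomass_efb.preprocessing_cost_usd_per_mt",
            "scenarios.current_tech_*.actual_yield_fraction",
            "capex_model_params",
            "labor_model_params",
            "misc_opex",
        ],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


class AssumptionFormatError(ValueError):
    """Raised when a config file cannot be parsed or fails schema checks."""


def write_assumption_set(a: AssumptionSet, path: Union[str, Path]) -> None:
    """Write a set as YAML in canonical (declaration) key order."""
    Path(path).write_text(
        yaml.safe_dump(a.model_dump(), sort_keys=False), encoding="utf-8"
    )


def load_assumption_set(path: Union[str, Path]) -> AssumptionSet:
    """Load and validate a YAML assumption set; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:  # carries line/column marks
        raise AssumptionFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise AssumptionFormatError(f"{path} does not contain a mapping")
    try:
        a = AssumptionSet.model_validate(raw)
    except ValidationError as exc:
        raise AssumptionFormatError(f"schema violation in {path}: {exc}") from exc
    violations = validate_assumption_set(a)
    if violations:
        raise AssumptionFormatError(
            f"invalid assumption set {path}: " + "; ".join(violations)
        )
    return a


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_assumption_set(a: AssumptionSet) -> List[str]:
    """Check every domain invariant; violations are returned as data.

    Each message names the type, field, and broken rule.  An empty list
    means the set is internally consistent.
    """
    v: List[str] = []
    region_names = {r.name for r in a.regions}

    for r in a.regions:
        if r.operator_salary_usd_per_year <= 0:
            v.append(f"RegionProfile {r.name}: operator_salary_usd_per_year must be > 0")
        if not (0 <= r.corporate_tax_rate < 1):
            v.append(f"RegionProfile {r.name}: corporate_tax_rate must be in [0, 1)")
        if r.salary_multiplier < 1:
            v.append(f"RegionProfile {r.name}: salary_multiplier must be >= 1")

    for f in a.feedstocks:
        for reg, p in f.price_usd_per_mt.items():
            if p < 0:
                v.append(f"FeedstockProfile {f.name}: price_usd_per_mt[{reg}] must be >= 0")
        if not (0 < f.preprocessing_efficiency_g_per_g <= 1):
            v.append(f"FeedstockProfile {f.name}: preprocessing_efficiency_g_per_g must be in (0, 1]")
        if not (0 <= f.yield_drag_fraction <= 0.03):
            v.append(f"FeedstockProfile {f.name}: yield_drag_fraction exceeds the 3% cap")
        if not (0 < f.capex_multiplier <= 1):
            v.append(f"FeedstockProfile {f.name}: capex_multiplier must be in (0, 1]")
        if f.availability_cap_l is not None and f.availability_cap_l <= 0:
            v.append(f"FeedstockProfile {f.name}: availability_cap_l must be positive")
        if f.category == "direct_sugar":
            if f.preprocessing_efficiency_g_per_g != 1.0:
                v.append(f"FeedstockProfile {f.name}: direct sugars require preprocessing_efficiency_g_per_g = 1")
            if f.preprocessing_cost_usd_per_mt != 0.0:
                v.append(f"FeedstockProfile {f.name}: direct sugars require preprocessing_cost_usd_per_mt = 0")
            if f.yield_drag_fraction != 0.0:
                v.append(f"FeedstockProfile {f.name}: direct sugars require yield_drag_fraction = 0")
        extra = set(f.regions_available) - region_names
        if extra:
            v.append(f"FeedstockProfile {f.name}: regions_available {sorted(extra)} not among declared regions")
        missing_prices = set(f.regions_available) - set(f.price_usd_per_mt)
        if missing_prices:
            v.append(f"FeedstockProfile {f.name}: price_usd_per_mt missing for {sorted(missing_prices)}")

    for p in a.products:
        for reg, price in p.commodity_price_usd_per_mt.items():
            if price <= 0:
                v.append(f"ProductProfile {p.name}: commodity_price_usd_per_mt[{reg}] must be > 0")
        if not (0.9 <= p.cost_adjustment_factor <= 1.1):
            v.append(f"ProductProfile {p.name}: cost_adjustment_factor must stay within a few percent of 1")

    for s in a.scenarios:
        for feed, t in s.titer_g_per_l.items():
            if t <= 0:
                v.append(f"ProductivityScenario {s.name}: titer_g_per_l[{feed}] must be > 0")
        if not (0 < s.actual_yield_fraction <= 1):
            v.append(f"ProductivityScenario {s.name}: actual_yield_fraction must be in (0, 1]")
        for feed, t in s.theoretical_yield_g_per_g.items():
            if t <= 0:
                v.append(f"ProductivityScenario {s.name}: theoretical_yield_g_per_g[{feed}] must be > 0")

    for label, model in (
        ("capex_model_params", a.capex_model_params),
        ("labor_model_params", a.labor_model_params),
    ):
        if model.n_points < 2:
            v.append(f"AssumptionSet.{label}: n_points must be >= 2")
        if not (0 <= model.r_squared <= 1):
            v.append(f"AssumptionSet.{label}: r_squared must be in [0, 1]")

    for field in (
        "media_usd_per_batch_l",
        "recovery_usd_per_kg_lipid",
        "consumables_usd_per_year",
        "disposables_usd_per_year",
        "waste_usd_per_mt_feedstock",
    ):
        if getattr(a.misc_opex, field) < 0:
            v.append(f"MiscOpexRates.{field} must be >= 0")

    if not (0 <= a.facilities_rate <= 1):
        v.append("AssumptionSet.facilities_rate must be in [0, 1]")
    if not (0 <= a.other_rate <= 1):
        v.append("AssumptionSet.other_rate must be in [0, 1]")
    if a.depreciation_years <= 0:
        v.append("AssumptionSet.depreciation_years must be > 0")

    return v
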