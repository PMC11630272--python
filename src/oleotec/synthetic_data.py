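"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the three external inputs the engine consumes: a
plant-build table (log-log linear CapEx-capacity relation with lognormal
noise), a strain-performance table (titers from a named distribution with
known population quantiles, yields bounded by stoichiometry), and a
perturbed assumption set (each cost input scaled by an independent factor,
always valid).  Each artifact type draws from its own seeded stream, so
adding or re-running one generator never perturbs another's output.

The generators reproduce the *structure* of the real inputs, not their
values: they make no attempt to mimic the actual published tables.
"""

from __future__ import annotations

from typing import Dict, List, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .assumptions import (
    THEORETICAL_YIELDS,
    AssumptionSet,
    default_assumption_set,
)
from .capex_labor import MODELED_CAPACITY_RANGE, BuildRecord
from .strain_scenarios import StrainRecord

# Per-artifact stream ids, combined with the user seed via SeedSequence.
_STREAMS = {"builds": 1, "strains": 2, "assumptions": 3}


class SyntheticSpec(BaseModel):
    """Parameters of the synthetic-data generators.

    ``capex_intercept``/``capex_exponent`` are the power-law ground truth;
    ``noise_sd_log`` the lognormal noise scale on CapEx.  ``titer_family``
    names the titer distribution (``lognormal``, ``uniform``, or ``point``)
    with ``titer_params`` its parameters.  ``assumption_perturbation`` is
    the relative half-range of the cost-input perturbation factors.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_builds: int = 40
    capex_intercept: float = 3.0
    capex_exponent: float = 0.62
    noise_sd_log: float = 0.15
    fte_intercept: float = 2.4
    fte_exponent: float = 0.35
    n_strains: int = 10
    records_per_strain: int = 5
    titer_family: Literal["lognormal", "uniform", "point"] = "lognormal"
    titer_params: Dict[str, float] = {"mean_log": 3.0, "sd_log": 0.6}
    glycerol_fraction: float = 0.2
    missing_rate: float = 0.1
    assumption_perturbation: float = 0.0


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAMS[stream]])


def gen_build_records(spec: SyntheticSpec) -> List[BuildRecord]:
    """Plant builds with log-uniform capacities over the modeled range and
    power-law CapEx (and FTEs) under multiplicative lognormal noise."""
    if spec.n_builds < 2:
        raise ValueError("n_builds must be >= 2")
    rng = _rng(spec, "builds")
    lo, hi = MODELED_CAPACITY_RANGE
    caps = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_builds))
    capex = (
        spec.capex_intercept
        * caps**spec.capex_exponent
        * np.exp(rng.normal(0.0, spec.noise_sd_log, size=spec.n_builds))
    )
    ftes = (
        spec.fte_intercept
        * caps**spec.fte_exponent
        * np.exp(rng.normal(0.0, spec.noise_sd_log, size=spec.n_builds))
    )
    regions = rng.choice(["USA", "EU", "SEA"], size=spec.n_builds)
    return [
        BuildRecord(
            capacity_l=float(c), capex_usd=float(x), ftes=float(f), region=str(r)
        )
        for c, x, f, r in zip(caps, capex, ftes, regions)
    ]


def _draw_titers(
    spec: SyntheticSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    p = spec.titer_params
    if spec.titer_family == "lognormal":
        return rng.lognormal(p["mean_log"], p["sd_log"], size=n)
    if spec.titer_family == "uniform":
        return rng.uniform(p["low"], p["high"], size=n)
    return np.full(n, p["value"])


def gen_strain_table(spec: SyntheticSpec) -> List[StrainRecord]:
    """Strain records with titers from the named family and yields bounded
    by each feed's stoichiometric maximum; missing values injected at
    ``missing_rate``."""
    if spec.n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = _rng(spec, "strains")
    records: List[StrainRecord] = []
    for i in range(spec.n_strains):
        feed = "glycerol" if rng.random() < spec.glycerol_fraction else "glucose"
        titers = _draw_titers(spec, rng, spec.records_per_strain)
        for t in titers:
            frac = rng.uniform(0.2, 0.95)
            yld: Optional[float] = frac * THEORETICAL_YIELDS[feed]
            prod: Optional[float] = float(t) / rng.uniform(48.0, 240.0)
            if rng.random() < spec.missing_rate:
                yld = None
            if rng.random() < spec.missing_rate:
                prod = None
            records.append(
                StrainRecord(
                    strain=f"strain_{i:02d}",
                    titer_g_per_l=float(t),
                    feed=feed,
                    productivity_g_per_l_per_hr=prod,
                    yield_g_per_g=yld,
                    source="synthetic",
                )
            )
    return records


def gen_assumption_set(spec: SyntheticSpec) -> AssumptionSet:
    """The default assumption set with every cost input scaled by an
    independent factor in [1 - p, 1 + p]; always passes validation."""
    p = spec.assumption_perturbation
    if not (0 <= p < 1):
        raise ValueError("assumption_perturbation must be in [0, 1)")
    rng = _rng(spec, "assumptions")
    a = default_assumption_set()

    def factor() -> float:
        return float(rng.uniform(1.0 - p, 1.0 + p))

    for r in a.regions:
        r.operator_salary_usd_per_year *= factor()
    for f in a.feedstocks:
        f.price_usd_per_mt = {
            k: v * factor() for k, v in f.price_usd_per_mt.items()
        }
        f.preprocessing_cost_usd_per_mt *= factor()
    m = a.misc_opex
    m.media_usd_per_batch_l *= factor()
    m.recovery_usd_per_kg_lipid *= factor()
    m.consumables_usd_per_year *= factor()
    m.disposables_usd_per_year *= factor()
    m.waste_usd_per_mt_feedstock *= factor()
    return a
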