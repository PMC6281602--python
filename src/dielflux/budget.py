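"""Ecosystem-scale interpretation: night-time TAG consumption partition,
caloric enrichment at dusk, and depth-integrated / global carbon flux.

These are deliberately simple interpretation models layered on top of the
measured rates.  The night partition treats phytoplankton self-respiration
and mortality (grazing plus lysis) as competing first-order sinks acting on
the day's TAG stock, under the constraint that total night consumption
returns the stock to its dawn baseline — consistent with stable dawn
concentrations over multi-day campaigns.  The caloric model follows the
classical lipid/protein/carbohydrate caloric-equivalent bookkeeping.
Global extrapolation multiplies a depth-integrated rate by habitat area and
days per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BudgetParams",
    "BudgetResult",
    "night_partition",
    "caloric_enrichment",
    "depth_integrate",
    "global_flux",
    "DEFAULT_CALORIC_EQUIVALENTS",
    "DEFAULT_GYRE_AREA_M2",
]

#: caloric equivalents, kcal per g, for (lipid, protein, carbohydrate)
DEFAULT_CALORIC_EQUIVALENTS: tuple[float, float, float] = (9.4, 5.65, 4.1)

#: subtropical gyres as ~40% of Earth's surface (5.10e14 m²)
DEFAULT_GYRE_AREA_M2: float = 0.40 * 5.10e14


@dataclass(frozen=True)
class BudgetParams:
    """Parameters of the downstream budget models.

    ``respiration_rate`` and ``mortality_rate`` are night-time first-order
    loss rates (d⁻¹) for producer self-respiration and for mortality
    processes; only their ratio matters for the partition.  Caloric
    equivalents are energy per mass for (lipid, protein, carbohydrate).
    """

    respiration_rate: float = 0.7
    mortality_rate: float = 0.3
    night_hours: float = 12.0
    caloric_equivalents: tuple[float, float, float] = DEFAULT_CALORIC_EQUIVALENTS
    gyre_area_m2: float = DEFAULT_GYRE_AREA_M2
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        if self.respiration_rate < 0 or self.mortality_rate < 0:
            raise ValueError("loss rates must be non-negative")
        lip, pro, carb = self.caloric_equivalents
        if min(lip, pro, carb) <= 0 or lip <= carb:
            raise ValueError("caloric equivalents must be positive with lipid > carbohydrate")


@dataclass(frozen=True)
class BudgetResult:
    frac_self_respired: float
    frac_mortality: float
    caloric_gain_pct: float
    depth_integrated_rate: float
    global_flux_pg_yr: float


def night_partition(params: BudgetParams) -> tuple[float, float]:
    """Fraction of the day's TAG production consumed by each night-time sink.

    Competing first-order losses scaled so that total night consumption
    equals daytime net production (the stock returns to its dawn baseline):
    the split is simply r/(r+m) and m/(r+m), invariant to common rescaling
    of the rates.
    """
    r, m = params.respiration_rate, params.mortality_rate
    if r + m <= 0:
        raise ValueError("at least one loss rate must be positive")
    return r / (r + m), m / (r + m)


def caloric_enrichment(
    dawn_composition: tuple[float, float, float],
    tag_added: float,
    caloric_equivalents: tuple[float, float, float] = DEFAULT_CALORIC_EQUIVALENTS,
) -> float:
    """Percent increase in calories per dawn dry mass from daytime TAG gain.

    ``dawn_composition`` is (lipid, protein, carbohydrate) mass fractions of
    dawn dry mass (sum ≤ 1, remainder caloric-neutral ash/other);
    ``tag_added`` is the added lipid mass as a fraction of dawn dry mass,
    with the other pools unchanged.  Monotone increasing in both
    ``tag_added`` and the lipid caloric equivalent.
    """
    comp = np.asarray(dawn_composition, dtype=float)
    eq = np.asarray(caloric_equivalents, dtype=float)
    if np.any(comp < 0) or tag_added < 0:
        raise ValueError("fractions and added TAG mass must be non-negative")
    if comp.sum() > 1 + 1e-9:
        raise ValueError("dawn mass fractions must sum to <= 1")
    dawn_cal = float(comp @ eq)
    if dawn_cal <= 0:
        raise ValueError("dawn composition has no caloric content")
    dusk_cal = dawn_cal + tag_added * eq[0]
    return 100.0 * (dusk_cal - dawn_cal) / dawn_cal


def depth_integrate(depths, rates) -> float:
    """Trapezoidal depth integral of a volumetric rate (per m³ → per m²).

    Integrates from the shallowest depth down to the first depth where the
    rate is non-positive (rate clamped to 0 at that endpoint), or to the end
    of the profile; deeper points are outside the production layer by
    construction.
    """
    z = np.asarray(depths, dtype=float)
    r = np.asarray(rates, dtype=float)
    if z.size != r.size or z.size < 2:
        raise ValueError("need >=2 (depth, rate) points")
    if np.any(np.diff(z) <= 0):
        raise ValueError("depths must be strictly ascending")
    nonpos = np.flatnonzero(r <= 0)
    if nonpos.size:
        end = nonpos[0]
        if end == 0:
            return 0.0
        z, r = z[: end + 1], np.maximum(r[: end + 1], 0.0)
    return float(np.trapezoid(r, z))


def global_flux(
    depth_integrated_rate: float,
    gyre_area_m2: float = DEFAULT_GYRE_AREA_M2,
    days_per_year: float = 365.0,
) -> float:
    """Annual flux in Pg C yr⁻¹ from a rate in mg C m⁻² d⁻¹.

    flux = rate × area × days × 10⁻¹⁸ (mg → Pg); exactly linear in each
    argument.
    """
    if min(depth_integrated_rate, gyre_area_m2, days_per_year) < 0:
        raise ValueError("inputs must be non-negative")
    return depth_integrated_rate * gyre_area_m2 * days_per_year * 1.0e-18
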