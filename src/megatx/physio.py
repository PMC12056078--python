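"""Gas-fermentation physiology: N2-referenced gas rates, yields, stoichiometry,
growth rate and carbon balance for chemostat and batch cultures.

Conventions follow standard acetogen chemostat practice:

* Specific rates q are in mmol per gram dry biomass per hour, with uptake
  positive and production negative.  On CO the water-gas shift makes q_H2
  and q_CO2 negative (net production) while q_CO stays positive.
* In a chemostat at steady state the specific growth rate equals the
  dilution rate D (h^-1), so the biomass yield on a substrate is
  Y_X/S = 1000 * D / q_S (g mol^-1).
* Off-gas compositions are referenced to the inert N2 fraction: N2 is
  neither consumed nor produced, so the outlet molar flow is
  inlet_flow * y_N2_in / y_N2_out, which makes every rate invariant to a
  consistent rescaling of the outlet stream (volume change correction).
* The carbon balance is the carbon leaving in products and biomass divided
  by the carbon entering in substrates, in percent.  Biomass carbon uses a
  configurable grams-per-Cmol (default 25.0, the standard CH1.8O0.5N0.2
  assumption) since elemental composition is rarely measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError

M_ACETATE = 60.05  # g mol^-1

#: carbon atoms per mole of each species
CARBON_ATOMS = {"H2": 0, "CO2": 1, "CO": 1, "acetate": 2, "N2": 0}


@dataclass(frozen=True)
class PhysioParams:
    acetate_molar_mass: float = M_ACETATE
    biomass_g_per_cmol: float = 25.0
    carbon_atoms: dict = field(default_factory=lambda: dict(CARBON_ATOMS))

    def __post_init__(self):
        if self.acetate_molar_mass <= 0 or self.biomass_g_per_cmol <= 0:
            raise InvalidInputError("molar masses must be positive")


@dataclass(frozen=True)
class SteadyStateRecord:
    """One steady-state chemostat condition.

    Gas rates are signed (uptake positive, production negative); ``q_ace``
    is the acetate formation rate reported as a positive magnitude, or None
    to have it computed from titer and dilution rate.
    """

    strain: str
    gas: str
    dilution_rate: float  # D, h^-1
    biomass: float  # g L^-1
    acetate: float  # g L^-1
    q_h2: float | None = None
    q_co2: float | None = None
    q_co: float | None = None
    q_ace: float | None = None

    def __post_init__(self):
        if self.dilution_rate <= 0:
            raise InvalidInputError("dilution rate must be positive")
        if self.biomass <= 0:
            raise InvalidInputError("biomass must be positive")
        if self.acetate < 0:
            raise InvalidInputError("acetate concentration must be >= 0")


@dataclass(frozen=True)
class GcObservation:
    """Inlet/outlet gas-chromatography mole fractions plus process state."""

    inlet_fractions: dict  # species -> mole fraction in [0, 1]
    outlet_fractions: dict
    inlet_flow: float  # mmol h^-1
    broth_volume: float  # L
    biomass: float  # g L^-1

    def __post_init__(self):
        for name, fractions in (
            ("inlet", self.inlet_fractions),
            ("outlet", self.outlet_fractions),
        ):
            if any(not 0 <= y <= 1 for y in fractions.values()):
                raise InvalidInputError(f"{name} mole fractions must lie in [0, 1]")
            if sum(fractions.values()) > 1 + 1e-9:
                raise InvalidInputError(f"{name} mole fractions sum above 1")
        if self.inlet_fractions.get("N2", 0) <= 0 or self.outlet_fractions.get("N2", 0) <= 0:
            raise InvalidInputError("N2 must be present in both streams (internal standard)")
        if self.inlet_flow <= 0 or self.broth_volume <= 0 or self.biomass <= 0:
            raise InvalidInputError("flow, volume and biomass must be positive")


@dataclass(frozen=True)
class GrowthCurve:
    """An OD time series with the exponential-phase fit window, in hours."""

    times: tuple
    od: tuple
    window: tuple  # (t_start, t_end)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if len(self.od) != t.size:
            raise InvalidInputError("times and OD lengths differ")
        lo, hi = self.window
        if lo >= hi or lo < t[0] or hi > t[-1]:
            raise InvalidInputError("fit window must lie within the time range")


def gas_rates_from_gc(obs: GcObservation) -> dict[str, float]:
    """Signed specific gas rates (mmol g^-1 h^-1) from one GC observation.

    The outlet flow follows from N2 conservation, and
    q_i = (inlet_flow * y_i_in - outlet_flow * y_i_out) / (V * X); N2's own
    rate is exactly zero by construction.
    """
    y_n2_out = obs.outlet_fractions["N2"]
    outlet_flow = obs.inlet_flow * obs.inlet_fractions["N2"] / y_n2_out
    vx = obs.broth_volume * obs.biomass
    species = set(obs.inlet_fractions) | set(obs.outlet_fractions)
    rates = {}
    for sp in species:
        inflow = obs.inlet_flow * obs.inlet_fractions.get(sp, 0.0)
        outflow = outlet_flow * obs.outlet_fractions.get(sp, 0.0)
        rates[sp] = (inflow - outflow) / vx
    rates["N2"] = 0.0
    return rates


def specific_acetate_rate(
    rec: SteadyStateRecord, params: PhysioParams = PhysioParams()
) -> float:
    """q_Ace = 1000 * D * c_Ace / (M_acetate * X), feed acetate assumed zero."""
    return 1000.0 * rec.dilution_rate * rec.acetate / (
        params.acetate_molar_mass * rec.biomass
    )


def yield_acetate_per_biomass(
    rec: SteadyStateRecord, params: PhysioParams = PhysioParams()
) -> float:
    """Y_Ace/X = c_Ace / (M_acetate * X) in mol g^-1, to 2 decimals."""
    return round(rec.acetate / (params.acetate_molar_mass * rec.biomass), 2)


def yield_biomass_per_substrate(rec: SteadyStateRecord, substrate: str) -> float:
    """Y_X/S = 1000 * D / q_S in g mol^-1; requires net uptake (q_S > 0)."""
    q = _rate(rec, substrate)
    if q is None or q <= 0:
        raise InvalidInputError(
            f"{substrate} is not being consumed (q={q}); biomass yield undefined"
        )
    return 1000.0 * rec.dilution_rate / q


def substrate_per_acetate(rec: SteadyStateRecord, substrate: str) -> float:
    """Moles of substrate consumed per mole of acetate formed, to 1 decimal."""
    q_ace = rec.q_ace if rec.q_ace is not None else specific_acetate_rate(rec)
    if q_ace <= 0:
        raise InvalidInputError("acetate formation rate must be positive")
    q = _rate(rec, substrate)
    if q is None:
        raise InvalidInputError(f"no rate recorded for {substrate}")
    return round(q / q_ace, 1)


def carbon_balance(
    rec: SteadyStateRecord, params: PhysioParams = PhysioParams()
) -> float:
    """Carbon recovery in percent: (products + acetate + biomass C) / uptake C.

    Signed gas rates sort themselves: positive rates contribute carbon in,
    negative rates carbon out.  Biomass carbon is 1000 * D / (g per Cmol)
    mmol C g^-1 h^-1.
    """
    uptake_c = 0.0
    produced_c = 0.0
    for sp, key in (("H2", "q_h2"), ("CO2", "q_co2"), ("CO", "q_co")):
        q = getattr(rec, key)
        if q is None:
            continue
        n_c = params.carbon_atoms[sp]
        if q > 0:
            uptake_c += q * n_c
        else:
            produced_c += abs(q) * n_c
    q_ace = rec.q_ace if rec.q_ace is not None else specific_acetate_rate(rec)
    produced_c += q_ace * params.carbon_atoms["acetate"]
    produced_c += 1000.0 * rec.dilution_rate / params.biomass_g_per_cmol
    if uptake_c <= 0:
        raise InvalidInputError("no net carbon uptake; carbon balance undefined")
    return 100.0 * produced_c / uptake_c


def growth_rate(curve: GrowthCurve) -> tuple[float, float]:
    """(mu in h^-1, doubling time in h) from ln(OD) vs time in the fit window.

    mu is the least-squares slope of ln(OD) against time restricted to the
    exponential-phase window; the doubling time is ln(2)/mu, reported to one
    decimal as is customary.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    lo, hi = curve.window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise InvalidInputError("need at least 3 points inside the fit window")
    if np.any(od[mask] <= 0):
        raise InvalidInputError("non-positive OD inside the fit window")
    fit = stats.linregress(t[mask], np.log(od[mask]))
    mu = float(fit.slope)
    if mu <= 0:
        raise InvalidInputError("no positive growth in the fit window")
    return mu, round(math.log(2) / mu, 1)


def doubling_time(mu: float) -> float:
    """ln(2)/mu in hours, to one decimal."""
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    return round(math.log(2) / mu, 1)


def steady_state_report(
    rec: SteadyStateRecord, params: PhysioParams = PhysioParams()
) -> dict:
    """The derived quantities for one record, mirroring a chemostat table row."""
    out = {
        "strain": rec.strain,
        "gas": rec.gas,
        "D_per_h": rec.dilution_rate,
        "biomass_g_per_l": rec.biomass,
        "acetate_g_per_l": rec.acetate,
        "q_ace_mmol_per_g_h": round(specific_acetate_rate(rec, params), 1),
        "y_ace_per_biomass_mol_per_g": yield_acetate_per_biomass(rec, params),
    }
    for substrate, key in (("CO", "q_co"), ("H2", "q_h2"), ("CO2", "q_co2")):
        q = getattr(rec, key)
        out[f"q_{substrate.lower()}_mmol_per_g_h"] = q
        if q is not None and q > 0:
            out[f"y_biomass_per_{substrate.lower()}_g_per_mol"] = round(
                yield_biomass_per_substrate(rec, substrate), 2
            )
            out[f"{substrate.lower()}_per_acetate"] = substrate_per_acetate(
                rec, substrate
            )
    try:
        out["c_balance_pct"] = round(carbon_balance(rec, params), 1)
    except InvalidInputError:
        out["c_balance_pct"] = None
    return out


def _rate(rec: SteadyStateRecord, substrate: str) -> float | None:
    key = {"H2": "q_h2", "CO2": "q_co2", "CO": "q_co"}.get(substrate)
    if key is None:
        raise InvalidInputError(f"unknown substrate {substrate!r}")
    return getattr(rec, key)
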