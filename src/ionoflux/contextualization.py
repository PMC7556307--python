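"""Turn culture conditions and strain measurements into flux constraints.

A shake-flask phenotype — specific growth rate μ (h⁻¹), specific CO2
evolution rate (mmol/gDCW/h), carotenoid yields (mg/gDCW) and the secreted
β-ionone titer (mg/L) — is converted into interval constraints on the
pathway-extended model: growth and CO2 exchange are pinned to the measured
rates, each carotenoid accumulation sink to the flux equivalent of its
yield, and the β-ionone exchange to the titer-derived specific rate.

Measured values become intervals of half-width ``tol_frac`` (default 5%)
around the measurement, not equalities: strict equalities on noisy
measurements routinely make the LP infeasible.  Every constraint carries a
provenance note naming the measurement field it came from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model_io import DEFAULT_BOUND, MetabolicModel, ModelError, carbon_count
from .pathway_extension import (
    CAROTENOID_SINKS,
    EX_BIONONE,
    PATHWAY_FORMULAS,
    SINK_APO27,
    SINK_C14DIAL,
    PathwaySpec,
    molar_mass,
    yield_to_specific_rate,
)

logger = logging.getLogger(__name__)

# Canonical reaction ids for the growth context (the toy host uses these;
# override the keyword arguments for other model dialects).
EX_GLUCOSE = "EX_glc__D_e"
EX_O2 = "EX_o2_e"
EX_CO2 = "EX_co2_e"
ATPM = "ATPM"

#: Default non-growth-associated maintenance, mmol ATP/gDCW/h (consensus
#: value used by curated yeast reconstructions).
DEFAULT_NGAM = 0.7

#: Literature fallback rates for aerobic batch growth of S. cerevisiae on
#: glucose, used — and flagged — only when a measurement row lacks them.
DEFAULT_AEROBIC_RATES: dict[str, float] = {
    "mu": 0.37,          # h^-1, respiro-fermentative batch growth
    "q_co2": 22.0,       # mmol/gDCW/h
    "glucose_uptake": 15.0,  # mmol/gDCW/h
}


class MeasurementError(ValueError):
    """Raised for inconsistent or incomplete strain measurements."""


@dataclass
class StrainMeasurement:
    """One strain's shake-flask phenotype.

    Optional fields are ``None`` when not measured; downstream stages that
    need them fail with a message naming the missing field rather than
    substituting silently.
    """

    strain_id: str
    mu: float | None = None                      # h^-1
    q_co2: float | None = None                   # mmol/gDCW/h
    biomass_conc: float | None = None            # gDCW/L at harvest
    total_carotenoids: float = 0.0               # mg/gDCW
    frac_beta_carotene: float = 1.0              # fractions of total
    frac_lycopene: float = 0.0
    frac_phytoene: float = 0.0
    ionone_titer: float | None = None            # mg/L
    culture_time: float | None = None            # h
    glucose_uptake_exp: float | None = None      # mmol/gDCW/h, literature-derived

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and math.isnan(v):
                setattr(self, f.name, None if f.name in _OPTIONAL else 0.0)
        for name in ("mu", "q_co2", "biomass_conc", "total_carotenoids",
                     "frac_beta_carotene", "frac_lycopene", "frac_phytoene",
                     "ionone_titer", "culture_time", "glucose_uptake_exp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise MeasurementError(f"{self.strain_id}: {name} negative ({v})")
        frac_sum = self.frac_beta_carotene + self.frac_lycopene + self.frac_phytoene
        if frac_sum > 1 + 1e-9:
            raise MeasurementError(
                f"{self.strain_id}: carotenoid profile fractions sum to {frac_sum:.4f} > 1"
            )

    def species_yield(self, species: str) -> float:
        """Yield of one carotenoid species, mg/gDCW."""
        frac = getattr(self, f"frac_{species}")
        return self.total_carotenoids * frac


_OPTIONAL = {"mu", "q_co2", "biomass_conc", "ionone_titer", "culture_time",
             "glucose_uptake_exp"}

_TABLE_COLUMNS = [f.name for f in dataclass_fields(StrainMeasurement)]


def read_measurements(path: str | Path) -> list[StrainMeasurement]:
    """Read a comma-delimited strain measurement table (one row per strain).

    The header must use the field names of :class:`StrainMeasurement`;
    missing optional fields may be empty.
    """
    df = pd.read_csv(path, comment="#")
    unknown = set(df.columns) - set(_TABLE_COLUMNS)
    if unknown:
        raise MeasurementError(f"{path}: unknown columns {sorted(unknown)}")
    if "strain_id" not in df.columns:
        raise MeasurementError(f"{path}: missing strain_id column")
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if not pd.isna(row[k])}
        kwargs["strain_id"] = str(kwargs["strain_id"])
        out.append(StrainMeasurement(**kwargs))
    return out


def write_measurements(measurements: list[StrainMeasurement], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{k: getattr(m, k) for k in _TABLE_COLUMNS} for m in measurements],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


@dataclass
class ContextConstraints:
    """The interval constraints applied to a model, with provenance."""

    entries: list[tuple[str, float, float, str]] = field(default_factory=list)
    tol_frac: float = 0.05

    def add(self, reaction_id: str, lower: float, upper: float, note: str) -> None:
        if lower > upper:
            raise ModelError(f"{reaction_id}: inverted interval [{lower}, {upper}]")
        self.entries.append((reaction_id, lower, upper, note))

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        out = model.copy()
        for rid, lo, hi, _ in self.entries:
            out.set_bounds(rid, lo, hi)
        return out


def apply_growth_context(
    model: MetabolicModel,
    ngam: float = DEFAULT_NGAM,
    glucose_exchange: str = EX_GLUCOSE,
    o2_exchange: str = EX_O2,
    co2_exchange: str = EX_CO2,
    maintenance: str = ATPM,
) -> MetabolicModel:
    """Configure aerobic growth on glucose as the sole carbon source.

    Closes uptake through every carbon-carrying exchange except glucose,
    opens O2 uptake and CO2 export, and sets the maintenance ATP floor.
    Fermentation-product exports stay open (only uptake is closed).
    """
    for rid in (glucose_exchange, o2_exchange, co2_exchange, maintenance):
        if rid not in model.reactions:
            raise ModelError(f"growth context needs reaction {rid!r}, not in model")
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind != "exchange" or rxn.id == glucose_exchange:
            continue
        (met_id,) = rxn.stoichiometry
        met = out.metabolites[met_id]
        if met.formula is None:
            raise ModelError(
                f"exchange {rxn.id}: metabolite {met_id} has no formula; "
                "cannot decide whether it is a carbon source"
            )
        if carbon_count(met) > 0 and rxn.lower_bound < 0:
            out.set_bounds(rxn.id, 0.0, rxn.upper_bound)
    out.set_bounds(o2_exchange, -DEFAULT_BOUND, DEFAULT_BOUND)
    out.set_bounds(co2_exchange, 0.0, DEFAULT_BOUND)
    atpm = out.reactions[maintenance]
    out.set_bounds(maintenance, ngam, max(atpm.upper_bound, ngam))
    return out


def titer_to_specific_rate(
    titer_mg_l: float,
    biomass_conc: float | None,
    culture_time: float | None,
    mu: float | None,
    molar_mass_g_per_mol: float,
    mode: str = "endpoint",
) -> float:
    """Convert a culture titer (mg/L) to a biomass-specific rate (mmol/gDCW/h).

    ``endpoint``: average rate over the culture, titer/(X·t·M) — appropriate
    for a product secreted and captured over the whole cultivation.
    ``growth_coupled``: instantaneous growth-proportional rate μ·titer/(X·M).
    """
    if titer_mg_l < 0:
        raise MeasurementError("titer must be non-negative")
    if molar_mass_g_per_mol <= 0:
        raise MeasurementError("molar mass must be positive")
    if titer_mg_l == 0:
        return 0.0
    if biomass_conc is None or biomass_conc <= 0:
        raise MeasurementError("titer conversion needs a positive biomass_conc")
    if mode == "endpoint":
        if culture_time is None or culture_time <= 0:
            raise MeasurementError("endpoint mode needs a positive culture_time")
        return titer_mg_l / (biomass_conc * culture_time * molar_mass_g_per_mol)
    if mode == "growth_coupled":
        if mu is None or mu < 0:
            raise MeasurementError("growth_coupled mode needs mu")
        return mu * titer_mg_l / (biomass_conc * molar_mass_g_per_mol)
    raise MeasurementError(f"unknown titer mode {mode!r}")


def _interval(center: float, tol_frac: float) -> tuple[float, float]:
    half = abs(center) * tol_frac
    return center - half, center + half


def constrain_strain(
    model: MetabolicModel,
    measurement: StrainMeasurement,
    spec: PathwaySpec,
    tol_frac: float = 0.05,
    ionone_mode: str = "endpoint",
    co2_exchange: str = EX_CO2,
) -> tuple[MetabolicModel, ContextConstraints]:
    """Constrain a pathway-extended, growth-contextualized model to one strain.

    Returns a new model plus the constraint set (reaction, lower, upper,
    provenance).  Growth and CO2 are pinned to μ and q_CO2; each measured
    carotenoid sink to its yield-derived rate; the β-ionone exchange to the
    titer-derived rate (or 0 when no titer is reported, since the exchange
    would otherwise leak unmeasured product); the unmeasured cleavage
    co-product sinks (C14 dialdehyde, C27 apocarotenal) are left free.
    """
    if measurement.mu is None or measurement.q_co2 is None:
        raise MeasurementError(
            f"{measurement.strain_id}: contextualization needs mu and q_co2 "
            "(supply them or use the flagged literature defaults)"
        )
    if not model.objective_reaction:
        raise ModelError("model has no objective (growth) reaction")
    cons = ContextConstraints(tol_frac=tol_frac)
    mu = measurement.mu
    cons.add(model.objective_reaction, *_interval(mu, tol_frac), "mu")
    cons.add(co2_exchange, *_interval(measurement.q_co2, tol_frac), "q_co2")

    for species, sink_id in CAROTENOID_SINKS.items():
        if sink_id not in model.reactions:
            continue
        rate = yield_to_specific_rate(
            measurement.species_yield(species), mu, spec.molar_masses[species]
        )
        if rate > 0:
            lo, hi = _interval(rate, tol_frac)
            cons.add(sink_id, lo, hi,
                     f"total_carotenoids * frac_{species} (growth-coupled)")
        else:
            cons.add(sink_id, 0.0, 0.0, f"frac_{species} = 0")

    for sink_id in (SINK_C14DIAL, SINK_APO27):
        if sink_id in model.reactions:
            cons.add(sink_id, 0.0, DEFAULT_BOUND, "unmeasured cleavage co-product, free")

    if EX_BIONONE in model.reactions:
        if measurement.ionone_titer is not None:
            rate = titer_to_specific_rate(
                measurement.ionone_titer,
                measurement.biomass_conc,
                measurement.culture_time,
                mu,
                molar_mass(PATHWAY_FORMULAS["beta_ionone"]),
                mode=ionone_mode,
            )
            cons.add(EX_BIONONE, *_interval(rate, tol_frac),
                     f"ionone_titer ({ionone_mode})")
        else:
            cons.add(EX_BIONONE, 0.0, 0.0, "no ionone titer measured")

    constrained = cons.apply(model)
    return constrained, cons


def with_defaults(
    measurement: StrainMeasurement,
    defaults: Mapping[str, float] = DEFAULT_AEROBIC_RATES,
) -> StrainMeasurement:
    """Fill missing μ / q_CO2 / glucose uptake from the literature table,
    logging each substitution so reports can flag it."""
    updates = {}
    if measurement.mu is None:
        updates["mu"] = defaults["mu"]
    if measurement.q_co2 is None:
        updates["q_co2"] = defaults["q_co2"]
    if measurement.glucose_uptake_exp is None:
        updates["glucose_uptake_exp"] = defaults["glucose_uptake"]
    if not updates:
        return measurement
    for k, v in updates.items():
        logger.warning("%s: %s not measured, using literature default %g",
                       measurement.strain_id, k, v)
    kwargs = {f.name: getattr(measurement, f.name)
              for f in dataclass_fields(StrainMeasurement)}
    kwargs.update(updates)
    return StrainMeasurement(**kwargs)
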