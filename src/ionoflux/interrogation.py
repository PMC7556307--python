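"""Model interrogation: the four derived analyses on a contextualized model.

1. **Minimal glucose uptake** — with growth, CO2 and product rates pinned to
   the measurements, the smallest glucose uptake able to support them; its
   relative error against the literature uptake gauges model fidelity (this
   amounts to optimizing the biomass yield on glucose).
2. **Carbon recovery** — the fraction of consumed substrate carbon accounted
   for by the measured outputs (biomass, CO2, carotenoids, β-ionone); a low
   closure (< ~80%) precludes meaningful flux conclusions.
3. **Counterfactual maximum β-ionone yield** — the β-carotene production the
   model could have achieved without any cleavage, minus the observed
   accumulation, gives the carbon divertible to cleavage; maximizing
   β-ionone under that cap yields the ceiling against which the observed
   titer is compared (the *departure* from optimal cleavage).
4. **C14:ionone molar ratio** — in the optimal cleavage scenario, moles of
   C14 dialdehyde co-product per mole of β-ionone; pure double cleavage
   pins it at 1:2 (0.5), so smaller values diagnose single-site cleavage
   or activity on upstream substrates.

All flux-derived statistics are computed on the parsimonious optimum
(minimum total absolute flux), because FBA optima are degenerate; the
degeneracy breadth of the ratio is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .contextualization import (
    EX_GLUCOSE,
    ContextConstraints,
    MeasurementError,
    StrainMeasurement,
    constrain_strain,
    titer_to_specific_rate,
)
from .fba_core import (
    REL_TOL,
    FluxSolution,
    InfeasibleError,
    LinearConstraint,
    minimize_total_flux,
    optimize,
)
from .model_io import DEFAULT_BOUND, MetabolicModel, ModelError, carbon_count
from .pathway_extension import (
    EX_BIONONE,
    PATHWAY_FORMULAS,
    RXN_CCD1_DOUBLE,
    RXN_CCD1_SINGLE,
    SINK_BCAROTENE,
    CAROTENOID_SINKS,
    PathwaySpec,
    cleavage_reaction_ids,
    molar_mass,
    yield_to_specific_rate,
)


class InterrogationError(RuntimeError):
    """A procedure could not be carried out on this strain/model combination."""


def predict_min_glucose(
    constrained_model: MetabolicModel, glucose_exchange: str = EX_GLUCOSE
) -> tuple[float, FluxSolution]:
    """Minimal glucose uptake supporting the strain constraints.

    Glucose uptake is a negative exchange flux, so minimizing uptake is
    maximizing the exchange flux; the returned rate is its magnitude.  The
    retained solution is the parsimonious one.
    """
    if glucose_exchange not in constrained_model.reactions:
        raise ModelError(f"no glucose exchange {glucose_exchange!r} in model")
    sol = optimize(constrained_model, glucose_exchange, "max")
    if sol.status == "infeasible":
        raise InterrogationError(
            "strain constraints are infeasible: no flux state reproduces the "
            "measured rates (check tol_frac and the constraint set)"
        )
    if not sol.optimal:
        raise InterrogationError(f"glucose minimization ended {sol.status}")
    sol = minimize_total_flux(constrained_model, glucose_exchange, sol.objective_value)
    return max(0.0, -sol.objective_value), sol


def relative_error(pred: float, exp: float) -> float:
    """|pred − exp| / exp, as a percentage. Requires exp > 0."""
    if exp <= 0:
        raise ValueError(f"experimental reference must be positive, got {exp}")
    return abs(pred - exp) / exp * 100.0


def biomass_carbon_content(
    model: MetabolicModel, fallback_mmolc_per_gdcw: float = 40.0
) -> float:
    """Carbon fixed into biomass per unit growth flux, mmolC/gDCW.

    Derived from the biomass reaction composition: carbon consumed minus
    carbon released (e.g. CO2 terms).  Falls back to a standard yeast carbon
    content when the biomass reaction's precursors carry no formulas.
    """
    bm = model.reactions.get(model.objective_reaction)
    if bm is None:
        return fallback_mmolc_per_gdcw
    net = 0.0
    seen_formula = False
    for met_id, coef in bm.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.formula is None:
            continue
        seen_formula = True
        net += -coef * carbon_count(met)
    if not seen_formula or net <= 0:
        return fallback_mmolc_per_gdcw
    return net


def carbon_recovery(
    solution: FluxSolution,
    measurement: StrainMeasurement,
    model: MetabolicModel,
    measured_reactions: list[str] | None = None,
    biomass_carbon_fallback: float = 40.0,
    glucose_exchange: str = EX_GLUCOSE,
) -> float:
    """Percentage of consumed glucose carbon recovered in measured outputs.

    numerator   = C_biomass(μ) + C_CO2(q_CO2) + Σ C·(measured product fluxes)
    denominator = C_glucose · experimental glucose uptake

    The experimental uptake must be supplied in the measurement
    (``glucose_uptake_exp``); the denominator deliberately uses the
    experimental, not the predicted, uptake — recovery against the model's
    own minimal uptake would be close to 100% by construction.
    """
    if measurement.glucose_uptake_exp is None or measurement.glucose_uptake_exp <= 0:
        raise MeasurementError(
            f"{measurement.strain_id}: carbon recovery needs glucose_uptake_exp "
            "(supply the literature uptake rate in the measurement table)"
        )
    if not solution.optimal:
        raise InterrogationError("carbon recovery needs an optimal solution")
    mu = measurement.mu or 0.0
    q_co2 = measurement.q_co2 or 0.0
    carbon = mu * biomass_carbon_content(model, biomass_carbon_fallback)
    carbon += q_co2  # CO2 carries 1 C
    if measured_reactions is None:
        measured_reactions = [
            rid for rid in list(CAROTENOID_SINKS.values()) + [EX_BIONONE]
            if rid in model.reactions
        ]
    for rid in measured_reactions:
        rxn = model.reactions[rid]
        (met_id,) = rxn.stoichiometry
        carbon += abs(solution.fluxes.get(rid, 0.0)) * carbon_count(
            model.metabolites[met_id]
        )
    glc_rxn = model.reactions[glucose_exchange]
    (glc_met,) = glc_rxn.stoichiometry
    c_glc = carbon_count(model.metabolites[glc_met])
    return 100.0 * carbon / (c_glc * measurement.glucose_uptake_exp)


@dataclass
class CounterfactualResult:
    """Outcome of the counterfactual maximum-β-ionone analysis."""

    q_car_theoretical: float       # mmol/gDCW/h, max β-carotene w/o cleavage
    q_car_exp: float               # mmol/gDCW/h, observed accumulation
    divertible_carbon: float       # mmolC/gDCW/h available to cleavage
    q_ionone_max: float            # mmol/gDCW/h, ceiling under the carbon cap
    q_ionone_exp: float            # mmol/gDCW/h, observed
    departure_pct: float | None    # 100·(1 − exp/max); None when max = 0
    c14_ionone_ratio: float | None # mol C14 per mol ionone at the optimum
    c14_ionone_ratio_range: tuple[float, float] | None  # degeneracy breadth
    solution: FluxSolution


def counterfactual_max_ionone(
    constrained_model: MetabolicModel,
    measurement: StrainMeasurement,
    spec: PathwaySpec,
    ionone_mode: str = "endpoint",
    carotene_carbon: float = 40.0,
) -> CounterfactualResult:
    """How much β-ionone could the strain have made from its spare β-carotene?

    Step 1: with β-ionone production forced to zero and every other strain
    constraint kept, maximize the β-carotene accumulation sink — the
    theoretical accumulation ``q_car_theoretical``.
    Step 2: the gap to the observed accumulation, in carbon units
    (40 C per β-carotene), is the divertible carbon.
    Step 3: restore the observed β-carotene accumulation, cap total carbon
    entering the cleavage reactions at the divertible carbon, and maximize
    β-ionone export; the parsimonious optimum supplies the departure and
    the C14:ionone molar ratio.
    """
    for rid in (SINK_BCAROTENE, EX_BIONONE):
        if rid not in constrained_model.reactions:
            raise ModelError(f"model lacks {rid}; extend it with the pathway first")
    mu = measurement.mu
    if mu is None:
        raise MeasurementError(f"{measurement.strain_id}: needs mu")
    q_car_exp = yield_to_specific_rate(
        measurement.species_yield("beta_carotene"), mu,
        spec.molar_masses["beta_carotene"],
    )
    q_ionone_exp = 0.0
    if measurement.ionone_titer:
        q_ionone_exp = titer_to_specific_rate(
            measurement.ionone_titer, measurement.biomass_conc,
            measurement.culture_time, mu,
            molar_mass(PATHWAY_FORMULAS["beta_ionone"]), mode=ionone_mode,
        )

    # Step 1 — theoretical β-carotene accumulation without ionone production.
    step1 = constrained_model.copy()
    step1.set_bounds(EX_BIONONE, 0.0, 0.0)
    step1.set_bounds(SINK_BCAROTENE, 0.0, DEFAULT_BOUND)
    sol1 = optimize(step1, SINK_BCAROTENE, "max")
    if sol1.status == "infeasible":
        raise InterrogationError(
            f"{measurement.strain_id}: constraints infeasible with ionone "
            "production suppressed"
        )
    q_car_theoretical = sol1.objective_value

    # Step 2 — divertible carbon.
    divertible = carotene_carbon * (q_car_theoretical - q_car_exp)
    if divertible < -REL_TOL * max(1.0, abs(q_car_theoretical)):
        raise InterrogationError(
            f"{measurement.strain_id}: measured β-carotene accumulation "
            f"({q_car_exp:.4g}) exceeds the model optimum "
            f"({q_car_theoretical:.4g}) — measurement exceeds model optimum"
        )
    divertible = max(divertible, 0.0)

    # Step 3 — maximum β-ionone under the divertible-carbon cap.
    step3 = constrained_model.copy()
    step3.set_bounds(EX_BIONONE, 0.0, DEFAULT_BOUND)
    cleavages = cleavage_reaction_ids(step3)
    cap = LinearConstraint(
        {rid: carotene_carbon for rid in cleavages},
        divertible,
        name="divertible-carbon cap on cleavage",
    )
    sol3 = optimize(step3, EX_BIONONE, "max", extra_constraints=[cap])
    if sol3.status == "infeasible":
        raise InterrogationError(
            f"{measurement.strain_id}: ionone-maximization step infeasible"
        )
    q_ionone_max = max(0.0, sol3.objective_value)
    sol3 = minimize_total_flux(step3, EX_BIONONE, q_ionone_max,
                               extra_constraints=[cap])

    if q_ionone_max <= REL_TOL:
        return CounterfactualResult(
            q_car_theoretical, q_car_exp, divertible, 0.0, q_ionone_exp,
            departure_pct=None, c14_ionone_ratio=None,
            c14_ionone_ratio_range=None, solution=sol3,
        )
    departure = (1.0 - q_ionone_exp / q_ionone_max) * 100.0
    v_double = sol3.fluxes.get(RXN_CCD1_DOUBLE, 0.0)
    ratio = v_double / q_ionone_max  # 1 C14 per double-cleavage event
    ratio_range = _ratio_degeneracy(step3, cap, q_ionone_max)
    return CounterfactualResult(
        q_car_theoretical, q_car_exp, divertible, q_ionone_max, q_ionone_exp,
        departure_pct=departure, c14_ionone_ratio=ratio,
        c14_ionone_ratio_range=ratio_range, solution=sol3,
    )


def _ratio_degeneracy(
    model: MetabolicModel, cap: LinearConstraint, q_ionone_max: float
) -> tuple[float, float] | None:
    """Range of the C14:ionone ratio over the optimal face (two aux LPs)."""
    if RXN_CCD1_DOUBLE not in model.reactions:
        return None
    probe = model.copy()
    half = max(abs(q_ionone_max) * REL_TOL, 1e-9)
    probe.set_bounds(EX_BIONONE, q_ionone_max - half, q_ionone_max + half)
    lo = optimize(probe, RXN_CCD1_DOUBLE, "min", extra_constraints=[cap])
    hi = optimize(probe, RXN_CCD1_DOUBLE, "max", extra_constraints=[cap])
    if not (lo.optimal and hi.optimal):
        return None
    return (lo.objective_value / q_ionone_max, hi.objective_value / q_ionone_max)


@dataclass
class InterrogationReport:
    """Per-strain derived quantities from all four procedures."""

    strain_id: str
    q_glc_pred: float | None = None
    q_glc_exp: float | None = None
    rel_error_pct: float | None = None
    carbon_recovery_pct: float | None = None
    q_car_theoretical: float | None = None
    q_car_exp: float | None = None
    divertible_carbon: float | None = None
    q_ionone_max: float | None = None
    q_ionone_exp: float | None = None
    departure_pct: float | None = None
    c14_ionone_ratio: float | None = None
    c14_ionone_ratio_range: tuple[float, float] | None = None
    parsimonious: bool = True
    tolerance: float = REL_TOL
    notes: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.c14_ionone_ratio_range is not None:
            d["c14_ionone_ratio_range"] = list(self.c14_ionone_ratio_range)
        return d


def interrogate_strain(
    extended_model: MetabolicModel,
    measurement: StrainMeasurement,
    spec: PathwaySpec,
    tol_frac: float = 0.05,
    ionone_mode: str = "endpoint",
) -> InterrogationReport:
    """Run all four procedures for one strain on a growth-contextualized,
    pathway-extended model. Stages that lack their required measurements are
    skipped with a note rather than aborting the whole report."""
    report = InterrogationReport(strain_id=measurement.strain_id)
    notes: list[str] = []
    constrained, _ = constrain_strain(
        extended_model, measurement, spec, tol_frac=tol_frac,
        ionone_mode=ionone_mode,
    )
    q_glc_pred, solution = predict_min_glucose(constrained)
    report.q_glc_pred = q_glc_pred
    report.q_glc_exp = measurement.glucose_uptake_exp
    if measurement.glucose_uptake_exp:
        report.rel_error_pct = relative_error(
            q_glc_pred, measurement.glucose_uptake_exp
        )
        report.carbon_recovery_pct = carbon_recovery(
            solution, measurement, extended_model
        )
    else:
        notes.append("no experimental glucose uptake: error/recovery skipped")
    try:
        cf = counterfactual_max_ionone(
            constrained, measurement, spec, ionone_mode=ionone_mode
        )
    except InterrogationError as exc:
        notes.append(str(exc))
    else:
        report.q_car_theoretical = cf.q_car_theoretical
        report.q_car_exp = cf.q_car_exp
        report.divertible_carbon = cf.divertible_carbon
        report.q_ionone_max = cf.q_ionone_max
        report.q_ionone_exp = cf.q_ionone_exp
        report.departure_pct = cf.departure_pct
        report.c14_ionone_ratio = cf.c14_ionone_ratio
        report.c14_ionone_ratio_range = cf.c14_ionone_ratio_range
        if cf.departure_pct is None:
            notes.append("q_ionone_max = 0: departure undefined")
    report.notes = "; ".join(notes)
    return report


def reports_to_frame(reports: list[InterrogationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        d = r.to_dict()
        rng = d.pop("c14_ionone_ratio_range", None)
        d["c14_ratio_lo"] = rng[0] if rng else None
        d["c14_ratio_hi"] = rng[1] if rng else None
        rows.append(d)
    return pd.DataFrame(rows)


def write_reports_json(reports: list[InterrogationReport], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([r.to_dict() for r in reports], indent=1))
    return path
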