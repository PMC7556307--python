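"""Toy host models with known optima, synthetic measurements, and the
published strain table — everything needed to exercise the full analysis
without downloading a genome-scale reconstruction.

The toy host lumps yeast central metabolism into a handful of reactions
with tunable stoichiometry, so every optimum has a closed form:

* respiration:    glc + 6 O2 + a·ADP → 6 CO2 + a·ATP        (a = atp_per_glucose)
* fermentation:   glc + 2 ADP → 2 ethanol + 2 CO2 + 2 ATP   (optional branch)
* biomass:        (c/6)·glc + g·ATP → 1 gDCW                (c = carbon_per_biomass,
                                                             g = gam_atp)
* isoprenoid:     1.5 glc + 6 ATP → IPP + 4 CO2;  3 IPP → FPP (capacity-bounded)

Hence on the purely respiratory optimum

    q_glc_min(mu, ngam) = mu·(c/6 + g/a) + ngam/a

and the maximum β-carotene flux after pathway extension is
``fpp_capacity / 2`` (each carotene consumes 2 GGPP = 2 FPP + 2 IPP, and
FPP synthesis carries the capacity bound).

The measurement simulator converts a feasible flux state into the units a
shake-flask experiment reports (mg/gDCW yields, mg/L titers) and applies
multiplicative log-normal noise — measurements are positive and HPLC/OD
errors are roughly proportional — with a stated coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .contextualization import StrainMeasurement
from .fba_core import minimize_total_flux, optimize
from .model_io import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)
from .pathway_extension import (
    CAROTENOID_SINKS,
    EX_BIONONE,
    RXN_CCD1_DOUBLE,
    RXN_CCD1_SINGLE,
    SINK_C14DIAL,
    PathwaySpec,
)

# ---------------------------------------------------------------------------
# Toy host model
# ---------------------------------------------------------------------------


@dataclass
class ToyModelConfig:
    """Parameters of the lumped toy host.

    Defaults approximate aerobic S. cerevisiae: ~40 mmol carbon per gDCW
    (≈0.48 gC/gDCW), a lumped P/O-equivalent ATP yield of 16 mol ATP per mol
    glucose respired, 60 mmol ATP/gDCW growth-associated maintenance, and an
    isoprenoid-precursor capacity sized so maximal carotenoid accumulation
    falls in the few-mg/gDCW range observed in single-copy strains.
    """

    atp_per_glucose: float = 16.0       # mol ATP / mol glucose respired
    carbon_per_biomass: float = 40.0    # mmol C / gDCW
    gam_atp: float = 60.0               # mmol ATP / gDCW growth-associated
    fpp_capacity: float = 0.02          # mmol/gDCW/h upper bound on FPP synthase
    include_fermentation_branch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("atp_per_glucose", "carbon_per_biomass", "gam_atp"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if self.fpp_capacity < 0:
            raise ModelError("fpp_capacity must be non-negative")

    def min_glucose(self, mu: float, ngam: float = 0.0) -> float:
        """Closed-form minimal glucose uptake at growth rate mu (respiratory)."""
        a = self.atp_per_glucose
        return mu * (self.carbon_per_biomass / 6.0 + self.gam_atp / a) + ngam / a

    def max_growth(self, glucose_uptake: float, ngam: float = 0.0) -> float:
        """Closed-form maximal growth rate at a given glucose uptake."""
        a = self.atp_per_glucose
        return (glucose_uptake - ngam / a) / (
            self.carbon_per_biomass / 6.0 + self.gam_atp / a
        )


def build_toy_model(config: ToyModelConfig | None = None) -> MetabolicModel:
    """Construct the lumped toy host. Deterministic: equal configs give
    byte-identical serialized models."""
    cfg = config or ToyModelConfig()
    a = cfg.atp_per_glucose
    model = MetabolicModel(
        description=(
            "toy aerobic yeast host; "
            f"atp_per_glucose={cfg.atp_per_glucose:g}, "
            f"carbon_per_biomass={cfg.carbon_per_biomass:g} mmolC/gDCW, "
            f"gam_atp={cfg.gam_atp:g}, fpp_capacity={cfg.fpp_capacity:g}; "
            "closed forms: q_glc_min(mu,ngam)=mu*(c/6+g/a)+ngam/a, "
            "max carotene flux after extension = fpp_capacity/2"
        )
    )
    mets = [
        Metabolite("glc__D_e", "D-glucose", "e", "C6H12O6"),
        Metabolite("glc__D_c", "D-glucose", "c", "C6H12O6"),
        Metabolite("o2_e", "oxygen", "e", "O2"),
        Metabolite("o2_c", "oxygen", "c", "O2"),
        Metabolite("co2_e", "carbon dioxide", "e", "CO2"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("h2o_e", "water", "e", "H2O"),
        Metabolite("h2o_c", "water", "c", "H2O"),
        Metabolite("atp_c", "ATP", "c", "C10H16N5O13P3"),
        Metabolite("adp_c", "ADP", "c", "C10H15N5O10P2"),
        Metabolite("pi_c", "phosphate", "c", "H3O4P"),
        Metabolite("ppi_c", "diphosphate", "c", "H4O7P2"),
        Metabolite("fad_c", "FAD", "c", "C27H33N9O15P2"),
        Metabolite("fadh2_c", "FADH2", "c", "C27H35N9O15P2"),
        Metabolite("ipp_c", "isopentenyl diphosphate", "c", "C5H12O7P2"),
        Metabolite("fpp_c", "farnesyl diphosphate", "c", "C15H28O7P2"),
    ]
    if cfg.include_fermentation_branch:
        mets += [
            Metabolite("etoh_e", "ethanol", "e", "C2H6O"),
            Metabolite("etoh_c", "ethanol", "c", "C2H6O"),
        ]
    for m in mets:
        model.add_metabolite(m)

    B = DEFAULT_BOUND
    rxns = [
        Reaction("EX_glc__D_e", {"glc__D_e": -1}, -B, B, "exchange",
                 name="D-glucose exchange"),
        Reaction("EX_o2_e", {"o2_e": -1}, -B, B, "exchange", name="O2 exchange"),
        Reaction("EX_co2_e", {"co2_e": -1}, 0, B, "exchange", name="CO2 exchange"),
        Reaction("EX_h2o_e", {"h2o_e": -1}, -B, B, "exchange", name="H2O exchange"),
        Reaction("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0, B, "internal",
                 name="glucose uptake transport"),
        Reaction("O2t", {"o2_e": -1, "o2_c": 1}, 0, B, "internal"),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, 0, B, "internal"),
        Reaction("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -B, B, "internal"),
        Reaction(
            "RESP",
            {"glc__D_c": -1, "o2_c": -6, "adp_c": -a, "pi_c": -a,
             "co2_c": 6, "atp_c": a, "h2o_c": 6 + a},
            0, B, "internal", name="lumped glycolysis + respiration",
        ),
        Reaction("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
                 0, B, "internal", name="non-growth maintenance ATPase"),
        Reaction(
            "BIOMASS_toy",
            {"glc__D_c": -cfg.carbon_per_biomass / 6.0,
             "atp_c": -cfg.gam_atp, "h2o_c": -cfg.gam_atp,
             "adp_c": cfg.gam_atp, "pi_c": cfg.gam_atp},
            0, B, "biomass", name="biomass pseudo-reaction (1 gDCW per unit flux)",
        ),
        # lumped mevalonate route: 1.5 glucose (C9) -> IPP (C5) + 4 CO2;
        # H/O bookkeeping is lumped (carbon and phosphorus balance exactly)
        Reaction(
            "MVA",
            {"glc__D_c": -1.5, "atp_c": -6, "ipp_c": 1, "co2_c": 4,
             "adp_c": 6, "pi_c": 4},
            0, B, "internal", name="lumped mevalonate pathway to IPP",
        ),
        Reaction("FPPS", {"ipp_c": -3, "fpp_c": 1, "ppi_c": 2},
                 0, cfg.fpp_capacity, "internal",
                 name="FPP synthase (capacity-bounded)"),
        Reaction("PPIH", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2}, 0, B, "internal",
                 name="inorganic diphosphatase"),
        Reaction("FADR", {"fadh2_c": -1, "o2_c": -0.5, "fad_c": 1, "h2o_c": 1},
                 0, B, "internal", name="FADH2 reoxidation"),
    ]
    if cfg.include_fermentation_branch:
        rxns += [
            Reaction(
                "FERM",
                {"glc__D_c": -1, "adp_c": -2, "pi_c": -2,
                 "etoh_c": 2, "co2_c": 2, "atp_c": 2, "h2o_c": 2},
                0, B, "internal", name="lumped fermentation to ethanol",
            ),
            Reaction("ETOHt", {"etoh_c": -1, "etoh_e": 1}, 0, B, "internal"),
            Reaction("EX_etoh_e", {"etoh_e": -1}, 0, B, "exchange",
                     name="ethanol exchange"),
        ]
    for r in rxns:
        model.add_reaction(r)
    model.objective_reaction = "BIOMASS_toy"
    return model


# ---------------------------------------------------------------------------
# Ground-truth flux states and simulated measurements
# ---------------------------------------------------------------------------


@dataclass
class TrueStrainState:
    """A feasible flux state of the extended toy model, used as ground truth.

    ``fluxes`` satisfies S·v = 0 exactly (it comes from an LP solve); the
    headline rates are extracted from it for convenience.
    """

    mu: float
    q_glc: float
    q_co2: float
    sink_fluxes: dict[str, float] = field(default_factory=dict)  # species -> flux
    cleavage_double: float = 0.0
    cleavage_single: float = 0.0
    q_ionone: float = 0.0
    fluxes: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.0
    seed: int = 0


def make_true_state(
    extended_model: MetabolicModel,
    mu: float,
    carotenoid_sink_fluxes: Mapping[str, float],
    cleavage_double: float = 0.0,
    cleavage_single: float = 0.0,
) -> TrueStrainState:
    """Solve for a complete, minimal-glucose flux state with the given growth
    rate, carotenoid accumulation fluxes (keyed by species name) and cleavage
    fluxes. Raises if the combination is infeasible (e.g. beyond the FPP
    capacity)."""
    probe = extended_model.copy()
    probe.set_bounds(probe.objective_reaction, mu, mu)
    for species, flux in carotenoid_sink_fluxes.items():
        probe.set_bounds(CAROTENOID_SINKS[species], flux, flux)
    probe.set_bounds(RXN_CCD1_DOUBLE, cleavage_double, cleavage_double)
    if RXN_CCD1_SINGLE in probe.reactions:
        probe.set_bounds(RXN_CCD1_SINGLE, cleavage_single, cleavage_single)
    elif cleavage_single:
        raise ModelError("single cleavage requested but not in the model")
    probe.set_bounds(SINK_C14DIAL, 0, DEFAULT_BOUND)
    probe.set_bounds(EX_BIONONE, 0, DEFAULT_BOUND)
    first = optimize(probe, "EX_glc__D_e", "max")
    if not first.optimal:
        raise ModelError(f"true state infeasible ({first.status})")
    sol = minimize_total_flux(probe, "EX_glc__D_e", first.objective_value)
    return TrueStrainState(
        mu=mu,
        q_glc=-sol.fluxes["EX_glc__D_e"],
        q_co2=sol.fluxes["EX_co2_e"],
        sink_fluxes={
            sp: sol.fluxes[rid]
            for sp, rid in CAROTENOID_SINKS.items()
            if rid in sol.fluxes
        },
        cleavage_double=cleavage_double,
        cleavage_single=cleavage_single,
        q_ionone=sol.fluxes.get(EX_BIONONE, 0.0),
        fluxes=dict(sol.fluxes),
    )


def simulate_measurements(
    model: MetabolicModel,
    true_state: TrueStrainState,
    spec: PathwaySpec,
    n_strains: int = 1,
    noise_cv: float = 0.0,
    seed: int = 0,
    biomass_conc: float = 5.0,
    culture_time: float = 72.0,
    strain_prefix: str = "sim",
) -> list[StrainMeasurement]:
    """Convert a ground-truth flux state into noisy shake-flask measurements.

    Yields are v·M/μ (mg/gDCW); the β-ionone titer is the endpoint inverse
    v·X·t·M (mg/L) at the stated harvest biomass and culture time.  Noise is
    multiplicative log-normal with the given coefficient of variation (unit
    mean, so measurements are unbiased).  The three specific rates (μ,
    q_CO2, glucose uptake) share one noise factor per strain — their
    dominant error source is the common biomass denominator, and fully
    correlated rate errors keep the noisy measurement stoichiometrically
    self-consistent — while each yield and the titer get independent
    factors; fractions are recomputed from the noised per-species yields.
    ``noise_cv=0`` reproduces the true fluxes exactly through the
    contextualization conversions.
    """
    if noise_cv < 0:
        raise ModelError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    def noisy(x: float) -> float:
        if x == 0 or sigma == 0:
            return x
        return x * float(rng.lognormal(-sigma**2 / 2.0, sigma))

    mu = true_state.mu
    out = []
    for i in range(n_strains):
        rate_factor = noisy(1.0)  # shared by mu, q_co2 and glucose uptake
        yields = {
            sp: true_state.sink_fluxes.get(sp, 0.0) * spec.molar_masses[sp] / mu
            for sp in CAROTENOID_SINKS
        }
        yields = {sp: noisy(y) for sp, y in yields.items()}
        total = sum(yields.values())
        titer = (
            true_state.q_ionone
            * biomass_conc
            * culture_time
            * spec.molar_masses["beta_ionone"]
        )
        out.append(
            StrainMeasurement(
                strain_id=f"{strain_prefix}{i + 1}",
                mu=mu * rate_factor,
                q_co2=true_state.q_co2 * rate_factor,
                biomass_conc=biomass_conc,
                total_carotenoids=total,
                frac_beta_carotene=yields["beta_carotene"] / total if total else 1.0,
                frac_lycopene=yields["lycopene"] / total if total else 0.0,
                frac_phytoene=yields["phytoene"] / total if total else 0.0,
                ionone_titer=noisy(titer) if titer else None,
                culture_time=culture_time,
                glucose_uptake_exp=true_state.q_glc * rate_factor,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Published strain table
# ---------------------------------------------------------------------------

#: Shake-flask results reported for the engineered β-carotene / β-ionone
#: S. cerevisiae strain series (72-h cultivations).  Growth rates, CO2 rates
#: and harvest biomass were not printed for these strains, so those fields
#: are deliberately left empty: rate-dependent analyses on this table
#: require user-supplied rates or the flagged literature defaults.
PUBLISHED_STRAINS: tuple[tuple[str, float | None, float | None], ...] = (
    # (strain, total carotenoids mg/gDCW, beta-ionone titer mg/L)
    ("beta-Car1.1", 4.0, None),
    ("beta-Car1.2", 3.8, None),
    ("beta-Car2.1", 3.8, None),
    ("beta-Car3", 12.0, None),
    ("beta-Car4.b", 16.0, None),
    ("beta-Car5", 32.0, None),
    ("beta-iono2.1", None, 1.8),
    ("beta-iono4.1", 14.2, None),   # residual carotenoids at harvest
    ("beta-iono5.1", 26.7, 18.2),   # residual carotenoids + titer
    ("beta-iono5.2", None, 26.3),
    ("beta-iono5.3", None, 33.0),
)

#: Reported ranges and context that accompany the table.
PUBLISHED_METADATA: dict = {
    "locus_yield_range_mg_gdcw": (2.6, 4.1),  # single-copy tandem, six loci
    "culture_time_h": 72.0,
    "residual_strains": ("beta-iono4.1", "beta-iono5.1"),
}


def published_strain_table() -> list[StrainMeasurement]:
    """The published strain measurements as a read-only measurement list."""
    rows = []
    for strain, total, titer in PUBLISHED_STRAINS:
        rows.append(
            StrainMeasurement(
                strain_id=strain,
                total_carotenoids=total if total is not None else 0.0,
                ionone_titer=titer,
                culture_time=PUBLISHED_METADATA["culture_time_h"],
            )
        )
    return rows


def published_fold_changes() -> dict[str, float]:
    """Fold changes and percentage differences implied by the published table.

    These are the arithmetic consequences of the printed yields/titers:
    gene-dosage and tHMGR effects on total carotenoids, cleavage-gene-dosage
    effects on the β-ionone titer, and the spread across integration loci.
    """
    t = {strain: total for strain, total, _ in PUBLISHED_STRAINS}
    titer = {strain: ti for strain, _, ti in PUBLISHED_STRAINS}
    lo, hi = PUBLISHED_METADATA["locus_yield_range_mg_gdcw"]
    return {
        # second tandem copy: beta-Car3 vs its parent beta-Car2.1
        "carotenoid_fold_car3_vs_car2.1": t["beta-Car3"] / t["beta-Car2.1"],
        # whole dosage series: beta-Car5 vs the initial beta-Car1.1
        "carotenoid_fold_car5_vs_car1.1": t["beta-Car5"] / t["beta-Car1.1"],
        # tHMGR overexpression: beta-Car5 vs beta-Car4.b
        "carotenoid_fold_car5_vs_car4b": t["beta-Car5"] / t["beta-Car4.b"],
        # highest vs lowest carotene background at one CCD1 copy
        "ionone_fold_iono5.1_vs_iono2.1": titer["beta-iono5.1"] / titer["beta-iono2.1"],
        # three CCD1 copies in the best background vs the initial producer
        "ionone_fold_iono5.3_vs_iono2.1": titer["beta-iono5.3"] / titer["beta-iono2.1"],
        # spread across integration loci, % of the lowest-yield locus
        "locus_yield_spread_pct": (hi - lo) / lo * 100.0,
    }
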