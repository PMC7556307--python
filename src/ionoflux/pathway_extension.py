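"""Heterologous carotenoid/apocarotenoid pathway: stoichiometry and grafting.

The pathway extends a yeast host from its native isoprenoid precursors
(IPP/FPP) to β-carotene and its cleavage products:

* CrtE (GGPP synthase):        FPP + IPP → GGPP + PPi
* CrtYB phytoene synthase:     2 GGPP → phytoene + 2 PPi
* CrtI (lumped desaturase):    phytoene + 4 FAD → lycopene + 4 FADH2
* CrtYB lycopene cyclase:      lycopene → β-carotene
* CCD1 double cleavage:        β-carotene + 2 O2 → 2 β-ionone + C14-dialdehyde
* CCD1 single cleavage (opt.): β-carotene + O2 → β-ionone + C27-apocarotenal

CCD1 oxidatively cleaves the 9,10 and 9',10' double bonds; acting at both
sites splits the C40 backbone into two C13 ionones and one C14 dialdehyde
(40 = 13 + 13 + 14).  Carotenoid accumulation is modeled as irreversible
sink drains (pigment retained in biomass never re-enters metabolism);
β-ionone leaves through an exchange reaction (it is secreted and captured
in the culture medium/overlay).  All sinks are created closed and opened
only by contextualization.

Every non-boundary template reaction is elementally balanced for C, H, O
(and P for the prenyl steps); :func:`check_elemental_balance` verifies this
for arbitrary reactions and is also the full-element backend for model
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .model_io import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    MissingFormulaError,
    ModelError,
    Reaction,
    parse_formula,
)

#: Standard atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
    "S": 32.065,
    "Na": 22.98977,
    "K": 39.0983,
    "Mg": 24.305,
    "Ca": 40.078,
    "Cl": 35.453,
    "Fe": 55.845,
    "Zn": 65.38,
}

#: Elemental formulas of the pathway species (neutral forms).
PATHWAY_FORMULAS: dict[str, str] = {
    "ipp": "C5H12O7P2",        # isopentenyl diphosphate
    "fpp": "C15H28O7P2",       # farnesyl diphosphate
    "ggpp": "C20H36O7P2",      # geranylgeranyl diphosphate
    "phytoene": "C40H64",
    "lycopene": "C40H56",
    "beta_carotene": "C40H56",
    "beta_ionone": "C13H20O",
    "c14_dialdehyde": "C14H16O2",   # rosafluene dialdehyde, the double-cleavage co-product
    "c27_apocarotenal": "C27H36O",  # β-apo-10'-carotenal, the single-cleavage co-product
    "o2": "O2",
    "fad": "C27H33N9O15P2",
    "fadh2": "C27H35N9O15P2",
    "diphosphate": "H4O7P2",
}

#: Host metabolites the pathway plugs into, role -> default id in the toy host.
DEFAULT_HOST_MAP: dict[str, str] = {
    "fpp": "fpp_c",
    "ipp": "ipp_c",
    "o2": "o2_c",
    "fad": "fad_c",
    "fadh2": "fadh2_c",
    "diphosphate": "ppi_c",
}

#: Ids of the metabolites the extension itself introduces, role -> new id.
PATHWAY_MET_IDS: dict[str, str] = {
    "ggpp": "ggpp_c",
    "phytoene": "phytoene_c",
    "lycopene": "lycopene_c",
    "beta_carotene": "bcaro_c",
    "beta_ionone": "bionone_c",
    "c14_dialdehyde": "c14dial_c",
    "c27_apocarotenal": "apo27_c",
}

BIONONE_EXTERNAL_ID = "bionone_e"

# Reaction ids used by downstream modules.
RXN_CRTE = "CRTE"
RXN_CRTYB_SYNTHASE = "CRTYB_PSY"
RXN_CRTI = "CRTI"
RXN_CRTYB_CYCLASE = "CRTYB_LCY"
RXN_CCD1_DOUBLE = "CCD1_DOUBLE"
RXN_CCD1_SINGLE = "CCD1_SINGLE"
SINK_PHYTOENE = "SK_phytoene_c"
SINK_LYCOPENE = "SK_lycopene_c"
SINK_BCAROTENE = "SK_bcaro_c"
SINK_C14DIAL = "SK_c14dial_c"
SINK_APO27 = "SK_apo27_c"
RXN_BIONONE_TRANSPORT = "BIONt"
EX_BIONONE = "EX_bionone_e"

#: Sinks holding the measurable carotenoid species, profile field -> sink id.
CAROTENOID_SINKS: dict[str, str] = {
    "beta_carotene": SINK_BCAROTENE,
    "lycopene": SINK_LYCOPENE,
    "phytoene": SINK_PHYTOENE,
}


def molar_mass(formula: str | Mapping[str, int]) -> float:
    """Molecular weight in g/mol from an elemental formula.

    >>> round(molar_mass("C13H20O"), 2)
    192.3
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ModelError("empty formula has no molar mass")
    try:
        return sum(ATOMIC_WEIGHTS[e] * n for e, n in counts.items())
    except KeyError as exc:
        raise ModelError(f"no atomic weight for element {exc.args[0]!r}") from exc


def yield_to_specific_rate(
    yield_mg_per_gdcw: float, mu_per_h: float, molar_mass_g_per_mol: float
) -> float:
    """Convert a biomass-specific yield (mg/gDCW) to a flux (mmol/gDCW/h).

    Assumes growth-associated production: a cell population growing at μ with
    a constant content Y accumulates the product at rate μ·Y, i.e.
    μ [1/h] · Y [mg/gDCW] / M [mg/mmol] = mmol/gDCW/h.
    """
    if yield_mg_per_gdcw < 0 or mu_per_h < 0:
        raise ModelError("yield and growth rate must be non-negative")
    if molar_mass_g_per_mol <= 0:
        raise ModelError("molar mass must be positive")
    return mu_per_h * yield_mg_per_gdcw / molar_mass_g_per_mol


@dataclass
class PathwaySpec:
    """The reaction set to graft, with formulas and molar masses.

    ``metabolite_formulas`` / ``molar_masses`` are keyed by pathway role name
    (``beta_carotene``, ``c14_dialdehyde``, ...); ``reactions`` use the
    concrete metabolite ids produced by combining ``host_map`` (existing host
    species) and :data:`PATHWAY_MET_IDS` (novel species).
    """

    reactions: list[Reaction] = field(default_factory=list)
    new_metabolites: list[Metabolite] = field(default_factory=list)
    metabolite_formulas: dict[str, dict[str, int]] = field(default_factory=dict)
    molar_masses: dict[str, float] = field(default_factory=dict)
    allow_single_cleavage: bool = False
    allow_c27_sink: bool = False
    host_map: dict[str, str] = field(default_factory=dict)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def to_json_fragment(self) -> dict:
        """The reaction set in the same COBRA-style JSON dialect as models."""
        return {
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "formula": _fmt(m.formula),
                }
                for m in self.new_metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "metabolites": r.stoichiometry,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "notes": {"kind": r.kind},
                }
                for r in self.reactions
            ],
        }


def _fmt(formula):
    from .model_io import format_formula

    return format_formula(formula) if formula else None


def build_pathway_spec(
    allow_single_cleavage: bool = False,
    allow_c27_sink: bool = False,
    host_map: Mapping[str, str] | None = None,
) -> PathwaySpec:
    """Construct the default carotenogenic/apocarotenogenic pathway spec.

    ``host_map`` overrides which host metabolite ids supply FPP, IPP, O2,
    FAD/FADH2 and accept diphosphate (defaults match the generated toy host;
    pass e.g. BiGG ids to target a genome-scale model).
    """
    hm = dict(DEFAULT_HOST_MAP)
    if host_map:
        hm.update(host_map)
    formulas = {k: parse_formula(v) for k, v in PATHWAY_FORMULAS.items()}
    masses = {k: molar_mass(v) for k, v in PATHWAY_FORMULAS.items()}

    ids = dict(PATHWAY_MET_IDS)
    new_mets = [
        Metabolite(ids["ggpp"], "geranylgeranyl diphosphate", "c", formulas["ggpp"]),
        Metabolite(ids["phytoene"], "phytoene", "c", formulas["phytoene"]),
        Metabolite(ids["lycopene"], "lycopene", "c", formulas["lycopene"]),
        Metabolite(ids["beta_carotene"], "beta-carotene", "c", formulas["beta_carotene"]),
        Metabolite(ids["beta_ionone"], "beta-ionone", "c", formulas["beta_ionone"]),
        Metabolite(
            ids["c14_dialdehyde"], "C14 dialdehyde (rosafluene-dial)", "c",
            formulas["c14_dialdehyde"],
        ),
        Metabolite(BIONONE_EXTERNAL_ID, "beta-ionone (extracellular)", "e",
                   formulas["beta_ionone"]),
    ]
    reactions = [
        Reaction(
            RXN_CRTE,
            {hm["fpp"]: -1, hm["ipp"]: -1, ids["ggpp"]: 1, hm["diphosphate"]: 1},
            0, DEFAULT_BOUND, "internal", name="GGPP synthase (CrtE)",
        ),
        Reaction(
            RXN_CRTYB_SYNTHASE,
            {ids["ggpp"]: -2, ids["phytoene"]: 1, hm["diphosphate"]: 2},
            0, DEFAULT_BOUND, "internal", name="phytoene synthase (CrtYB)",
        ),
        Reaction(
            RXN_CRTI,
            {ids["phytoene"]: -1, hm["fad"]: -4, ids["lycopene"]: 1, hm["fadh2"]: 4},
            0, DEFAULT_BOUND, "internal",
            name="phytoene desaturase, 4 lumped steps (CrtI)",
        ),
        Reaction(
            RXN_CRTYB_CYCLASE,
            {ids["lycopene"]: -1, ids["beta_carotene"]: 1},
            0, DEFAULT_BOUND, "internal", name="lycopene beta-cyclase (CrtYB)",
        ),
        Reaction(
            RXN_CCD1_DOUBLE,
            {
                ids["beta_carotene"]: -1,
                hm["o2"]: -2,
                ids["beta_ionone"]: 2,
                ids["c14_dialdehyde"]: 1,
            },
            0, DEFAULT_BOUND, "internal",
            name="CCD1 9,10/9',10' double cleavage",
        ),
        # accumulation sinks: created closed, opened by contextualization
        Reaction(SINK_PHYTOENE, {ids["phytoene"]: -1}, 0, 0, "sink",
                 name="phytoene accumulation"),
        Reaction(SINK_LYCOPENE, {ids["lycopene"]: -1}, 0, 0, "sink",
                 name="lycopene accumulation"),
        Reaction(SINK_BCAROTENE, {ids["beta_carotene"]: -1}, 0, 0, "sink",
                 name="beta-carotene accumulation"),
        Reaction(SINK_C14DIAL, {ids["c14_dialdehyde"]: -1}, 0, 0, "sink",
                 name="C14 dialdehyde accumulation"),
        Reaction(
            RXN_BIONONE_TRANSPORT,
            {ids["beta_ionone"]: -1, BIONONE_EXTERNAL_ID: 1},
            0, DEFAULT_BOUND, "internal", name="beta-ionone secretion",
        ),
        Reaction(EX_BIONONE, {BIONONE_EXTERNAL_ID: -1}, 0, 0, "exchange",
                 name="beta-ionone exchange"),
    ]
    if allow_single_cleavage:
        new_mets.append(
            Metabolite(ids["c27_apocarotenal"], "beta-apo-10'-carotenal", "c",
                       formulas["c27_apocarotenal"])
        )
        reactions.insert(
            5,
            Reaction(
                RXN_CCD1_SINGLE,
                {
                    ids["beta_carotene"]: -1,
                    hm["o2"]: -1,
                    ids["beta_ionone"]: 1,
                    ids["c27_apocarotenal"]: 1,
                },
                0, DEFAULT_BOUND, "internal", name="CCD1 9,10 single cleavage",
            ),
        )
        if allow_c27_sink:
            reactions.append(
                Reaction(SINK_APO27, {ids["c27_apocarotenal"]: -1}, 0, 0, "sink",
                         name="C27 apocarotenal accumulation")
            )
    return PathwaySpec(
        reactions=reactions,
        new_metabolites=new_mets,
        metabolite_formulas=formulas,
        molar_masses=masses,
        allow_single_cleavage=allow_single_cleavage,
        allow_c27_sink=allow_c27_sink,
        host_map=hm,
    )


def check_elemental_balance(
    reaction: Reaction, metabolites: Mapping[str, Metabolite]
) -> dict[str, float] | str:
    """Per-element imbalance of a reaction (empty map iff balanced).

    Each entry is reactant atoms minus product atoms, so a reaction short of
    one O2 on the substrate side reports ``{"O": -2}``.  Boundary and biomass
    pseudo-reactions are by definition unbalanced and are reported as the
    string ``"skipped"`` rather than as violations.  Raises
    :class:`MissingFormulaError` when a participant lacks a formula.
    """
    if reaction.kind != "internal":
        return "skipped"
    net: dict[str, float] = {}
    for met_id, coef in reaction.stoichiometry.items():
        met = metabolites[met_id]
        if met.formula is None:
            raise MissingFormulaError(
                f"reaction {reaction.id}: metabolite {met_id} has no formula"
            )
        for element, n in met.formula.items():
            net[element] = net.get(element, 0.0) - coef * n
    return {e: v for e, v in net.items() if abs(v) > 1e-9}


def extend_model(model: MetabolicModel, spec: PathwaySpec) -> MetabolicModel:
    """Graft the pathway onto a host model; returns a new, validated model.

    The host must already contain the metabolites named by the spec's
    ``host_map`` (FPP, IPP, O2, FAD/FADH2, diphosphate).  All added sinks and
    the β-ionone exchange start closed.
    """
    for role, met_id in spec.host_map.items():
        if met_id not in model.metabolites:
            raise ModelError(
                f"host model lacks required metabolite {met_id!r} (role {role})"
            )
    out = model.copy()
    for met in spec.new_metabolites:
        if met.id in out.metabolites:
            raise ModelError(f"id collision: metabolite {met.id} already in host")
        out.add_metabolite(
            Metabolite(met.id, met.name, met.compartment,
                       dict(met.formula) if met.formula else None, met.charge)
        )
    for rxn in spec.reactions:
        if rxn.id in out.reactions:
            raise ModelError(f"id collision: reaction {rxn.id} already in host")
        out.add_reaction(
            Reaction(rxn.id, dict(rxn.stoichiometry), rxn.lower_bound,
                     rxn.upper_bound, rxn.kind, rxn.name)
        )
    from .model_io import validate_model

    violations = validate_model(out)
    if violations:
        raise ModelError(f"extension produced an invalid model: {violations}")
    return out


def cleavage_reaction_ids(model: MetabolicModel) -> list[str]:
    """The CCD1 reactions present in a model (double, and single if enabled)."""
    return [r for r in (RXN_CCD1_DOUBLE, RXN_CCD1_SINGLE) if r in model.reactions]
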