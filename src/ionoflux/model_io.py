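"""Metabolic model containers, elemental-formula parsing, and model I/O.

The containers here are deliberately small: a metabolic model is a set of
metabolites (with elemental formulas, so carbon accounting is always
possible), a set of bounded reactions, and one objective reaction.  Flux
units are mmol/gDCW/h throughout the package; growth rate is h^-1.  Yields
(mg/gDCW) and titers (mg/L) exist only at the measurement boundary and are
converted exactly once, in :mod:`ionoflux.contextualization`.

Two on-disk formats are supported: a COBRA-style JSON dialect (primary,
lossless for every field including the reaction ``kind`` tag) and flat SBML
Level 3 with the FBC extension (bridged through cobrapy; the ``kind`` tag is
reconstructed from id conventions on read).
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Reaction categories. ``exchange`` and ``sink`` are boundary pseudo-reactions
#: touching exactly one metabolite (exchange: medium transfer; sink:
#: intracellular accumulation drain). ``biomass`` is the growth pseudo-reaction
#: and is exempt from elemental balance checks.
REACTION_KINDS = ("internal", "exchange", "sink", "biomass")

#: Default magnitude for "unbounded" fluxes, mmol/gDCW/h (community convention).
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised for malformed models, formulas, or files."""


class MissingFormulaError(ModelError):
    """Raised when a carbon-dependent operation meets a metabolite without a formula."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula string into an element -> count map.

    The grammar is ``(ElementSymbol Count?)+`` with no parentheses; an absent
    count means 1.  Repeated element symbols accumulate.

    >>> parse_formula("C13H20O")
    {'C': 13, 'H': 20, 'O': 1}
    """
    if not isinstance(text, str) or not text.strip():
        raise ModelError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ModelError(
                f"malformed formula {text!r}: unparseable token at position {pos}"
            )
        element, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n < 1:
            raise ModelError(
                f"malformed formula {text!r}: zero count at position {pos}"
            )
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render an element map back to Hill-ordered text (C, H, then alphabetical)."""
    elements = sorted(
        counts, key=lambda e: (e != "C", e != "H", e)
    )
    return "".join(
        f"{e}{counts[e]}" if counts[e] != 1 else e for e in elements if counts[e]
    )


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` is an element -> count map (``None`` when the source model
    carries no formula; carbon-dependent operations then fail loudly rather
    than assuming zero carbon).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):  # convenience: accept formula text
            self.formula = parse_formula(self.formula)
        if self.formula is not None:
            bad = {e: n for e, n in self.formula.items() if n < 1}
            if bad:
                raise ModelError(f"metabolite {self.id}: non-positive counts {bad}")


def carbon_count(met: Metabolite) -> int:
    """Number of carbon atoms in a metabolite's formula (0 if C absent).

    Raises :class:`MissingFormulaError` when the metabolite has no formula —
    never silently returns 0 for an unknown composition.
    """
    if met.formula is None:
        raise MissingFormulaError(
            f"metabolite {met.id} has no formula; carbon count undefined"
        )
    return met.formula.get("C", 0)


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds (mmol/gDCW/h).

    ``stoichiometry`` maps metabolite id -> signed coefficient, negative for
    consumed species.  Boundary reactions (exchange, sink) must touch exactly
    one metabolite; by convention their flux is negative for uptake and
    positive for export/accumulation.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    kind: str = "internal"
    name: str = ""
    gene_rule: str = ""  # opaque gene-association string, never evaluated

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def boundary(self) -> bool:
        return self.kind in ("exchange", "sink")


@dataclass
class MetabolicModel:
    """A stoichiometric network: metabolites, reactions, one objective."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_reaction: str = ""
    description: str = ""

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id} references undeclared metabolites: {missing}"
            )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def set_bounds(self, reaction_id: str, lower: float, upper: float) -> None:
        if reaction_id not in self.reactions:
            raise ModelError(f"no such reaction: {reaction_id}")
        if lower > upper:
            raise ModelError(
                f"reaction {reaction_id}: bounds [{lower}, {upper}] inverted"
            )
        rxn = self.reactions[reaction_id]
        rxn.lower_bound, rxn.upper_bound = float(lower), float(upper)


def validate_model(model: MetabolicModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid).

    Checks: referential integrity, bound ordering, boundary-reaction arity,
    objective existence, and carbon balance of every internal reaction whose
    participants all carry formulas (a full multi-element check is available
    via :func:`ionoflux.pathway_extension.check_elemental_balance`).
    """
    violations: list[str] = []
    for rxn in model.reactions.values():
        missing = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if missing:
            violations.append(f"{rxn.id}: undeclared metabolites {missing}")
            continue
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(f"{rxn.id}: inverted bounds")
        if rxn.boundary and len(rxn.stoichiometry) != 1:
            violations.append(
                f"{rxn.id}: {rxn.kind} reaction touches "
                f"{len(rxn.stoichiometry)} metabolites (must be exactly 1)"
            )
        if rxn.kind == "internal":
            formulas = [model.metabolites[m].formula for m in rxn.stoichiometry]
            if all(f is not None for f in formulas):
                net_c = sum(
                    coef * model.metabolites[m].formula.get("C", 0)  # type: ignore[union-attr]
                    for m, coef in rxn.stoichiometry.items()
                )
                if abs(net_c) > 1e-6:
                    violations.append(
                        f"{rxn.id}: carbon imbalance of {net_c:+g} C"
                    )
    if model.objective_reaction and model.objective_reaction not in model.reactions:
        violations.append(f"objective reaction {model.objective_reaction} not found")
    return violations


# ---------------------------------------------------------------------------
# COBRA-style JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": "ionoflux_model",
        "description": model.description,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": format_formula(m.formula) if m.formula else None,
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gene_reaction_rule": r.gene_rule,
                "objective_coefficient": 1.0
                if r.id == model.objective_reaction
                else 0.0,
                "notes": {"kind": r.kind},
            }
            for r in model.reactions.values()
        ],
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(description=data.get("description", ""))
    for m in data["metabolites"]:
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=parse_formula(m["formula"]) if m.get("formula") else None,
                charge=m.get("charge"),
            )
        )
    for r in data["reactions"]:
        kind = (r.get("notes") or {}).get("kind") or _infer_kind(
            r["id"], r["metabolites"]
        )
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                kind=kind,
                gene_rule=r.get("gene_reaction_rule", ""),
            )
        )
        if r.get("objective_coefficient"):
            model.objective_reaction = r["id"]
    return model


def _infer_kind(rxn_id: str, stoich: Mapping[str, float]) -> str:
    """Heuristic kind recovery for files that do not carry the tag (SBML)."""
    if "biomass" in rxn_id.lower():
        return "biomass"
    if len(stoich) == 1:
        return "sink" if rxn_id.upper().startswith("SK_") else "exchange"
    return "internal"


def write_model(model: MetabolicModel, path: str | Path, format: str = "auto") -> Path:
    """Serialize a model to JSON or SBML (L3 + FBC). Round-trips with read_model."""
    path = Path(path)
    if not model.reactions:
        raise ModelError("refusing to write a model with no reactions")
    violations = validate_model(model)
    if violations:
        raise ModelError(f"model invalid, not writing: {violations}")
    fmt = _resolve_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=True))
    else:
        _write_sbml(model, path)
    return path


def read_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Load a model from COBRA-style JSON or SBML; validates before returning."""
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    fmt = _resolve_format(path, format)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelError(f"{path}: not valid JSON ({exc})") from exc
        model = _model_from_dict(data)
    else:
        model = _read_sbml(path)
    violations = validate_model(model)
    if violations:
        raise ModelError(f"{path}: invalid model: {violations}")
    return model


def _resolve_format(path: Path, format: str) -> str:
    if format in ("json", "sbml"):
        return format
    if format != "auto":
        raise ModelError(f"unknown format {format!r} (use auto|json|sbml)")
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    # fall back to sniffing the first bytes
    if path.exists():
        head = path.read_bytes()[:200].lstrip()
        return "sbml" if head.startswith(b"<") else "json"
    raise ModelError(f"cannot infer format of {path}; pass format explicitly")


# ---------------------------------------------------------------------------
# SBML bridge (through cobrapy, which wraps libsbml with the FBC extension)
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("ionoflux_model")
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(
            m.id,
            formula=format_formula(m.formula) if m.formula else None,
            name=m.name,
            compartment=m.compartment,
            charge=m.charge,
        )
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions.values():
        crxn = cobra.Reaction(r.id, name=r.name)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        crxn.bounds = (r.lower_bound, r.upper_bound)
    if model.objective_reaction:
        cm.objective = model.objective_reaction
    return cm


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(_to_cobra(model), str(path))


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    model = MetabolicModel(description=cm.name or "")
    for cmet in cm.metabolites:
        model.add_metabolite(
            Metabolite(
                id=cmet.id,
                name=cmet.name or "",
                compartment=cmet.compartment or "c",
                formula=parse_formula(cmet.formula) if cmet.formula else None,
                charge=cmet.charge,
            )
        )
    objective_ids = {
        r.id for r in cm.reactions if getattr(r, "objective_coefficient", 0.0)
    }
    for crxn in cm.reactions:
        stoich = {m.id: coef for m, coef in crxn.metabolites.items()}
        model.add_reaction(
            Reaction(
                id=crxn.id,
                name=crxn.name or "",
                stoichiometry=stoich,
                lower_bound=crxn.lower_bound,
                upper_bound=crxn.upper_bound,
                kind=_infer_kind(crxn.id, stoich),
                gene_rule=crxn.gene_reaction_rule or "",
            )
        )
    if objective_ids:
        model.objective_reaction = sorted(objective_ids)[0]
    return model
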