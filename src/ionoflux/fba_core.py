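"""Flux balance analysis: the linear programs behind every interrogation.

The steady-state assumption S·v = 0 together with flux bounds defines a
polytope; every procedure in this package optimizes a single flux over that
polytope, optionally followed by a parsimony tie-break (minimize total
absolute flux at the fixed optimum) so that flux-derived ratios are unique
even when the optimum is degenerate.

The solver backend is scipy's HiGHS interface (dual simplex, deterministic).
Solutions are post-checked against the mass balance and bounds and rejected
— never silently patched — when they violate the tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, ModelError

#: Relative feasibility/optimality tolerance for the post-check.
REL_TOL = 1e-6
#: Absolute floor for the post-check.
ABS_TOL = 1e-9


class SolverError(RuntimeError):
    """Numerical solver failure, distinct from a genuinely infeasible LP."""


class InfeasibleError(RuntimeError):
    """The constraint set admits no flux distribution."""


@dataclass
class LinearConstraint:
    """An extra inequality  sum_j coefs[j]·v_j <= bound  on top of S·v = 0."""

    coefficients: dict[str, float]
    upper: float
    name: str = ""


@dataclass
class FluxSolution:
    """Outcome of one LP solve over a metabolic model."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_reaction: str = ""
    tolerance: float = REL_TOL
    parsimonious: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _build_matrices(model: MetabolicModel):
    """Stoichiometric matrix with deterministic (insertion-order) indexing."""
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.stoichiometry.items():
            S[met_index[met], j] += coef
    return rxn_ids, S, lb, ub


def _check_solution(S, lb, ub, v, tol_scale: float) -> None:
    residual = np.abs(S @ v).max() if S.size else 0.0
    limit = max(ABS_TOL, REL_TOL * tol_scale)
    if residual > limit:
        raise SolverError(
            f"solution violates mass balance: max |S·v| = {residual:.3e} > {limit:.3e}"
        )
    slack = max(ABS_TOL, REL_TOL * tol_scale)
    if np.any(v < lb - slack) or np.any(v > ub + slack):
        raise SolverError("solution violates flux bounds beyond tolerance")


def _diagnose_infeasible(model: MetabolicModel) -> str:
    tight = [
        f"{r.id}[{r.lower_bound:g},{r.upper_bound:g}]"
        for r in model.reactions.values()
        if r.lower_bound > 0 or r.upper_bound < 0 or r.lower_bound == r.upper_bound != 0
    ]
    return "forced-flux constraints: " + (", ".join(tight) if tight else "none")


def optimize(
    model: MetabolicModel,
    objective_reaction: str,
    direction: str = "max",
    extra_constraints: Sequence[LinearConstraint] = (),
) -> FluxSolution:
    """Maximize or minimize one reaction flux subject to S·v = 0 and bounds.

    ``extra_constraints`` adds linear inequalities (used e.g. to cap total
    carbon flux through the cleavage reactions).  Infeasibility is reported
    as a :class:`FluxSolution` with ``status='infeasible'``; numerical solver
    failures raise :class:`SolverError` instead.
    """
    if objective_reaction not in model.reactions:
        raise ModelError(f"objective reaction {objective_reaction} not in model")
    if direction not in ("max", "min"):
        raise ModelError(f"direction must be max or min, got {direction!r}")
    rxn_ids, S, lb, ub = _build_matrices(model)
    j_obj = rxn_ids.index(objective_reaction)
    c = np.zeros(len(rxn_ids))
    c[j_obj] = -1.0 if direction == "max" else 1.0

    A_ub, b_ub = _extra_to_arrays(extra_constraints, rxn_ids)
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(
            status="infeasible",
            objective_value=float("nan"),
            objective_reaction=objective_reaction,
        )
    if res.status == 3:
        return FluxSolution(
            status="unbounded",
            objective_value=float("inf") if direction == "max" else float("-inf"),
            objective_reaction=objective_reaction,
        )
    if res.status != 0:
        raise SolverError(
            f"LP solver failed (status {res.status}: {res.message}); "
            + _diagnose_infeasible(model)
        )
    v = res.x
    _check_solution(S, lb, ub, v, tol_scale=max(1.0, np.abs(v).max()))
    return FluxSolution(
        status="optimal",
        objective_value=float(v[j_obj]),
        fluxes={rid: float(x) for rid, x in zip(rxn_ids, v)},
        objective_reaction=objective_reaction,
    )


def _extra_to_arrays(extra: Sequence[LinearConstraint], rxn_ids: list[str]):
    if not extra:
        return None, None
    A = np.zeros((len(extra), len(rxn_ids)))
    b = np.zeros(len(extra))
    index = {r: j for j, r in enumerate(rxn_ids)}
    for i, con in enumerate(extra):
        for rid, coef in con.coefficients.items():
            if rid not in index:
                raise ModelError(f"constraint {con.name!r}: unknown reaction {rid}")
            A[i, index[rid]] = coef
        b[i] = con.upper
    return A, b


def fix_flux(
    model: MetabolicModel, reaction: str, value: float, tol_frac: float = 0.0
) -> MetabolicModel:
    """Return a copy of the model with one flux pinned to value·(1 ± tol_frac).

    The interval is oriented so lower <= upper also for negative values.  The
    original model is never modified.  A value outside the reaction's current
    structural bounds is allowed (the caller may be deliberately probing) but
    logged as a warning since it guarantees infeasibility.
    """
    if reaction not in model.reactions:
        raise ModelError(f"no such reaction: {reaction}")
    if tol_frac < 0:
        raise ModelError("tol_frac must be >= 0")
    rxn = model.reactions[reaction]
    half = abs(value) * tol_frac
    lo, hi = value - half, value + half
    if hi < rxn.lower_bound or lo > rxn.upper_bound:
        import logging

        logging.getLogger(__name__).warning(
            "fixing %s to [%g, %g] outside structural bounds [%g, %g]: "
            "model will be infeasible",
            reaction, lo, hi, rxn.lower_bound, rxn.upper_bound,
        )
    out = model.copy()
    out.set_bounds(reaction, lo, hi)
    return out


def minimize_total_flux(
    model: MetabolicModel,
    objective_reaction: str,
    objective_value: float,
    extra_constraints: Sequence[LinearConstraint] = (),
) -> FluxSolution:
    """Parsimonious tie-break: among flux states attaining the given objective
    value (within tolerance), return one minimizing sum |v_j|.

    Implemented by splitting each flux into forward and reverse non-negative
    parts and minimizing their sum; the split carries no integer variables,
    and the unit cost guarantees forward and reverse parts are never
    simultaneously active at the optimum.
    """
    if objective_reaction not in model.reactions:
        raise ModelError(f"objective reaction {objective_reaction} not in model")
    pinned = model.copy()
    half = max(abs(objective_value) * REL_TOL, ABS_TOL)
    rxn = pinned.reactions[objective_reaction]
    lo = max(rxn.lower_bound, objective_value - half)
    hi = min(rxn.upper_bound, objective_value + half)
    if lo > hi:
        lo, hi = objective_value - half, objective_value + half
    pinned.set_bounds(objective_reaction, lo, hi)

    rxn_ids, S, lb, ub = _build_matrices(pinned)
    n = len(rxn_ids)
    # v = p - q with p, q >= 0; bounds arranged per sign of [lb, ub]
    bounds = []
    for j in range(n):
        if lb[j] >= 0:
            bounds.append((lb[j], ub[j]))  # p
        else:
            bounds.append((0.0, max(ub[j], 0.0)))
    for j in range(n):
        if ub[j] <= 0:
            bounds.append((-ub[j], -lb[j]))  # q
        else:
            bounds.append((0.0, max(-lb[j], 0.0)))
    A_eq = np.hstack([S, -S])
    A_ub, b_ub = _extra_to_arrays(extra_constraints, rxn_ids)
    if A_ub is not None:
        A_ub = np.hstack([A_ub, -A_ub])
    res = linprog(
        np.ones(2 * n),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(
            f"no flux state attains {objective_reaction} = {objective_value:g}; "
            + _diagnose_infeasible(pinned)
        )
    if res.status != 0:
        raise SolverError(f"parsimony LP failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    _check_solution(S, lb, ub, v, tol_scale=max(1.0, np.abs(v).max()))
    return FluxSolution(
        status="optimal",
        objective_value=float(v[rxn_ids.index(objective_reaction)]),
        fluxes={rid: float(x) for rid, x in zip(rxn_ids, v)},
        objective_reaction=objective_reaction,
        parsimonious=True,
    )


def optimize_parsimonious(
    model: MetabolicModel,
    objective_reaction: str,
    direction: str = "max",
    extra_constraints: Sequence[LinearConstraint] = (),
) -> FluxSolution:
    """Optimize, then re-solve for the minimum-total-flux representative."""
    first = optimize(model, objective_reaction, direction, extra_constraints)
    if not first.optimal:
        return first
    return minimize_total_flux(
        model, objective_reaction, first.objective_value, extra_constraints
    )
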