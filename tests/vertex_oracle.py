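"""Brute-force vertex-enumeration oracle for small flux polytopes.

Independent of the package's LP path: enumerates candidate vertices of
{v : S v = 0, lb <= v <= ub} by fixing every size-(n - rank S) subset of
variables at a bound combination and solving the remaining square system.
Exponential, so only usable for networks of <= ~10 reactions — which is
the point: it cross-checks the simplex solver on enumerable instances.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9) -> list[np.ndarray]:
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    vertices: list[np.ndarray] = []
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # fixing this subset cannot give a unique basic solution
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            if free:
                rhs = -S[:, fixed] @ np.array(bounds_choice) if fixed else np.zeros(
                    S.shape[0]
                )
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.abs(S @ v).max() > 1e-7 if S.size else False:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            vertices.append(v)
    return vertices


def brute_force_optimum(S, lb, ub, c, direction: str = "max"):
    """Optimal objective value over the polytope, or None when infeasible."""
    S, lb, ub, c = (np.asarray(x, dtype=float) for x in (S, lb, ub, c))
    verts = enumerate_vertices(S, lb, ub)
    if not verts:
        return None
    values = [float(c @ v) for v in verts]
    return max(values) if direction == "max" else min(values)
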