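"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: linear programs are
solved by enumerating basic feasible solutions (vertices) of
``{x : A x = b, lb <= x <= ub}``, and quadratic programs by exhaustive
active-set enumeration with closed-form equality-constrained least squares.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def enumerate_vertices(A, b, lb, ub, tol=1e-7):
    """All vertices of {x: A x = b, lb <= x <= ub} by basis enumeration.

    Fixes n - rank(A) variables at a bound and solves for the rest; feasible
    solutions are vertices.  Exponential — for tiny systems only.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = A.shape
    rank = np.linalg.matrix_rank(A, tol=1e-10)
    n_fix = n - rank
    vertices = []
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A_free = A[:, free]
        if np.linalg.matrix_rank(A_free, tol=1e-10) < rank:
            continue
        for bounds_choice in product(*[(lb[j], ub[j]) for j in fixed]):
            if any(not np.isfinite(v) for v in bounds_choice):
                continue
            rhs = b - A[:, list(fixed)] @ np.array(bounds_choice)
            x_free, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            if np.max(np.abs(A_free @ x_free - rhs)) > tol:
                continue
            x = np.empty(n)
            x[list(fixed)] = bounds_choice
            x[free] = x_free
            if np.all(x >= lb - tol) and np.all(x <= ub + tol):
                vertices.append(np.clip(x, lb, ub))
    return vertices


def lp_by_vertex_enumeration(c, A, b, lb, ub, maximize=False):
    """Optimal value of a bounded LP via vertex enumeration."""
    verts = enumerate_vertices(A, b, lb, ub)
    assert verts, "no vertex found: infeasible or unbounded toy LP"
    vals = [float(np.dot(c, v)) for v in verts]
    return max(vals) if maximize else min(vals)


def fba_oracle(network, objective=None):
    """FBA optimum by vertex enumeration of the steady-state polytope."""
    S, _, rxns = network.stoichiometric_matrix()
    lb, ub = zip(*network.bounds())
    c = np.zeros(len(rxns))
    c[rxns.index(objective or network.biomass_reaction)] = 1.0
    return lp_by_vertex_enumeration(c, S, np.zeros(S.shape[0]), lb, ub, maximize=True)


def pfba_oracle(network, objective=None):
    """Minimal Σ|v| at optimal growth via the split-variable lifted polytope."""
    growth = fba_oracle(network, objective)
    S, _, rxns = network.stoichiometric_matrix()
    n = len(rxns)
    A = np.hstack([S, -S])
    lbs, ubs = zip(*network.bounds())
    lb = np.array([max(l, 0.0) for l in lbs] + [max(-u, 0.0) for u in ubs])
    ub = np.array([max(u, 0.0) for u in ubs] + [max(-l, 0.0) for l in lbs])
    j = rxns.index(objective or network.biomass_reaction)
    growth_row = np.zeros(2 * n)
    growth_row[j] = 1.0
    growth_row[n + j] = -1.0
    A = np.vstack([A, growth_row])
    b = np.zeros(A.shape[0])
    b[-1] = growth
    return lp_by_vertex_enumeration(np.ones(2 * n), A, b, lb, ub, maximize=False)


def qp_oracle(network, measured, tol=1e-8):
    """Stage-1 MFA QP by brute-force enumeration of box active sets.

    For every assignment of variables to {free, at-lb, at-ub} the
    equality-constrained least-squares subproblem is solved in closed form
    (nullspace + lstsq); the best box-feasible candidate is the global
    optimum of the convex QP.  Exponential (3^n) — tiny networks only.
    """
    S, _, rxns = network.stoichiometric_matrix()
    n = len(rxns)
    idx = np.array([rxns.index(r) for r in measured])
    target = np.array([measured[r] for r in measured])
    lb, ub = map(np.array, zip(*network.bounds()))

    P = np.zeros((len(idx), n))
    P[np.arange(len(idx)), idx] = 1.0

    best = None
    for assignment in product((0, 1, 2), repeat=n):
        fixed = [j for j, a in enumerate(assignment) if a != 0]
        free = [j for j, a in enumerate(assignment) if a == 0]
        x = np.zeros(n)
        for j in fixed:
            x[j] = lb[j] if assignment[j] == 1 else ub[j]
        if not np.all(np.isfinite(x[fixed] if fixed else [0.0])):
            continue
        if free:
            rhs = -S[:, fixed] @ x[fixed] if fixed else np.zeros(S.shape[0])
            S_free = S[:, free]
            x_part, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            if np.max(np.abs(S_free @ x_part - rhs)) > 1e-7:
                continue  # no steady state with this pinning
            # nullspace of the free block
            _, sv, Vt = np.linalg.svd(S_free)
            rank = int(np.sum(sv > 1e-10 * (sv[0] if len(sv) else 1.0)))
            N = Vt[rank:].T
            x[free] = x_part
            if N.size:
                # least squares in the nullspace coordinates
                A_ls = P[:, free] @ N
                b_ls = target - P @ x
                z, *_ = np.linalg.lstsq(A_ls, b_ls, rcond=None)
                x[free] = x_part + N @ z
        if np.max(np.abs(S @ x)) > 1e-6:
            continue
        if np.any(x < lb - tol) or np.any(x > ub + tol):
            continue
        val = float(np.sum((x[idx] - target) ** 2))
        if best is None or val < best[0] - 1e-12:
            best = (val, np.clip(x, lb, ub))
    assert best is not None, "QP oracle found no feasible candidate"
    return best[1]
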