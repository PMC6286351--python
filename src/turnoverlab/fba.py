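"""Flux balance analysis and parsimonious FBA.

Both problems are linear programs over the steady-state polytope
``{v : S v = 0, lb <= v <= ub}`` and are solved with scipy's HiGHS backend.
pFBA is the standard two-stage scheme: fix the growth optimum, then minimize
the total absolute flux Σ|v|, linearized by splitting each reaction into
non-negative forward and backward parts.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .network import FluxVector, MetabolicNetwork

__all__ = ["FbaError", "solve_fba", "solve_pfba", "STEADY_STATE_TOL"]

#: reported steady-state tolerance: every returned flux vector satisfies
#: ``max |S v| <= STEADY_STATE_TOL``.
STEADY_STATE_TOL = 1e-6

_FEAS_TOL = 1e-9


class FbaError(RuntimeError):
    """LP did not return an optimal solution (infeasible/unbounded)."""

    def __init__(self, message: str, status: str = "error"):
        super().__init__(message)
        self.status = status


def _solve_lp(c, A_eq, b_eq, bounds, context: str):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": _FEAS_TOL,
                 "dual_feasibility_tolerance": _FEAS_TOL},
    )
    if res.status != 0:
        kind = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
        raise FbaError(f"{context}: LP {kind} ({res.message})", status=kind)
    return res


def solve_fba(
    network: MetabolicNetwork,
    objective: str | None = None,
    direction: str = "max",
) -> FluxVector:
    """Maximize (or minimize) one reaction flux at steady state.

    Parameters
    ----------
    objective
        Reaction id; defaults to the network's biomass reaction.
    direction
        ``"max"`` or ``"min"``.

    Raises
    ------
    FbaError
        If the LP is infeasible or unbounded.
    KeyError
        If the objective reaction does not exist.
    """
    if objective is None:
        objective = network.biomass_reaction
    if objective not in network.reactions:
        raise KeyError(f"unknown objective reaction {objective!r}")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, _, rxns = network.stoichiometric_matrix()
    c = np.zeros(len(rxns))
    c[rxns.index(objective)] = -1.0 if direction == "max" else 1.0
    res = _solve_lp(c, S, np.zeros(S.shape[0]), network.bounds(), f"FBA({objective})")
    fluxes = dict(zip(rxns, res.x))
    obj = fluxes[objective]
    return FluxVector(fluxes, obj)


def solve_pfba(
    network: MetabolicNetwork,
    objective: str | None = None,
    lexicographic: bool = False,
) -> FluxVector:
    """Parsimonious FBA: minimal Σ|v| among growth-optimal flux states.

    Stage 1 finds the growth optimum; stage 2 pins growth to that optimum
    (relative tolerance 1e-9) and minimizes the sum of absolute fluxes over
    split forward/backward variables.  With ``lexicographic=True`` a third
    pass additionally fixes Σ|v| and minimizes each |v_i| in reaction-index
    order, making the full flux vector reproducible even on degenerate
    optimal faces (one extra LP per reaction — intended for small networks).
    """
    if objective is None:
        objective = network.biomass_reaction
    growth = solve_fba(network, objective).objective_value

    S, _, rxns = network.stoichiometric_matrix()
    n = len(rxns)
    # v = f - b with f, b >= 0; columns [f | b]
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    bounds = []
    for lb, ub in network.bounds():
        bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for lb, ub in network.bounds():
        bounds.append((max(-ub, 0.0), max(-lb, 0.0)))
    # pin the growth optimum (forward part carries it for growth >= 0)
    j = rxns.index(objective)
    slack = 1e-9 * max(1.0, abs(growth))
    lo, hi = growth - slack, growth + slack
    if growth >= 0:
        bounds[j] = (max(lo, 0.0), max(hi, 0.0))
    else:
        bounds[n + j] = (max(-hi, 0.0), max(-lo, 0.0))

    c = np.ones(2 * n)
    res = _solve_lp(c, A_eq, b_eq, bounds, "pFBA")
    total = res.fun
    x = res.x

    if lexicographic:
        # fix Σ|v| via an explicit row, then greedily minimize each |v_i|
        A_fix = np.vstack([A_eq, np.ones(2 * n)])
        b_fix = np.concatenate([b_eq, [total + 1e-9 * max(1.0, total)]])
        bnds = list(bounds)
        for i in range(n):
            c_i = np.zeros(2 * n)
            c_i[i] = c_i[n + i] = 1.0
            res_i = _solve_lp(c_i, A_fix, b_fix, bnds, f"pFBA-lex({rxns[i]})")
            bnds[i] = (0.0, max(res_i.x[i], 0.0))
            bnds[n + i] = (0.0, max(res_i.x[n + i], 0.0))
            x = res_i.x

    v = x[:n] - x[n:]
    fluxes = dict(zip(rxns, v))
    return FluxVector(fluxes, fluxes[objective])
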