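"""MFA-constrained flux states: a three-stage fit to measured fluxes.

Given fluxes measured by metabolic flux analysis for a subset of reactions,
the fitted network flux state is obtained in three stages:

1. quadratic program — minimize Σ_i (v_i − v_data,i)² over the steady-state
   polytope (least-squares projection of the data onto the feasible set);
2. pin the measured reactions at their stage-1 values and maximize flux
   through the ATP maintenance reaction (LP);
3. additionally pin the ATP maintenance flux at its stage-2 optimum and
   minimize the Euclidean norm ‖v‖₂ (QP) as a parsimony objective.

The QPs are solved with scipy's SLSQP on an orthonormal reduction of the
steady-state constraints, which is ample at the network sizes this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .fba import FbaError, _solve_lp
from .network import FluxVector, MetabolicNetwork

__all__ = [
    "MfaFitResult",
    "mfa_constrained_flux",
    "read_measured_fluxes",
    "write_mfa_result",
]

#: measured-flux pinning tolerance for stages 2-3 (equality bounds are
#: widened by this amount to avoid numerical infeasibility)
PIN_TOL = 1e-6


@dataclass
class MfaFitResult:
    stage1_flux: FluxVector
    atpm_optimum: float
    final_flux: FluxVector
    pearson_to_data: float


def read_measured_fluxes(path) -> dict[str, dict[str, float]]:
    """Read a measured-flux TSV (reaction_id, flux, condition) into
    per-condition dictionaries."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for cond, grp in table.groupby("condition"):
        out[str(cond)] = dict(zip(grp.reaction_id, grp.flux.astype(float)))
    return out


def write_mfa_result(result: MfaFitResult, path, condition: str = "") -> None:
    """Write one fit as TSV: final fluxes plus the fit summary columns."""
    with open(path, "w") as fh:
        fh.write("condition\treaction_id\tflux\tatpm_optimum\tpearson_to_data\n")
        for rid, v in result.final_flux.fluxes.items():
            fh.write(
                f"{condition}\t{rid}\t{v:.12g}\t{result.atpm_optimum:.12g}"
                f"\t{result.pearson_to_data:.6g}\n"
            )


def _solve_qp(Q_diag_idx, target, S, bounds, x0, context):
    """Minimize sum((x[idx] - target)^2) (or ||x||^2 if idx is None) s.t. Sx=0, bounds."""
    n = S.shape[1]
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])

    if Q_diag_idx is None:
        def fun(x):
            return float(x @ x)

        def jac(x):
            return 2.0 * x
    else:
        idx = np.asarray(Q_diag_idx)
        t = np.asarray(target)

        def fun(x):
            d = x[idx] - t
            return float(d @ d)

        def jac(x):
            g = np.zeros(n)
            g[idx] = 2.0 * (x[idx] - t)
            return g

    # reduce S v = 0 to an orthonormal full-rank basis: redundant
    # stoichiometric rows make the SQP subproblems singular
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(sv > 1e-10 * sv[0])) if len(sv) else 0
    B = Vt[:rank]
    x0 = np.clip(x0, lb, ub)
    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        constraints=[LinearConstraint(B, 0.0, 0.0)],
        bounds=list(zip(lb, ub)),
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    violation = float(np.max(np.abs(S @ res.x))) if S.size else 0.0
    if (not res.success and violation > 1e-6) or not np.all(np.isfinite(res.x)):
        raise FbaError(f"{context}: QP failed ({res.message})", status="infeasible")
    return np.clip(res.x, lb, ub)


def mfa_constrained_flux(
    network: MetabolicNetwork,
    measured: dict[str, float],
    atpm_reaction: str,
) -> MfaFitResult:
    """Fit a steady-state flux vector to measured fluxes (three stages).

    Parameters
    ----------
    measured
        Reaction id -> measured flux (mmol·gDW⁻¹·h⁻¹).
    atpm_reaction
        Id of the ATP maintenance reaction used as the stage-2 objective.

    Raises
    ------
    KeyError
        Unknown measured or ATPM reaction id.
    FbaError
        Stage-wise infeasibility; the message names the failing stage.
    """
    for rid in list(measured) + [atpm_reaction]:
        if rid not in network.reactions:
            raise KeyError(f"unknown reaction {rid!r}")

    S, _, rxns = network.stoichiometric_matrix()
    n = len(rxns)
    bounds = network.bounds()
    meas_ids = list(measured)
    meas_idx = [rxns.index(r) for r in meas_ids]
    v_data = np.array([measured[r] for r in meas_ids])

    # stage 1: QP projection of the data onto the steady-state polytope
    x1 = _solve_qp(meas_idx, v_data, S, bounds, np.zeros(n), "MFA stage 1")
    stage1 = FluxVector(dict(zip(rxns, x1)), float(np.sum((x1[meas_idx] - v_data) ** 2)))

    # stage 2: pin measured fluxes, maximize ATP maintenance
    bounds2 = list(bounds)
    for j in meas_idx:
        bounds2[j] = (x1[j] - PIN_TOL, x1[j] + PIN_TOL)
    c = np.zeros(n)
    c[rxns.index(atpm_reaction)] = -1.0
    res2 = _solve_lp(c, S, np.zeros(S.shape[0]), bounds2, "MFA stage 2")
    atpm_opt = float(res2.x[rxns.index(atpm_reaction)])

    # stage 3: additionally pin ATPM, minimize ||v||_2
    bounds3 = list(bounds2)
    bounds3[rxns.index(atpm_reaction)] = (atpm_opt - PIN_TOL, atpm_opt + PIN_TOL)
    x3 = _solve_qp(None, None, S, bounds3, res2.x, "MFA stage 3")
    final = FluxVector(dict(zip(rxns, x3)), float(np.linalg.norm(x3)))

    if len(meas_ids) >= 2 and np.std(v_data) > 0 and np.std(x3[meas_idx]) > 0:
        pearson = float(np.corrcoef(v_data, x3[meas_idx])[0, 1])
    else:
        pearson = float("nan")
    return MfaFitResult(stage1, atpm_opt, final, pearson)
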