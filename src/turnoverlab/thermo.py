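"""Reaction Gibbs energies and the thermodynamic efficiency η_rev.

For a reaction with signed stoichiometric coefficients ``S_i`` over
metabolite concentrations ``x_i`` (M), the reaction quotient is
``Q = Π x_i^{S_i}`` and the Gibbs energy is ``ΔG = RT·ln(Q/K_eq)``
(kJ·mol⁻¹, natural log, R = 8.314 J·mol⁻¹·K⁻¹).  The thermodynamic
efficiency is ``η_rev = 1 − exp(ΔG/RT) = 1 − Q/K_eq``: 0 at equilibrium and
approaching 1 for a perfectly forward-driven reaction.

Measurement gaps and uncertainty are handled by sampling log-concentration
and log-K_eq vectors uniformly over their bounding box, restricted to the
convex region where every high-flux reaction's ΔG sign opposes its flux
direction (a thermodynamic-feasibility surrogate).  Sampling uses a
hit-and-run walk, exact for this polytope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = [
    "R_KJ",
    "ThermoCondition",
    "ThermoResult",
    "ThermoFeasibilityError",
    "reaction_gibbs",
    "eta_rev",
    "thermo_feature",
]

#: gas constant in kJ·mol⁻¹·K⁻¹
R_KJ = 8.314e-3

#: default physiological concentration range (M) for unmeasured metabolites
DEFAULT_CONC_BOUNDS = (1e-6, 1e-1)


class ThermoFeasibilityError(RuntimeError):
    """No concentration/K_eq vector satisfies the directionality constraints."""


@dataclass
class ThermoCondition:
    """Point estimates and uncertainty bounds for one growth condition.

    ``concentrations``/``keq`` map ids to ``(value, lower, upper)`` tuples
    (all strictly positive, bounds bracketing the value); ``fluxes`` is the
    condition's flux vector, used to identify high-flux reactions whose
    direction constrains the sampling.
    """

    concentrations: dict[str, tuple[float, float, float]]
    keq: dict[str, tuple[float, float, float]]
    temperature: float = 298.15
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class ThermoResult:
    per_condition: pd.DataFrame  # columns: reaction, condition, delta_g, q, eta_rev
    mean_eta_rev: pd.Series  # reaction -> mean η_rev across conditions


def reaction_gibbs(
    stoich: dict[str, float],
    keq: float,
    concentrations: dict[str, float],
    temperature: float = 298.15,
) -> tuple[float, float]:
    """Return ``(ΔG in kJ/mol, Q)`` for one reaction.

    Raises
    ------
    KeyError
        A participating metabolite has no concentration (callers that can
        sample should do so rather than defaulting silently).
    ValueError
        Non-positive concentration or K_eq.
    """
    if keq <= 0:
        raise ValueError("K_eq must be strictly positive")
    ln_q = 0.0
    for met, coef in stoich.items():
        if met not in concentrations:
            raise KeyError(f"no concentration for metabolite {met!r}")
        x = concentrations[met]
        if x <= 0:
            raise ValueError(f"concentration of {met!r} must be strictly positive")
        ln_q += coef * np.log(x)
    delta_g = R_KJ * temperature * (ln_q - np.log(keq))
    return float(delta_g), float(np.exp(ln_q))


def eta_rev(delta_g: float, temperature: float = 298.15) -> float:
    """Thermodynamic efficiency ``1 − exp(ΔG/RT)``.

    Total function of ΔG; values below 0 indicate a reaction operating in
    reverse relative to its written direction.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(1.0 - np.exp(delta_g / (R_KJ * temperature)))


# ---------------------------------------------------------------------------
# feasibility-constrained sampling
# ---------------------------------------------------------------------------


def _hit_and_run(A, b, lo, hi, x0, n_samples, burn_in, rng):
    """Uniform samples from {x : A x <= b, lo <= x <= hi} starting at x0."""
    d = len(x0)
    x = x0.copy()
    out = np.empty((n_samples, d))
    kept = 0
    steps = 0
    total = n_samples + burn_in
    free = (hi - lo) > 1e-12  # frozen (point-estimate) coordinates never move
    while kept < n_samples:
        u = rng.normal(size=d)
        u[~free] = 0.0
        nrm = np.linalg.norm(u)
        if nrm == 0:
            out[kept:] = x
            break
        u /= nrm
        # chord limits from the box
        t_lo, t_hi = -np.inf, np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            for bound, sense in ((hi - x, 1.0), (lo - x, -1.0)):
                t = bound / u
                pos = u * sense > 0
                neg = u * sense < 0
                if pos.any():
                    t_hi = min(t_hi, np.min(t[pos]))
                if neg.any():
                    t_lo = max(t_lo, np.max(t[neg]))
            if A is not None and len(A):
                au = A @ u
                slack = b - A @ x
                pos = au > 1e-300
                neg = au < -1e-300
                if pos.any():
                    t_hi = min(t_hi, np.min(slack[pos] / au[pos]))
                if neg.any():
                    t_lo = max(t_lo, np.max(slack[neg] / au[neg]))
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi < t_lo:
            steps += 1
            continue
        x = x + rng.uniform(t_lo, t_hi) * u
        steps += 1
        if steps > burn_in:
            out[kept] = x
            kept += 1
        if steps > 100 * total:  # pragma: no cover - safety valve
            raise RuntimeError("hit-and-run failed to mix")
    return out


def _feasible_point(A, b, lo, hi):
    """Max-slack interior point via LP; returns (x, slack)."""
    d = len(lo)
    if A is None or not len(A):
        return 0.5 * (lo + hi), np.inf
    # maximize s s.t. A x + s <= b, lo <= x <= hi, s <= cap
    cap = 1.0
    c = np.zeros(d + 1)
    c[-1] = -1.0
    A_ub = np.hstack([A, np.ones((A.shape[0], 1))])
    bounds = [(l, h) for l, h in zip(lo, hi)] + [(None, cap)]
    res = linprog(c, A_ub=A_ub, b_ub=b, bounds=bounds, method="highs")
    if res.status != 0:
        raise ThermoFeasibilityError("feasibility LP failed")
    return res.x[:-1], float(res.x[-1])


def thermo_feature(
    network: MetabolicNetwork,
    conditions: list[ThermoCondition],
    flux_threshold: float = 0.1,
    n_samples: int = 1000,
    burn_in: int = 100,
    seed: int = 0,
    default_conc_bounds: tuple[float, float] = DEFAULT_CONC_BOUNDS,
    reactions: list[str] | None = None,
) -> ThermoResult:
    """Sample-averaged ΔG, Q and η_rev per reaction and condition.

    Per condition, concentration and K_eq vectors are sampled uniformly (in
    log space) within their bounds, subject to sign(ΔG) opposing the flux
    direction for every reaction with ``|v| > flux_threshold``
    (mmol·gDW⁻¹·h⁻¹).  Reactions below the threshold are unconstrained but
    still evaluated.  η_rev is averaged over samples within a condition and
    then across conditions.

    Raises
    ------
    ThermoFeasibilityError
        If no feasible vector exists; the message names violated reactions.
    """
    rng = np.random.default_rng(seed)
    if reactions is None:
        reactions = [
            r.id
            for r in network.reactions.values()
            if not r.is_exchange and r.id != network.biomass_reaction
        ]
    rows = []
    for ci, cond in enumerate(conditions):
        mets = sorted(
            {m for rid in reactions for m in network.reactions[rid].stoichiometry}
        )
        midx = {m: i for i, m in enumerate(mets)}
        d_m = len(mets)
        evaluable = [r for r in reactions if r in cond.keq]
        kidx = {r: d_m + i for i, r in enumerate(evaluable)}
        d = d_m + len(evaluable)

        lo = np.empty(d)
        hi = np.empty(d)
        for m, i in midx.items():
            if m in cond.concentrations:
                _, l, h = cond.concentrations[m]
            else:
                l, h = default_conc_bounds
            lo[i], hi[i] = np.log(l), np.log(h)
        for r, i in kidx.items():
            _, l, h = cond.keq[r]
            lo[i], hi[i] = np.log(l), np.log(h)

        # directionality constraints: for |v|>thr and v>0: S·y − ln k <= 0
        A_rows, b_rows, constrained = [], [], []
        for r in evaluable:
            v = cond.fluxes.get(r, 0.0)
            if abs(v) <= flux_threshold:
                continue
            row = np.zeros(d)
            for m, coef in network.reactions[r].stoichiometry.items():
                row[midx[m]] += coef
            row[kidx[r]] = -1.0
            if v < 0:
                row = -row
            A_rows.append(row)
            b_rows.append(0.0)
            constrained.append(r)
        A = np.array(A_rows) if A_rows else None
        b = np.array(b_rows) if b_rows else None

        degenerate = np.allclose(lo, hi, atol=1e-12)
        if degenerate:
            samples = 0.5 * (lo + hi)[None, :]
            if A is not None and np.any(A @ samples[0] > 1e-9):
                bad = [
                    constrained[i]
                    for i in np.nonzero(A @ samples[0] > 1e-9)[0]
                ]
                raise ThermoFeasibilityError(
                    f"condition {ci}: point estimates violate directionality "
                    f"for {bad}"
                )
        else:
            x0, slack = _feasible_point(A, b, lo, hi)
            if A is not None and slack <= 0:
                viol = A @ x0 - b
                bad = [constrained[i] for i in np.nonzero(viol >= -1e-12)[0]]
                raise ThermoFeasibilityError(
                    f"condition {ci}: no feasible concentration vector; "
                    f"violated reactions: {bad}"
                )
            samples = _hit_and_run(A, b, lo, hi, x0, n_samples, burn_in, rng)

        rt = R_KJ * cond.temperature
        for r in evaluable:
            row = np.zeros(d)
            for m, coef in network.reactions[r].stoichiometry.items():
                row[midx[m]] += coef
            ln_q = samples @ row
            ln_k = samples[:, kidx[r]]
            dg = rt * (ln_q - ln_k)
            eta = 1.0 - np.exp(dg / rt)
            rows.append(
                {
                    "reaction": r,
                    "condition": ci,
                    "delta_g": float(np.mean(dg)),
                    "q": float(np.mean(np.exp(ln_q))),
                    "eta_rev": float(np.mean(eta)),
                }
            )
    per_condition = pd.DataFrame(rows)
    mean_eta = (
        per_condition.groupby("reaction")["eta_rev"].mean()
        if len(per_condition)
        else pd.Series(dtype=float)
    )
    mean_eta.name = "eta_rev"
    return ThermoResult(per_condition, mean_eta)
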