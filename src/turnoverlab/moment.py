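"""Enzyme-capacity-constrained proteome allocation (MOMENT).

MOMENT extends FBA with enzyme variables: each catalyzed flux is coupled to
the concentration of its enzyme through the effective turnover rate,

    v_i <= 3600 · k_eff,i · (enzyme concentration available to i),

and the total metabolic enzyme mass is capped by a protein budget
``Σ_g MW_g · E_g <= C`` (default C = 0.32 g·gDW⁻¹).  GPR rules expand to
isozyme alternatives (OR: the reaction's usage splits across alternatives,
each coupled separately) and complexes (AND: every subunit must be present
at the complex usage, each paying its own mass).  Reactions whose enzymes
are membrane-localized fall outside the scope of the turnover predictions
and use a default rate (65 s⁻¹).

Solving the LP yields growth rate, fluxes and per-gene enzyme masses;
normalized masses are the predicted metabolic proteome mass fractions that
are compared against measured abundances by log10 RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .fba import FbaError
from .network import MetabolicNetwork, gpr_alternatives

__all__ = [
    "read_keff_csv",
    "write_keff_csv",
    "write_comparison_report",
    "MomentModel",
    "MomentSolution",
    "ProteomeComparison",
    "solve_moment",
    "predicted_mass_fractions",
    "compare_proteome",
    "MEMBRANE_DEFAULT_KEFF",
    "PROTEIN_BUDGET",
]

SECONDS_PER_HOUR = 3600.0
#: default turnover for membrane enzymes, s⁻¹
MEMBRANE_DEFAULT_KEFF = 65.0
#: metabolic protein budget, g protein per gDW
PROTEIN_BUDGET = 0.32
#: effectively unconstrained uptake bound, mmol·gDW⁻¹·h⁻¹
OPEN_UPTAKE = -1000.0


@dataclass
class MomentSolution:
    """Optimal growth, fluxes and enzyme allocation of one MOMENT LP."""

    growth_rate: float
    fluxes: dict[str, float]
    enzyme_concentration: dict[str, float]  # gene -> mmol·gDW⁻¹
    enzyme_mass: dict[str, float]  # gene -> g·gDW⁻¹
    protein_budget: float
    budget_dual: float  # shadow price of the protein budget

    def mass_fractions(self) -> pd.Series:
        return predicted_mass_fractions(self)


class MomentModel:
    """Capacity-constrained growth maximization built from a network.

    Parameters
    ----------
    network
        The metabolic network (GPRs and gene molecular weights required for
        every catalyzed reaction).
    keff
        Reaction id -> forward effective turnover rate in s⁻¹.  Reverse
        rates may be given in ``keff_reverse`` and default to the forward
        value.  Membrane-flagged reactions always use ``membrane_default``.
    default_keff
        Fallback for catalyzed reactions absent from ``keff``; if None, a
        missing rate raises.
    environment
        Exchange-reaction lower bounds; every other exchange uptake is
        closed.  ``None`` keeps the network's own bounds.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        keff: Mapping[str, float],
        keff_reverse: Mapping[str, float] | None = None,
        membrane_default: float = MEMBRANE_DEFAULT_KEFF,
        protein_budget: float = PROTEIN_BUDGET,
        default_keff: float | None = None,
        environment: Mapping[str, float] | None = None,
    ):
        if protein_budget <= 0:
            raise ValueError("protein budget must be positive")
        self.network = (
            network.with_exchange_bounds(environment)
            if environment is not None
            else network
        )
        self.keff = dict(keff)
        self.keff_reverse = dict(keff_reverse or {})
        self.membrane_default = membrane_default
        self.protein_budget = protein_budget
        self.default_keff = default_keff

    def _rate(self, rid: str, direction: str) -> float:
        rxn = self.network.reactions[rid]
        if rxn.membrane:
            return self.membrane_default
        if direction == "reverse" and rid in self.keff_reverse:
            k = self.keff_reverse[rid]
        elif rid in self.keff:
            k = self.keff[rid]
        elif self.default_keff is not None:
            k = self.default_keff
        else:
            raise KeyError(f"no k_eff for catalyzed reaction {rid!r}")
        if k <= 0:
            raise ValueError(f"k_eff for {rid!r} must be positive, got {k}")
        return float(k)

    def solve(self) -> MomentSolution:
        """Build and solve the LP; raises :class:`FbaError` if infeasible."""
        net = self.network
        S, _, rxns = net.stoichiometric_matrix()
        n = len(rxns)
        bounds: list[tuple[float, float]] = []
        for lb, ub in net.bounds():  # forward parts
            bounds.append((max(lb, 0.0), max(ub, 0.0)))
        for lb, ub in net.bounds():  # backward parts
            bounds.append((max(-ub, 0.0), max(-lb, 0.0)))

        # usage variables: one per (reaction, direction, isozyme alternative)
        usage: list[tuple[int, str, frozenset[str], float]] = []
        for j, rid in enumerate(rxns):
            rxn = net.reactions[rid]
            alts = gpr_alternatives(rxn.gpr)
            if not alts:
                continue
            if bounds[j][1] > 0:
                rate = self._rate(rid, "forward")
                for alt in alts:
                    usage.append((j, "forward", alt, rate))
            if bounds[n + j][1] > 0:
                rate = self._rate(rid, "reverse")
                for alt in alts:
                    usage.append((j, "reverse", alt, rate))
        m = len(usage)
        nvar = 2 * n + m
        bounds += [(0.0, None)] * m

        A_eq = np.hstack([S, -S, np.zeros((S.shape[0], m))])
        b_eq = np.zeros(S.shape[0])

        # coupling rows: v_dir - 3600 k Σ u <= 0, one row per catalyzed direction
        coupled: dict[tuple[int, str], list[int]] = {}
        for u_idx, (j, direction, _alt, _rate) in enumerate(usage):
            coupled.setdefault((j, direction), []).append(u_idx)
        A_ub_rows, b_ub = [], []
        for (j, direction), u_idxs in coupled.items():
            row = np.zeros(nvar)
            row[j if direction == "forward" else n + j] = 1.0
            for u_idx in u_idxs:
                rate = usage[u_idx][3]
                row[2 * n + u_idx] = -SECONDS_PER_HOUR * rate
            A_ub_rows.append(row)
            b_ub.append(0.0)
        # protein budget row
        budget_row = np.zeros(nvar)
        for u_idx, (_j, _d, alt, _rate) in enumerate(usage):
            budget_row[2 * n + u_idx] = sum(net.gene_mw[g] for g in alt)
        A_ub_rows.append(budget_row)
        b_ub.append(self.protein_budget)
        A_ub = np.vstack(A_ub_rows)

        c = np.zeros(nvar)
        j_bio = rxns.index(net.biomass_reaction)
        c[j_bio] = -1.0
        c[n + j_bio] = 1.0
        res = linprog(
            c, A_ub=A_ub, b_ub=np.array(b_ub), A_eq=A_eq, b_eq=b_eq,
            bounds=bounds, method="highs",
        )
        if res.status != 0:
            kind = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
            raise FbaError(f"MOMENT: LP {kind} ({res.message})", status=kind)

        x = res.x
        v = x[:n] - x[n : 2 * n]
        fluxes = dict(zip(rxns, v))
        conc: dict[str, float] = {g: 0.0 for g in net.genes()}
        for u_idx, (_j, _d, alt, _rate) in enumerate(usage):
            for g in alt:
                conc[g] += x[2 * n + u_idx]
        mass = {g: net.gene_mw[g] * e for g, e in conc.items()}
        budget_dual = float(-res.ineqlin.marginals[-1])
        return MomentSolution(
            growth_rate=float(fluxes[net.biomass_reaction]),
            fluxes=fluxes,
            enzyme_concentration=conc,
            enzyme_mass=mass,
            protein_budget=self.protein_budget,
            budget_dual=budget_dual,
        )


def solve_moment(
    network: MetabolicNetwork, keff: Mapping[str, float], **kwargs
) -> MomentSolution:
    """Functional wrapper around :class:`MomentModel`."""
    return MomentModel(network, keff, **kwargs).solve()


def predicted_mass_fractions(solution: MomentSolution) -> pd.Series:
    """Per-gene metabolic proteome mass fraction (sums to 1 over expressed
    genes); raises if no gene is expressed."""
    mass = pd.Series(solution.enzyme_mass, dtype=float)
    mass = mass[mass > 0]
    total = float(mass.sum())
    if total <= 0:
        raise ValueError("no expressed gene in the solution")
    out = mass / total
    out.name = "mass_fraction"
    return out


def write_keff_csv(keff: Mapping[str, float], path, direction: str = "forward",
                   source: str = "data") -> None:
    """Write a turnover vector as CSV (reaction_id, direction, keff_per_s,
    source); ``source`` tags provenance: data, median, ensemble or default."""
    pd.DataFrame(
        {
            "reaction_id": list(keff),
            "direction": direction,
            "keff_per_s": [float(keff[r]) for r in keff],
            "source": source,
        }
    ).to_csv(path, index=False)


def read_keff_csv(path) -> pd.DataFrame:
    """Read a turnover-vector CSV written by :func:`write_keff_csv`."""
    table = pd.read_csv(path)
    missing = {"reaction_id", "direction", "keff_per_s", "source"} - set(table.columns)
    if missing:
        raise ValueError(f"keff CSV missing columns: {sorted(missing)}")
    return table


def write_comparison_report(rows: list[dict], path) -> None:
    """Write per-condition comparison rows (condition, parameterization, n,
    RMSE) as TSV."""
    pd.DataFrame(rows, columns=["condition", "parameterization", "n", "rmse"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class ProteomeComparison:
    """Predicted vs. measured log10 mass fractions on the matched gene set."""

    table: pd.DataFrame  # index gene; columns predicted_log10, measured_log10
    rmse: float
    n: int


def compare_proteome(
    predicted: pd.Series,
    measured_copies: pd.Series,
    gene_mw: Mapping[str, float],
    intersect_with: Iterable[Iterable[str]] | None = None,
    exclude: Iterable[str] = (),
) -> ProteomeComparison:
    """log10 RMSE between predicted and measured proteome mass fractions.

    Genes enter the comparison when predicted fraction > 0 and the measured
    abundance exceeds 0 copies/cell; ``exclude`` removes genes outside the
    prediction scope (membrane complexes, expression machinery);
    ``intersect_with`` optionally restricts to the genes other
    parameterizations could also predict, so RMSEs are comparable.  Both
    sides are renormalized over the final matched set.
    """
    matched = set(predicted[predicted > 0].index) & set(
        measured_copies[measured_copies > 0].index
    )
    matched -= set(exclude)
    if intersect_with is not None:
        for gene_set in intersect_with:
            matched &= set(gene_set)
    genes = sorted(matched)
    if not genes:
        raise ValueError("no genes left to compare after matching")
    pred = predicted.loc[genes].astype(float)
    pred = pred / pred.sum()
    meas_mass = pd.Series(
        {g: measured_copies[g] * gene_mw[g] for g in genes}, dtype=float
    )
    meas = meas_mass / meas_mass.sum()
    table = pd.DataFrame(
        {
            "predicted_log10": np.log10(pred),
            "measured_log10": np.log10(meas),
        }
    )
    rmse = float(
        np.sqrt(np.mean((table.predicted_log10 - table.measured_log10) ** 2))
    )
    return ProteomeComparison(table, rmse, len(genes))
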