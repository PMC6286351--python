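"""In-vivo apparent turnover rates (k_app) and their per-reaction maximum.

For a unique homomeric enzyme — a single-gene reaction whose gene product is
used by no other reaction — the apparent turnover rate in a condition is

    k_app = v / (3600 · E)   [s⁻¹]

with flux ``v`` in mmol·gDW⁻¹·h⁻¹ and enzyme abundance ``E`` in mmol·gDW⁻¹
(3600 s·h⁻¹ converts the flux to per-second units).  The per-reaction
maximum across conditions, k_app,max, is the in-vivo proxy for the enzyme's
catalytic turnover number.
"""

from __future__ import annotations

import pandas as pd

from .network import MetabolicNetwork

__all__ = ["compute_kapp_max", "unique_homomer_reactions"]

SECONDS_PER_HOUR = 3600.0


def unique_homomer_reactions(network: MetabolicNetwork) -> dict[str, str]:
    """Reactions catalyzed by a single-gene GPR whose gene maps to exactly
    one reaction; returns reaction id -> gene id."""
    out: dict[str, str] = {}
    for rid, rxn in network.reactions.items():
        if rxn.gpr is None or rxn.gpr[0] != "gene":
            continue
        gene = rxn.gpr[1]
        if len(network.reactions_for_gene(gene)) == 1:
            out[rid] = gene
    return out


def compute_kapp_max(
    proteomics: pd.DataFrame,
    fluxes: pd.DataFrame,
    network: MetabolicNetwork,
) -> pd.Series:
    """k_app,max (s⁻¹) per unique homomeric reaction.

    Parameters
    ----------
    proteomics
        Gene x condition enzyme abundances in mmol·gDW⁻¹.
    fluxes
        Reaction x condition fluxes in mmol·gDW⁻¹·h⁻¹ (columns must match
        the proteomics conditions).
    network
        Supplies the GPR rules that define eligibility.

    Conditions with non-positive flux or abundance are skipped; reactions
    with no eligible condition are omitted from the result.
    """
    conditions = [c for c in fluxes.columns if c in proteomics.columns]
    out: dict[str, float] = {}
    for rid, gene in unique_homomer_reactions(network).items():
        if rid not in fluxes.index or gene not in proteomics.index:
            continue
        best = None
        for cond in conditions:
            v = float(fluxes.at[rid, cond])
            e = float(proteomics.at[gene, cond])
            if v > 0 and e > 0:
                k = v / (SECONDS_PER_HOUR * e)
                best = k if best is None else max(best, k)
        if best is not None:
            out[rid] = best
    s = pd.Series(out, dtype=float)
    s.index.name = "reaction"
    s.name = "kapp_max"
    return s
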