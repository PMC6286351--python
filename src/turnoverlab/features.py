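"""Reaction-level feature assembly.

Builds the machine-learning feature matrix at the direction-specific
reaction level: network features (mean sampled flux, the generalist
property, substrate counts), gene-level structural features summarized
through GPR rules, and the linearization step that puts skewed quantities on
a log10 scale and temperatures on an inverse-Kelvin (Arrhenius) scale.

Missingness is represented with NaN throughout; a value's missingness mask
is simply ``isna`` on the assembled frame.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, gpr_genes

__all__ = [
    "generalist_feature",
    "substrate_count",
    "summarize_gene_features",
    "linearize",
    "delinearize",
    "LOG10_FIELDS",
]

#: fields transformed to log10 by :func:`linearize`
LOG10_FIELDS = (
    "flux",
    "molecular_weight",
    "km",
    "substrate_concentration",
    "product_concentration",
    "kcat_in_vitro",
    "kapp_max",
)


def generalist_feature(network: MetabolicNetwork, reaction_id: str) -> float:
    """Maximum number of *other* reactions using any of this reaction's genes.

    A gene product used only by this reaction scores 0; an empty GPR yields
    NaN (feature missing).
    """
    genes = network.reactions[reaction_id].genes()
    if not genes:
        return float("nan")
    best = 0
    for g in genes:
        others = [r for r in network.reactions_for_gene(g) if r != reaction_id]
        best = max(best, len(others))
    return float(best)


def substrate_count(
    network: MetabolicNetwork, reaction_id: str, direction: str = "forward"
) -> int:
    """Distinct reactant-side metabolites, excluding water and protons.

    ``direction`` selects which side counts as reactants: the negative
    stoichiometric coefficients for ``"forward"``, the positive ones for
    ``"backward"``.  Water and protons are matched by elemental formula, not
    by id.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward|backward, got {direction!r}")
    sign = -1.0 if direction == "forward" else 1.0
    count = 0
    for met, coef in network.reactions[reaction_id].stoichiometry.items():
        if coef * sign <= 0:
            continue
        m = network.metabolites[met]
        if m.is_water or m.is_proton:
            continue
        count += 1
    return count


def _summarize_node(node, gene_df: pd.DataFrame, mw_column: str) -> pd.Series | None:
    """Recursive GPR summarization; returns None when no gene has data."""
    kind = node[0]
    if kind == "gene":
        g = node[1]
        if g not in gene_df.index:
            return None
        row = gene_df.loc[g]
        return None if row.isna().all() else row.astype(float)
    parts = [_summarize_node(c, gene_df, mw_column) for c in node[1]]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    stacked = pd.concat(parts, axis=1)
    agg = stacked.mean(axis=1)  # isozymes and non-MW complex features: average
    if kind == "and" and mw_column in stacked.index:
        mw = stacked.loc[mw_column]
        # complexes: subunit molecular weights add up
        agg[mw_column] = mw.sum() if mw.notna().any() else np.nan
    return agg


def summarize_gene_features(
    network: MetabolicNetwork,
    gene_features: pd.DataFrame,
    mw_column: str = "molecular_weight",
) -> pd.DataFrame:
    """Summarize per-gene structural features to the reaction level.

    AND nodes (enzyme complexes) sum molecular weight and average the other
    features; OR nodes (isozymes) average everything; the rules apply
    recursively over each reaction's GPR tree.  Genes without data are
    skipped; a reaction whose GPR has no data at all gets an all-NaN row.

    Parameters
    ----------
    gene_features
        DataFrame indexed by gene id, one column per structural feature
        (must include ``mw_column`` if molecular weights are to be summed).
    """
    cols = list(gene_features.columns)
    rows = {}
    for rid, rxn in network.reactions.items():
        if rxn.gpr is None:
            rows[rid] = pd.Series(np.nan, index=cols)
            continue
        agg = _summarize_node(rxn.gpr, gene_features, mw_column)
        rows[rid] = pd.Series(np.nan, index=cols) if agg is None else agg
    out = pd.DataFrame.from_dict(rows, orient="index")[cols]
    out.index.name = "reaction"
    return out


def linearize(
    table: pd.DataFrame,
    log_fields: tuple[str, ...] = LOG10_FIELDS,
    temperature_field: str = "assay_temperature",
) -> pd.DataFrame:
    """Transform features toward linearity.

    Listed fields are log10-transformed (non-positive values become NaN with
    a warning); ``assay_temperature`` in °C becomes
    ``assay_inverse_temperature`` in K⁻¹; everything else passes through.
    """
    out = table.copy()
    for col in log_fields:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            warnings.warn(
                f"linearize: {int(bad.sum())} non-positive value(s) in {col!r} "
                "masked as missing",
                stacklevel=2,
            )
            vals = vals.where(~bad)
        out[col] = np.log10(vals)
    if temperature_field in out.columns:
        kelvin = out[temperature_field].astype(float) + 273.15
        out["assay_inverse_temperature"] = 1.0 / kelvin
        out = out.drop(columns=[temperature_field])
    return out


def delinearize(
    table: pd.DataFrame,
    log_fields: tuple[str, ...] = LOG10_FIELDS,
    inverse_temperature_field: str = "assay_inverse_temperature",
) -> pd.DataFrame:
    """Inverse of :func:`linearize` (for round-trip checks and reporting)."""
    out = table.copy()
    for col in log_fields:
        if col in out.columns:
            out[col] = np.power(10.0, out[col].astype(float))
    if inverse_temperature_field in out.columns:
        out["assay_temperature"] = 1.0 / out[inverse_temperature_field] - 273.15
        out = out.drop(columns=[inverse_temperature_field])
    return out
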