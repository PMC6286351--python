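"""Synthetic inputs: toy networks, planted turnover data, proteomics.

Every input the pipeline consumes can be generated here at desk scale, so
all stages are testable without genome-scale downloads:

* :func:`generate_toy_gem` — small mass-balanced networks with exchange
  reactions for carbon/nitrogen/sulfur/phosphate sources, an optional
  oxygen exchange (usable, never required), a linear catabolic chain with a
  branch, GPRs mixing single genes, AND-complexes and OR-isozymes, membrane
  transporters, and a balanced biomass reaction.
* :func:`generate_turnover_dataset` — reaction-level features (network
  features computed through the pipeline, structural/biochemical features
  drawn from documented distributions) with a planted log-linear
  feature→turnover relationship, Gaussian log10 noise, configurable
  missingness, in-vitro-flavoured records with curation decoys, and an
  in-vivo-flavoured observation set restricted to single-gene reactions.
* :func:`generate_proteomics` — per-condition MOMENT solutions under a true
  turnover vector, converted to copies/cell with multiplicative lognormal
  noise.

The planted model's population R² is computable from its coefficients, the
realized feature covariance and the noise variance, which gives recovery
tests an exact target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import TurnoverRecord
from .environments import average_sampled_flux
from .features import generalist_feature, linearize, substrate_count, summarize_gene_features
from .moment import MomentModel
from .network import MetabolicNetwork, Metabolite, Reaction, parse_gpr

__all__ = [
    "ToyGemSpec",
    "PlantedTurnoverModel",
    "TurnoverDataset",
    "ProteomicsData",
    "generate_toy_gem",
    "generate_turnover_dataset",
    "generate_proteomics",
    "write_fixtures",
    "COPIES_PER_MMOL_PER_GDW",
]

#: copies/cell per (mmol·gDW⁻¹): Avogadro · 10⁻³ mol/mmol / 10¹² cells·gDW⁻¹.
#: Only relative abundances matter downstream; the constant is fixed for
#: round-tripping.
COPIES_PER_MMOL_PER_GDW = 6.022e8


# ---------------------------------------------------------------------------
# toy network
# ---------------------------------------------------------------------------


@dataclass
class ToyGemSpec:
    """Shape of a generated toy network."""

    n_carbon_sources: int = 3
    n_nitrogen_sources: int = 2
    n_sulfur_sources: int = 2
    n_phosphate_sources: int = 2
    n_internal_reactions: int = 8
    fraction_reversible: float = 0.25
    n_isozyme_reactions: int = 2
    n_complex_reactions: int = 2
    include_blocked_reaction: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_carbon_sources", "n_nitrogen_sources",
                     "n_sulfur_sources", "n_phosphate_sources"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_internal_reactions < 3:
            raise ValueError("n_internal_reactions must be >= 3")


def generate_toy_gem(spec: ToyGemSpec) -> MetabolicNetwork:
    """Deterministically generate a growth-capable toy network.

    The carbon backbone is ``source -> c1 -> m1 -> ... -> mL`` with a branch
    ``2·m_mid -> w`` feeding biomass alongside ``mL``; nitrogen, sulfur and
    phosphate are taken up into one-atom currency metabolites.  Biomass
    consumes the currencies into a single balanced biomass metabolite that
    is exported, so every internal reaction is elementally balanced.
    """
    rng = np.random.default_rng(spec.seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    gene_mw: dict[str, float] = {}
    gene_counter = [0]

    def new_gene() -> str:
        gene_counter[0] += 1
        g = f"g{gene_counter[0]:03d}"
        gene_mw[g] = float(np.round(10 ** rng.normal(np.log10(40.0), 0.2), 3))
        return g

    # currencies and chain intermediates (all single-atom carbon for balance)
    mets += [Metabolite("c1", {"C": 1}), Metabolite("n1", {"N": 1}),
             Metabolite("s1", {"S": 1}), Metabolite("p1", {"P": 1})]
    L = spec.n_internal_reactions
    chain_mets = [f"m{k}" for k in range(1, L + 1)]
    mets += [Metabolite(m, {"C": 1}) for m in chain_mets]
    mets += [Metabolite("w", {"C": 2})]
    mets += [Metabolite("o2_e", {"O": 2})]

    # sources: exchanges + membrane uptake reactions
    def add_sources(prefix, n, element, atoms_choices, target, per_atom):
        for i in range(n):
            atoms = int(rng.choice(atoms_choices))
            mid = f"{prefix}{i}_e"
            mets.append(Metabolite(mid, {element: atoms}))
            rxns.append(Reaction(f"EX_{prefix}{i}", {mid: -1.0}, 0.0, 1000.0))
            rxns.append(
                Reaction(
                    f"UPT_{prefix}{i}",
                    {mid: -1.0, target: float(atoms) / per_atom},
                    0.0,
                    1000.0,
                    parse_gpr(new_gene()),
                    membrane=True,
                )
            )

    add_sources("cs", spec.n_carbon_sources, "C", [2, 3, 4, 6], "c1", 1)
    add_sources("ns", spec.n_nitrogen_sources, "N", [1, 2], "n1", 1)
    add_sources("ss", spec.n_sulfur_sources, "S", [1], "s1", 1)
    add_sources("ps", spec.n_phosphate_sources, "P", [1], "p1", 1)
    rxns.append(Reaction("EX_o2", {"o2_e": -1.0}, 0.0, 1000.0))

    # carbon chain c1 -> m1 -> ... -> mL, plus one aerobic parallel step
    prev = "c1"
    chain_rids = []
    for k, m in enumerate(chain_mets, start=1):
        rid = f"CH{k}"
        lb = -1000.0 if rng.random() < spec.fraction_reversible else 0.0
        rxns.append(Reaction(rid, {prev: -1.0, m: 1.0}, lb, 1000.0,
                             parse_gpr(new_gene())))
        chain_rids.append(rid)
        prev = m
    # aerobic alternative for the first chain step (oxygen usable, not needed)
    rxns.append(
        Reaction("CH1_aero", {"c1": -1.0, "o2_e": -1.0, "m1": 1.0}, 0.0, 1000.0,
                 parse_gpr(new_gene()))
    )
    # branch: 2 m_mid -> w
    mid_met = chain_mets[len(chain_mets) // 2 - 1]
    rxns.append(Reaction("BR1", {mid_met: -2.0, "w": 1.0}, 0.0, 1000.0,
                         parse_gpr(new_gene())))

    # GPR variants: isozymes and complexes on chain reactions
    rid_by_name = {r.id: r for r in rxns}
    iso_targets = chain_rids[: spec.n_isozyme_reactions]
    for rid in iso_targets:
        rid_by_name[rid].gpr = parse_gpr(f"{new_gene()} or {new_gene()}")
    cplx_targets = chain_rids[spec.n_isozyme_reactions:
                              spec.n_isozyme_reactions + spec.n_complex_reactions]
    for rid in cplx_targets:
        rid_by_name[rid].gpr = parse_gpr(f"{new_gene()} and {new_gene()}")
    # a generalist gene shared by the last two plain chain reactions
    plain = [r for r in chain_rids if r not in iso_targets and r not in cplx_targets]
    if len(plain) >= 2:
        shared = new_gene()
        for rid in plain[-2:]:
            rid_by_name[rid].gpr = parse_gpr(shared)

    if spec.include_blocked_reaction:
        mets += [Metabolite("dead_a", {"C": 1}), Metabolite("dead_b", {"C": 1})]
        rxns.append(Reaction("DEAD", {"dead_a": -1.0, "dead_b": 1.0}, 0.0, 1000.0,
                             parse_gpr(new_gene())))

    # balanced biomass: 8 mL + 1 w + 2 n1 + 1 s1 + 1 p1 -> biomass_met
    bio_formula = {"C": 10, "N": 2, "S": 1, "P": 1}
    mets.append(Metabolite("biomass_met", bio_formula))
    rxns.append(
        Reaction(
            "BIOMASS",
            {chain_mets[-1]: -8.0, "w": -1.0, "n1": -2.0, "s1": -1.0,
             "p1": -1.0, "biomass_met": 1.0},
            0.0,
            1000.0,
        )
    )
    rxns.append(Reaction("EX_biomass", {"biomass_met": -1.0}, 0.0, 1000.0))

    for r in rxns:
        if r.gpr is not None:
            r.ec_class = int(rng.integers(1, 7))
    net = MetabolicNetwork(mets, rxns, "BIOMASS", gene_mw, oxygen_exchange="EX_o2")
    net.validate()
    return net


# ---------------------------------------------------------------------------
# planted turnover model
# ---------------------------------------------------------------------------

#: default planted coefficients on the linearized (log10) feature scale;
#: sign structure: turnover rises with flux, falls with active-site depth,
#: solvent exposure and the generalist property.
DEFAULT_COEFFICIENTS = {
    "flux": 0.45,
    "generalist": -0.25,
    "active_site_depth": -0.50,
    "active_site_exposure": -0.60,
    "molecular_weight": 0.30,
    "km": 0.25,
    "eta_rev": 0.40,
}


@dataclass
class PlantedTurnoverModel:
    """Log-linear feature→turnover ground truth.

    Exactly one of ``noise_sigma`` (log10 units) or ``target_r2`` must be
    set; with ``target_r2`` the noise is solved from the realized signal
    variance so the population R² is exact by construction.
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float = 1.2  # log10 s⁻¹ -> median turnover ~16 s⁻¹
    noise_sigma: float | None = None
    target_r2: float | None = None
    missing_fractions: dict[str, float] = field(default_factory=dict)
    block_missing_fraction: float = 0.0  # rows losing all structural features
    seed: int = 0

    def __post_init__(self):
        if (self.noise_sigma is None) == (self.target_r2 is None):
            raise ValueError("set exactly one of noise_sigma and target_r2")
        if self.target_r2 is not None and not (0.0 < self.target_r2 < 1.0):
            raise ValueError("target_r2 must lie in (0, 1)")

    def signal(self, features: pd.DataFrame) -> pd.Series:
        cols = [c for c in self.coefficients if c in features.columns]
        z = features[cols].astype(float)
        return sum(
            self.coefficients[c] * z[c] for c in cols
        ) + self.intercept

    def resolve_sigma(self, features: pd.DataFrame) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        var_signal = float(np.var(self.signal(features).to_numpy(), ddof=0))
        return float(np.sqrt(var_signal * (1.0 / self.target_r2 - 1.0)))

    def implied_r2(self, features: pd.DataFrame) -> float:
        """Population R² implied by the realized design and the noise."""
        var_signal = float(np.var(self.signal(features).to_numpy(), ddof=0))
        sigma = self.resolve_sigma(features)
        return var_signal / (var_signal + sigma**2)


_STRUCTURAL_BLOCK = (
    "active_site_depth",
    "active_site_exposure",
    "active_site_hydrophobicity",
    "n_active_site_residues",
)


@dataclass
class TurnoverDataset:
    """Everything :func:`generate_turnover_dataset` emits."""

    features: pd.DataFrame  # linearized, with missingness
    features_complete: pd.DataFrame  # linearized, before missingness
    y_true_log10: pd.Series  # per catalyzed reaction
    keff_true: pd.Series  # s⁻¹
    kapp_observations: pd.Series  # in-vivo-flavoured subset, log10 s⁻¹
    kcat_records: list[TurnoverRecord]
    reaction_map: dict[str, str]
    noise_sigma: float
    implied_r2: float


def _draw_gene_features(genes: list[str], network, rng) -> pd.DataFrame:
    n = len(genes)
    return pd.DataFrame(
        {
            "molecular_weight": [network.gene_mw[g] for g in genes],
            "disorder_fraction": rng.beta(2, 6, n),
            "active_site_depth": np.exp(rng.normal(np.log(6.0), 0.45, n)),
            "active_site_exposure": rng.beta(2, 2, n),
            "active_site_hydrophobicity": rng.normal(-0.5, 1.0, n),
            "n_active_site_residues": 3.0 + rng.poisson(2.0, n),
        },
        index=genes,
    )


def generate_turnover_dataset(
    network: MetabolicNetwork,
    planted: PlantedTurnoverModel,
    n_environments: int = 200,
    flux_feature: dict[str, float] | None = None,
    in_vivo_fraction: float = 0.7,
    in_vitro_fraction: float = 0.7,
    in_vitro_noise: float = 0.25,
) -> TurnoverDataset:
    """Features plus planted turnover observations for one network.

    ``flux_feature`` may be supplied to reuse a precomputed mean sampled
    flux; otherwise it is computed here with ``n_environments`` draws.
    The in-vitro record list includes curation decoys: one mutant, one
    inhibited record, one cross-database duplicate and one unmappable key.
    """
    rng = np.random.default_rng(planted.seed)
    catalyzed = [r.id for r in network.reactions.values() if r.gpr is not None]

    if flux_feature is None:
        flux_feature = average_sampled_flux(
            network, n_environments, seed=int(rng.integers(2**31 - 1))
        )
    gene_features = _draw_gene_features(sorted(network.genes()), network, rng)
    summarized = summarize_gene_features(network, gene_features).loc[catalyzed]

    raw = pd.DataFrame(index=pd.Index(catalyzed, name="reaction"))
    raw["flux"] = [abs(flux_feature.get(r, 0.0)) for r in catalyzed]
    raw["generalist"] = [generalist_feature(network, r) for r in catalyzed]
    raw["n_substrates"] = [substrate_count(network, r) for r in catalyzed]
    for col in summarized.columns:
        raw[col] = summarized[col]
    n = len(catalyzed)
    raw["ec_class"] = pd.Categorical(
        [str(network.reactions[r].ec_class or rng.integers(1, 7)) for r in catalyzed]
    )
    raw["eta_rev"] = rng.beta(4, 2, n)
    raw["km"] = 10 ** rng.normal(-4.0, 0.7, n)
    raw["substrate_concentration"] = 10 ** rng.normal(-3.0, 0.8, n)
    raw["product_concentration"] = 10 ** rng.normal(-3.0, 0.8, n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero fluxes become missing, by design
        complete = linearize(raw)

    sigma = planted.resolve_sigma(complete.fillna(complete.median(numeric_only=True)))
    signal = planted.signal(complete.fillna(complete.median(numeric_only=True)))
    y_true = signal + rng.normal(0.0, sigma, n)
    y_true.name = "log10_turnover"
    keff_true = (10.0**y_true).rename("keff_per_s")
    implied = planted.implied_r2(complete.fillna(complete.median(numeric_only=True)))

    # missingness
    table = complete.copy()
    for colname, frac in planted.missing_fractions.items():
        if colname in table.columns and frac > 0:
            mask = rng.random(n) < frac
            table.loc[mask, colname] = np.nan
    if planted.block_missing_fraction > 0:
        mask = rng.random(n) < planted.block_missing_fraction
        for colname in _STRUCTURAL_BLOCK:
            if colname in table.columns:
                table.loc[mask, colname] = np.nan

    # in-vivo-flavoured observations: single-gene reactions only
    single_gene = [
        r for r in catalyzed if network.reactions[r].gpr[0] == "gene"
    ]
    n_vivo = max(2, int(round(in_vivo_fraction * len(single_gene))))
    vivo_ids = list(rng.choice(single_gene, size=min(n_vivo, len(single_gene)),
                               replace=False))
    kapp_obs = y_true.loc[vivo_ids] + rng.normal(0.0, 0.05, len(vivo_ids))
    kapp_obs.name = "log10_kapp_max"

    # in-vitro-flavoured records with curation decoys
    n_vitro = max(2, int(round(in_vitro_fraction * n)))
    vitro_ids = list(rng.choice(catalyzed, size=min(n_vitro, n), replace=False))
    records: list[TurnoverRecord] = []
    reaction_map = {f"key_{r}": r for r in catalyzed}

    def mk(i, rid, **kw):
        value = float(
            10 ** (y_true.loc[rid] + rng.normal(0.0, in_vitro_noise))
        )
        defaults = dict(
            record_id=f"rec{i:03d}",
            reaction_key=f"key_{rid}",
            value=value,
            source_db="BRENDA",
            publication_id=f"pub{i:03d}",
            year=int(rng.integers(1985, 2018)),
            assay_ph=float(np.round(rng.normal(7.0, 0.5), 2)),
            assay_temperature=float(np.round(rng.normal(30.0, 4.0), 1)),
        )
        defaults.update(kw)
        return TurnoverRecord(**defaults)

    i = 0
    for rid in vitro_ids:
        records.append(mk(i, rid, source_db=str(rng.choice(["BRENDA", "METACYC", "SABIO"]))))
        i += 1
    # decoys
    rid0 = vitro_ids[0]
    records.append(mk(i, rid0, mutant=True)); i += 1
    records.append(mk(i, rid0, inhibitor_note=True, source_db="METACYC")); i += 1
    dup_pub = records[0].publication_id
    dup_db = "SABIO" if records[0].source_db != "SABIO" else "METACYC"
    records.append(
        mk(i, rid0, source_db=dup_db, publication_id=dup_pub,
           reaction_key=records[0].reaction_key)
    ); i += 1
    records.append(mk(i, rid0, reaction_key="key_unmappable")); i += 1

    return TurnoverDataset(
        features=table,
        features_complete=complete,
        y_true_log10=y_true,
        keff_true=keff_true,
        kapp_observations=kapp_obs,
        kcat_records=records,
        reaction_map=reaction_map,
        noise_sigma=sigma,
        implied_r2=implied,
    )


@dataclass
class PlantedRegression:
    """Network-free planted regression sample (rows are pseudo-reactions)."""

    features: pd.DataFrame  # with missingness
    features_complete: pd.DataFrame
    y: pd.Series  # log10 turnover
    noise_sigma: float
    implied_r2: float


def generate_planted_regression(
    n_rows: int,
    planted: PlantedTurnoverModel,
) -> PlantedRegression:
    """Draw feature rows directly from the documented marginals.

    Bypasses the network so regression behaviour can be studied at any
    sample size; columns and scales match :func:`generate_turnover_dataset`
    (already linearized), and features are drawn independently, so the
    implied population R² follows from the realized design covariance.
    """
    rng = np.random.default_rng(planted.seed)
    idx = pd.Index([f"rx{i:04d}" for i in range(n_rows)], name="reaction")
    complete = pd.DataFrame(
        {
            "flux": rng.normal(0.9, 0.6, n_rows),
            "generalist": rng.poisson(1.2, n_rows).astype(float),
            "n_substrates": 1.0 + rng.poisson(1.0, n_rows),
            "molecular_weight": rng.normal(np.log10(40.0), 0.2, n_rows),
            "disorder_fraction": rng.beta(2, 6, n_rows),
            "active_site_depth": np.exp(rng.normal(np.log(6.0), 0.45, n_rows)),
            "active_site_exposure": rng.beta(2, 2, n_rows),
            "active_site_hydrophobicity": rng.normal(-0.5, 1.0, n_rows),
            "n_active_site_residues": 3.0 + rng.poisson(2.0, n_rows),
            "ec_class": pd.Categorical(rng.integers(1, 7, n_rows).astype(str)),
            "eta_rev": rng.beta(4, 2, n_rows),
            "km": rng.normal(-4.0, 0.7, n_rows),
            "substrate_concentration": rng.normal(-3.0, 0.8, n_rows),
            "product_concentration": rng.normal(-3.0, 0.8, n_rows),
        },
        index=idx,
    )
    sigma = planted.resolve_sigma(complete)
    y = planted.signal(complete) + rng.normal(0.0, sigma, n_rows)
    y.name = "log10_turnover"
    implied = planted.implied_r2(complete)

    table = complete.copy()
    for colname, frac in planted.missing_fractions.items():
        if colname in table.columns and frac > 0:
            mask = rng.random(n_rows) < frac
            table.loc[mask, colname] = np.nan
    if planted.block_missing_fraction > 0:
        mask = rng.random(n_rows) < planted.block_missing_fraction
        for colname in _STRUCTURAL_BLOCK:
            if colname in table.columns:
                table.loc[mask, colname] = np.nan
    return PlantedRegression(table, complete, y, sigma, implied)


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------


@dataclass
class ProteomicsData:
    abundances: pd.DataFrame  # gene x condition, copies/cell
    fluxes: pd.DataFrame  # reaction x condition, mmol·gDW⁻¹·h⁻¹
    solutions: dict[str, object]  # condition -> MomentSolution
    copies_per_mmol: float = COPIES_PER_MMOL_PER_GDW


def generate_proteomics(
    network: MetabolicNetwork,
    keff_true: pd.Series | dict,
    conditions: dict[str, dict[str, float]],
    noise_sigma_log10: float = 0.0,
    seed: int = 0,
    protein_budget: float | None = None,
) -> ProteomicsData:
    """Per-condition MOMENT proteomes under a known turnover vector.

    ``conditions`` maps condition names to exchange lower-bound environments
    (e.g. ``{"glc": {"EX_cs0": -1000, "EX_o2": -1000, ...}}``); infeasible
    conditions are skipped with a warning.  Abundances are converted to
    copies/cell with :data:`COPIES_PER_MMOL_PER_GDW` and multiplied by
    lognormal noise of the given log10 sigma.
    """
    keff = dict(pd.Series(keff_true))
    rng = np.random.default_rng(seed)
    abund: dict[str, pd.Series] = {}
    flux: dict[str, pd.Series] = {}
    solutions: dict[str, object] = {}
    kwargs = {}
    if protein_budget is not None:
        kwargs["protein_budget"] = protein_budget
    for name, env in conditions.items():
        try:
            sol = MomentModel(network, keff, environment=env, **kwargs).solve()
        except Exception as err:  # infeasible condition
            warnings.warn(f"condition {name!r} skipped: {err}")
            continue
        conc = pd.Series(sol.enzyme_concentration, dtype=float)
        noise = 10 ** rng.normal(0.0, noise_sigma_log10, len(conc))
        abund[name] = conc * COPIES_PER_MMOL_PER_GDW * noise
        flux[name] = pd.Series(sol.fluxes, dtype=float)
        solutions[name] = sol
    if not abund:
        raise RuntimeError("no feasible condition")
    return ProteomicsData(
        pd.DataFrame(abund), pd.DataFrame(flux), solutions
    )


def write_fixtures(directory, seed: int = 0) -> dict[str, str]:
    """Write a seeded fixture set (network JSON, feature/turnover/proteomics
    CSVs) into ``directory``; returns the paths written."""
    import os

    os.makedirs(directory, exist_ok=True)
    net = generate_toy_gem(ToyGemSpec(seed=seed))
    planted = PlantedTurnoverModel(target_r2=0.76, seed=seed)
    data = generate_turnover_dataset(net, planted, n_environments=100)
    carbon = [r for r in net.exchange_reactions() if net.carbon_atoms(r) > 0]
    conditions = {
        f"cond_{rid}": {
            rid: -60.0 / net.carbon_atoms(rid),
            **{e: -1000.0 for e in net.exchange_reactions()
               if net.carbon_atoms(e) == 0 and e != "EX_biomass"},
        }
        for rid in carbon
    }
    prot = generate_proteomics(net, data.keff_true, conditions,
                               noise_sigma_log10=0.1, seed=seed)
    paths = {}
    paths["network"] = os.path.join(directory, "network.json")
    net.to_json(paths["network"])
    paths["features"] = os.path.join(directory, "features.csv")
    data.features.to_csv(paths["features"])
    paths["turnover"] = os.path.join(directory, "turnover_observations.csv")
    pd.DataFrame(
        {
            "reaction": data.kapp_observations.index,
            "log10_kapp_max": data.kapp_observations.to_numpy(),
        }
    ).to_csv(paths["turnover"], index=False)
    paths["proteomics"] = os.path.join(directory, "proteomics.csv")
    prot.abundances.to_csv(paths["proteomics"])
    return paths
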