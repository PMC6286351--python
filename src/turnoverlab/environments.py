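"""Random growth environments and the in-silico flux feature.

A growth environment opens a random subset of exchange reactions: oxygen
with probability 1/2, and for each of the elements C, N, S and P one source
drawn uniformly plus ``k ~ Binomial(2, 1/2)`` extra sources (drawn without
replacement, truncated to the available candidates).  Uptake bounds of
carbon-containing sources are normalized to the substrate's carbon atom
count so every environment supplies the same total carbon influx; other
sources are effectively unconstrained.  Environments that cannot sustain
growth are rejected and redrawn.

The flux feature is the per-reaction arithmetic mean of parsimonious-FBA
fluxes over many such environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import FbaError, solve_fba, solve_pfba
from .network import MetabolicNetwork

__all__ = [
    "EnvironmentSample",
    "EnvironmentSamplingError",
    "sample_environment",
    "apply_environment",
    "average_sampled_flux",
]

ELEMENTS = ("C", "N", "S", "P")


class EnvironmentSamplingError(RuntimeError):
    """No growth-sustaining environment found within the attempt cap."""


@dataclass
class EnvironmentSample:
    """One sampled growth environment."""

    oxygen_allowed: bool
    sources: dict[str, list[str]] = field(default_factory=dict)
    uptake_bounds: dict[str, float] = field(default_factory=dict)


def _draw_environment(
    network: MetabolicNetwork,
    rng: np.random.Generator,
    base_carbon_flux: float,
    unconstrained_bound: float,
) -> EnvironmentSample:
    # exchanges of biomass products are sinks, not nutrient candidates
    biomass = network.reactions[network.biomass_reaction]
    products = {m for m, coef in biomass.stoichiometry.items() if coef > 0}
    candidates: dict[str, list[str]] = {e: [] for e in ELEMENTS}
    for rid in network.exchange_reactions():
        if rid == network.oxygen_exchange:
            continue
        if next(iter(network.reactions[rid].stoichiometry)) in products:
            continue
        for e in network.exchange_elements(rid):
            candidates[e].append(rid)
    for e in ELEMENTS:
        if not candidates[e]:
            raise EnvironmentSamplingError(f"no exchange reaction supplies {e}")

    oxygen = bool(rng.random() < 0.5)
    sources: dict[str, list[str]] = {}
    opened: set[str] = set()
    for e in ELEMENTS:
        pool = candidates[e]
        k_extra = int(rng.binomial(2, 0.5))
        n_pick = min(1 + k_extra, len(pool))
        picked = [str(r) for r in rng.choice(pool, size=n_pick, replace=False)]
        sources[e] = picked
        opened |= set(picked)

    bounds: dict[str, float] = {}
    for rid in sorted(opened):
        n_c = network.carbon_atoms(rid)
        bounds[rid] = -base_carbon_flux / n_c if n_c > 0 else unconstrained_bound
    if oxygen and network.oxygen_exchange is not None:
        bounds[network.oxygen_exchange] = unconstrained_bound
    return EnvironmentSample(oxygen, sources, bounds)


def apply_environment(
    network: MetabolicNetwork, env: EnvironmentSample
) -> MetabolicNetwork:
    """Network copy with only the sampled uptakes open."""
    return network.with_exchange_bounds(env.uptake_bounds)


def sample_environment(
    network: MetabolicNetwork,
    rng: np.random.Generator | int,
    base_carbon_flux: float = 60.0,
    unconstrained_bound: float = -1000.0,
    attempt_cap: int = 10_000,
    growth_tol: float = 1e-6,
) -> EnvironmentSample:
    """Draw one growth-sustaining environment (rejection sampling).

    Raises
    ------
    EnvironmentSamplingError
        After ``attempt_cap`` consecutive non-growing draws.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for _ in range(attempt_cap):
        env = _draw_environment(network, rng, base_carbon_flux, unconstrained_bound)
        try:
            growth = solve_fba(apply_environment(network, env)).objective_value
        except FbaError:
            continue
        if growth > growth_tol:
            return env
    raise EnvironmentSamplingError(
        f"no growth-sustaining environment in {attempt_cap} attempts"
    )


def average_sampled_flux(
    network: MetabolicNetwork,
    n_environments: int,
    seed: int,
    base_carbon_flux: float = 60.0,
    attempt_cap: int = 10_000,
) -> dict[str, float]:
    """Mean pFBA flux per reaction over sampled growth environments.

    Deterministic given ``seed``; rejected (non-growing) environments do not
    count toward ``n_environments``.
    """
    if n_environments < 1:
        raise ValueError("n_environments must be >= 1")
    rng = np.random.default_rng(seed)
    rxns = network.reaction_ids
    acc = np.zeros(len(rxns))
    for _ in range(n_environments):
        env = sample_environment(
            network, rng, base_carbon_flux=base_carbon_flux, attempt_cap=attempt_cap
        )
        sol = solve_pfba(apply_environment(network, env))
        acc += np.array([sol.fluxes[r] for r in rxns])
    acc /= n_environments
    return dict(zip(rxns, acc))
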