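import numpy as np
import pytest

from turnoverlab.network import MetabolicNetwork, Metabolite, Reaction, parse_gpr
from turnoverlab.synthetic import ToyGemSpec, generate_toy_gem


def _exchange(rid, met, lb=0.0, ub=1000.0):
    return Reaction(rid, {met: -1.0}, lb, ub)


@pytest.fixture
def chain_network():
    """EX_A(-10) -> A -> B -> biomass: growth forced to 10 by the uptake."""
    mets = [
        Metabolite("A", {"C": 1}),
        Metabolite("B", {"C": 1}),
        Metabolite("bm", {"C": 1}),
    ]
    rxns = [
        _exchange("EX_A", "A", lb=-10.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, parse_gpr("g1")),
        Reaction("BIOMASS", {"B": -1.0, "bm": 1.0}, 0.0, 1000.0),
        _exchange("EX_bm", "bm"),
    ]
    return MetabolicNetwork(mets, rxns, "BIOMASS", {"g1": 40.0})


@pytest.fixture
def two_substrate_network():
    """Two substrates with different biomass yields (2 C vs 1 C)."""
    mets = [
        Metabolite("A", {"C": 2}),
        Metabolite("B", {"C": 1}),
        Metabolite("P", {"C": 1}),
        Metabolite("bm", {"C": 1}),
    ]
    rxns = [
        _exchange("EX_A", "A", lb=-10.0),
        _exchange("EX_B", "B", lb=-10.0),
        Reaction("RA", {"A": -1.0, "P": 2.0}, 0.0, 1000.0),
        Reaction("RB", {"B": -1.0, "P": 1.0}, 0.0, 1000.0),
        Reaction("BIOMASS", {"P": -1.0, "bm": 1.0}, 0.0, 1000.0),
        _exchange("EX_bm", "bm"),
    ]
    return MetabolicNetwork(mets, rxns, "BIOMASS")


@pytest.fixture
def parallel_routes_network():
    """A -> B directly, or A -> C -> B: equal yield, unequal route length."""
    mets = [
        Metabolite("A", {"C": 1}),
        Metabolite("B", {"C": 1}),
        Metabolite("C_int", {"C": 1}),
        Metabolite("bm", {"C": 1}),
    ]
    rxns = [
        _exchange("EX_A", "A", lb=-10.0),
        Reaction("DIRECT", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("LONG1", {"A": -1.0, "C_int": 1.0}, 0.0, 1000.0),
        Reaction("LONG2", {"C_int": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("BIOMASS", {"B": -1.0, "bm": 1.0}, 0.0, 1000.0),
        _exchange("EX_bm", "bm"),
    ]
    return MetabolicNetwork(mets, rxns, "BIOMASS")


def sources_network(carbon_atoms=(6,), with_oxygen=True):
    """One uptake route per listed carbon source plus single N/S/P sources;
    oxygen (if present) is never required for growth."""
    mets = [
        Metabolite("c1", {"C": 1}),
        Metabolite("n1", {"N": 1}),
        Metabolite("s1", {"S": 1}),
        Metabolite("p1", {"P": 1}),
        Metabolite("bm", {"C": 4, "N": 1, "S": 1, "P": 1}),
    ]
    rxns = []
    for i, atoms in enumerate(carbon_atoms):
        mets.append(Metabolite(f"cs{i}_e", {"C": atoms}))
        rxns.append(Reaction(f"EX_cs{i}", {f"cs{i}_e": -1.0}, 0.0, 1000.0))
        rxns.append(
            Reaction(f"UPT_cs{i}", {f"cs{i}_e": -1.0, "c1": float(atoms)}, 0.0, 1000.0)
        )
    for el, tgt in (("N", "n1"), ("S", "s1"), ("P", "p1")):
        mets.append(Metabolite(f"{el}_e", {el: 1}))
        rxns.append(Reaction(f"EX_{el}", {f"{el}_e": -1.0}, 0.0, 1000.0))
        rxns.append(Reaction(f"UPT_{el}", {f"{el}_e": -1.0, tgt: 1.0}, 0.0, 1000.0))
    oxygen = None
    if with_oxygen:
        mets.append(Metabolite("o2_e", {"O": 2}))
        rxns.append(Reaction("EX_o2", {"o2_e": -1.0}, 0.0, 1000.0))
        oxygen = "EX_o2"
    rxns.append(
        Reaction(
            "BIOMASS",
            {"c1": -4.0, "n1": -1.0, "s1": -1.0, "p1": -1.0, "bm": 1.0},
            0.0,
            1000.0,
        )
    )
    rxns.append(Reaction("EX_bm", {"bm": -1.0}, 0.0, 1000.0))
    return MetabolicNetwork(mets, rxns, "BIOMASS", oxygen_exchange=oxygen)


@pytest.fixture
def make_sources_network():
    return sources_network


@pytest.fixture(scope="session")
def toy_gem():
    return generate_toy_gem(ToyGemSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
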