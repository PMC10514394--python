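import pytest

from mdflux.generate import (
    GeneratorConfig,
    gen_branched_network,
    gen_coupled_motif,
    gen_linear_chain,
)
from mdflux.model import CompartModel, Metabolite, Reaction


@pytest.fixture
def gcfg():
    return GeneratorConfig()


@pytest.fixture
def chain_distributed(gcfg):
    """Canonical distributed-bottleneck chain: dG0 = (-5, +10)."""
    return gen_linear_chain(gcfg, [-5.0, 10.0])


@pytest.fixture
def chain_localized(gcfg):
    """Canonical localized-bottleneck chain: dG0 = (-30, +30)."""
    return gen_linear_chain(gcfg, [-30.0, 30.0])


@pytest.fixture
def motif(gcfg):
    return gen_coupled_motif(gcfg)


@pytest.fixture
def branched(gcfg):
    return gen_branched_network(gcfg)


def _met(mid, boundary=False):
    return Metabolite(id=mid, conc_lb=1e-6, conc_ub=1e-2, is_boundary=boundary)


@pytest.fixture
def trp_fragment():
    """Hand-built fragment of the l-tryptophan synthesis neighbourhood:
    the tryptophan-synthase partials, the aconitase partials and the two
    redundancy cases (orphan-substrate oxidase, isolated-stereoisomer
    dehydrogenase pair)."""
    mets = [
        _met("3ig3p_c"), _met("ser__L_c"), _met("g3p_c"), _met("h2o_c"),
        _met("trp__L_c"), _met("indole_c"), _met("pyr_c"), _met("nh4_c"),
        _met("cit_c"), _met("acon_C_c"), _met("icit_c"),
        _met("nmtrp_c"), _met("fald_c"), _met("h2o2_c"), _met("o2_c"),
        _met("r2hglut_c"), _met("akg_c"), _met("nadh_c"), _met("nad_c"),
    ]
    rxns = [
        Reaction(
            id="TRPS3",
            stoich={"3ig3p_c": -1.0, "g3p_c": 1.0, "indole_c": 1.0},
            genes=frozenset({"b1260", "b1261"}),
        ),
        Reaction(
            id="TRPS2",
            stoich={"indole_c": -1.0, "ser__L_c": -1.0, "h2o_c": 1.0, "trp__L_c": 1.0},
            dG0=-49.7, dG0_uncertainty=2.2,
            genes=frozenset({"b1260", "b1261"}),
        ),
        Reaction(
            id="TRPAS2_reverse",
            stoich={"indole_c": -1.0, "nh4_c": -1.0, "pyr_c": -1.0,
                    "h2o_c": 1.0, "trp__L_c": 1.0},
            dG0=-21.1, dG0_uncertainty=1.1, genes=frozenset({"b3708"}),
        ),
        Reaction(
            id="MTRPOXN",
            stoich={"nmtrp_c": -1.0, "h2o_c": -1.0, "o2_c": -1.0,
                    "fald_c": 1.0, "h2o2_c": 1.0, "trp__L_c": 1.0},
            dG0=-44.6, dG0_uncertainty=13.7, genes=frozenset({"b1059"}),
        ),
        Reaction(
            id="ACONTa",
            stoich={"cit_c": -1.0, "acon_C_c": 1.0, "h2o_c": 1.0},
            dG0=4.0, dG0_uncertainty=0.4, efficiency=3540.0,
            genes=frozenset({"b0118", "b1276"}),
        ),
        Reaction(
            id="ACONTb",
            stoich={"acon_C_c": -1.0, "h2o_c": -1.0, "icit_c": 1.0},
            dG0=4.3, dG0_uncertainty=0.45, efficiency=3540.0,
            genes=frozenset({"b0118", "b1276"}),
        ),
        # isolated R-stereoisomer substrate: consumed/produced nowhere else
        Reaction(
            id="ARHGDx",
            stoich={"akg_c": -1.0, "nadh_c": -1.0, "r2hglut_c": 1.0, "nad_c": 1.0},
            reversible=True, flux_lb=-1000.0, genes=frozenset({"b2913"}),
        ),
    ]
    return CompartModel(metabolites=mets, reactions=rxns, exchanges=set())
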