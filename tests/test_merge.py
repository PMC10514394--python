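import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdflux.generate import GeneratorConfig, gen_linear_chain, gen_random_model
from mdflux.merge import (
    MergeSpec,
    apply_scenario,
    find_redundant_reactions,
    merge_reactions,
    shared_gene_merge_hints,
    shut_reactions,
)
from mdflux.model import CompartModel, Metabolite, Reaction, ThermoConfig, split_reversible
from mdflux.opt import assemble_constraints, driving_force, solve_fba, solve_max_mdf

RT = 2.579


def _met(mid, boundary=False):
    return Metabolite(id=mid, conc_lb=1e-6, conc_ub=1e-2, is_boundary=boundary)


@pytest.fixture
def serine_partials():
    """The phosphoglycerate-dehydrogenase coupling: the NAD-releasing
    oxidation and the NADH-consuming reverse hydroxyglutarate reduction,
    both carried by the same gene."""
    mets = [
        _met("3pg_c"), _met("3php_c"), _met("akg_c"), _met("s2hglut_c"),
        _met("nad_c"), _met("nadh_c"), _met("h_c"),
    ]
    rxns = [
        Reaction(
            id="PGCD",
            stoich={"3pg_c": -1.0, "nad_c": -1.0, "3php_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
            dG0=26.4, efficiency=2000.0, genes=frozenset({"b2913"}),
        ),
        Reaction(
            id="AHGDx_reverse",
            stoich={"akg_c": -1.0, "nadh_c": -1.0, "h_c": -1.0, "s2hglut_c": 1.0, "nad_c": 1.0},
            dG0=-24.3, efficiency=145.44, genes=frozenset({"b2913"}),
        ),
    ]
    return CompartModel(metabolites=mets, reactions=rxns)


class TestMergeReactions:
    def test_serine_coupling_cancels_cofactors(self, serine_partials):
        res = merge_reactions(
            serine_partials,
            MergeSpec(
                "SerA",
                [("PGCD", 1), ("AHGDx_reverse", 1)],
                declared_intermediates={"nad_c", "nadh_c", "h_c"},
                dG0_override=2.1,
            ),
        )
        merged = res.merged_reaction
        assert merged.stoich == {
            "3pg_c": -1.0, "akg_c": -1.0, "3php_c": 1.0, "s2hglut_c": 1.0
        }
        assert res.cancelled == {"nad_c", "nadh_c", "h_c"}
        assert merged.dG0 == pytest.approx(2.1)
        assert "additivity dG0 = 2.1" in res.audit  # 26.4 - 24.3
        # the weaker catalytic step sets the merged efficiency
        assert merged.efficiency == pytest.approx(145.44)
        assert merged.genes == frozenset({"b2913"})
        assert merged.status == "added"
        assert res.new_model.reaction("PGCD").status == "shut"
        assert res.new_model.reaction("AHGDx_reverse").status == "shut"

    def test_tryptophan_synthase_overall_reaction(self, trp_fragment):
        res = merge_reactions(
            trp_fragment, MergeSpec("TRPS1_merged", [("TRPS3", 1), ("TRPS2", 1)])
        )
        assert res.cancelled == {"indole_c"}
        assert res.merged_reaction.stoich == {
            "3ig3p_c": -1.0, "ser__L_c": -1.0,
            "g3p_c": 1.0, "h2o_c": 1.0, "trp__L_c": 1.0,
        }

    def test_aconitase_reversible_pair(self, trp_fragment):
        res = merge_reactions(
            trp_fragment,
            MergeSpec("ACONT", [("ACONTa", 1), ("ACONTb", 1)], reversible_pair=True),
        )
        assert res.merged_reaction.stoich == {"cit_c": -1.0, "icit_c": 1.0}
        assert res.cancelled == {"acon_C_c", "h2o_c"}
        assert res.merged_reaction.dG0 == pytest.approx(8.3)
        rev = res.new_model.reaction("ACONT_r")
        assert rev.stoich == {"cit_c": 1.0, "icit_c": -1.0}
        assert rev.dG0 == pytest.approx(-8.3)
        assert rev.efficiency == res.merged_reaction.efficiency == 3540.0
        # uncertainties combine as a root sum of squares
        assert res.merged_reaction.dG0_uncertainty == pytest.approx(
            math.hypot(0.4, 0.45)
        )

    def test_declared_intermediate_must_cancel(self, serine_partials):
        with pytest.raises(ValueError, match="akg_c"):
            merge_reactions(
                serine_partials,
                MergeSpec("bad", [("PGCD", 1), ("AHGDx_reverse", 1)],
                          declared_intermediates={"akg_c"}),
            )

    def test_pure_lumping_warns_in_audit(self):
        mets = [_met("A"), _met("B"), _met("C"), _met("D")]
        rxns = [
            Reaction("R1", {"A": -1.0, "B": 1.0}, dG0=1.0),
            Reaction("R2", {"C": -1.0, "D": 1.0}, dG0=2.0),
        ]
        model = CompartModel(metabolites=mets, reactions=rxns)
        res = merge_reactions(model, MergeSpec("L", [("R1", 1), ("R2", 1)]))
        assert "pure lumping" in res.audit
        assert res.merged_reaction.dG0 == pytest.approx(3.0)

    def test_multipliers_weight_the_sum(self):
        mets = [_met("A"), _met("B"), _met("C")]
        rxns = [
            Reaction("R1", {"A": -1.0, "B": 2.0}, dG0=1.5),
            Reaction("R2", {"B": -1.0, "C": 1.0}, dG0=-4.0),
        ]
        model = CompartModel(metabolites=mets, reactions=rxns)
        res = merge_reactions(model, MergeSpec("M", [("R1", 1), ("R2", 2)]))
        assert res.merged_reaction.stoich == {"A": -1.0, "C": 2.0}
        assert res.merged_reaction.dG0 == pytest.approx(1.5 + 2 * -4.0)

    def test_reversible_part_rejected(self, trp_fragment):
        with pytest.raises(ValueError, match="direction-split"):
            merge_reactions(trp_fragment, MergeSpec("X", [("ARHGDx", 1), ("ACONTa", 1)]))


class TestDrivingForceAdditivity:
    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-12.0, -5.0), min_size=4, max_size=4),
           st.floats(-20.0, 20.0), st.floats(-20.0, 20.0))
    def test_additivity_at_any_concentration(self, logs, g1, g2):
        """The merged driving force equals the sum of partial driving
        forces at every concentration vector: the intermediate terms
        cancel algebraically."""
        mets = [_met(m) for m in ("A", "B", "C", "X")]
        rxns = [
            Reaction("R1", {"A": -1.0, "X": -1.0, "B": 1.0}, dG0=g1),
            Reaction("R2", {"B": -1.0, "C": 1.0, "X": 1.0}, dG0=g2),
        ]
        model = CompartModel(metabolites=mets, reactions=rxns)
        res = merge_reactions(model, MergeSpec("M", [("R1", 1), ("R2", 1)]))
        config = ThermoConfig()
        lc = dict(zip(("A", "B", "C", "X"), logs))
        f1 = driving_force(model.reaction("R1"), lc, config)
        f2 = driving_force(model.reaction("R2"), lc, config)
        fm = driving_force(res.merged_reaction, lc, config)
        assert fm == pytest.approx(f1 + f2, abs=1e-9)

    def test_three_partials_at_minus_0p632_sum_to_minus_1p897(self, gcfg):
        """Three sequential partials each running at a driving force of
        -0.632 kJ/mol merge into one overall reaction at -1.897 kJ/mol."""
        model, config = gen_linear_chain(gcfg, [0.632, 0.632, 0.632])
        lc = {m.id: math.log(1e-4) for m in model.internal_metabolites}
        partials = [model.reaction(f"R{i}") for i in (1, 2, 3)]
        for r in partials:
            assert driving_force(r, lc, config) == pytest.approx(-0.632)
        res = merge_reactions(model, MergeSpec("POFLX_like", [("R1", 1), ("R2", 1), ("R3", 1)]))
        fm = driving_force(res.merged_reaction, lc, config, model.boundary_ids())
        assert fm == pytest.approx(3 * -0.632, abs=1e-12)
        assert fm == pytest.approx(-1.897, abs=0.002)


class TestShut:
    def test_shut_forces_zero_flux(self, chain_distributed):
        model, config = chain_distributed
        out = shut_reactions(model, ["R2"])
        res = solve_fba(assemble_constraints(out, config), "EX_sink")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)
        # original untouched
        assert model.reaction("R2").status == "keep"

    def test_idempotent(self, chain_distributed):
        model, _ = chain_distributed
        once = shut_reactions(model, ["R1"])
        twice = shut_reactions(once, ["R1"])
        assert twice.reactions == once.reactions

    def test_unknown_id(self, chain_distributed):
        model, _ = chain_distributed
        with pytest.raises(KeyError, match="NOPE"):
            shut_reactions(model, ["NOPE"])


class TestRedundancy:
    def test_orphan_substrate_oxidase(self, trp_fragment):
        model = split_reversible(trp_fragment)
        flags = dict(find_redundant_reactions(model))
        assert flags.get("MTRPOXN") == "orphan-substrate: nmtrp_c"

    def test_isolated_stereoisomer_pair_both_directions(self, trp_fragment):
        model = split_reversible(trp_fragment)
        flags = dict(find_redundant_reactions(model))
        # r2hglut has no other producer/consumer: the forward direction
        # dead-ends and the reverse starves
        assert "ARHGDx" in flags
        assert "ARHGDx_reverse" in flags

    def test_connected_chain_clean(self, chain_distributed):
        model, _ = chain_distributed
        assert find_redundant_reactions(model) == []


class TestScenario:
    def _aerobic_toy(self):
        mets = [
            _met("S_ext", boundary=True), _met("O2_ext", boundary=True),
            _met("P_ext", boundary=True),
            _met("A"), _met("o2_c"), _met("P"),
        ]
        rxns = [
            Reaction("EX_glc", {"S_ext": -1.0, "A": 1.0}, flux_ub=10.0),
            Reaction("EX_o2", {"O2_ext": -1.0, "o2_c": 1.0}, flux_ub=20.0),
            Reaction("OX", {"A": -1.0, "o2_c": -1.0, "P": 1.0}),
            Reaction("EX_P", {"P": -1.0, "P_ext": 1.0}),
        ]
        return CompartModel(
            metabolites=mets, reactions=rxns,
            exchanges={"EX_glc", "EX_o2", "EX_P"},
        )

    def test_anaerobic_cuts_oxygen_dependent_product(self):
        model = self._aerobic_toy()
        anaer = apply_scenario(model, "anaerobic")
        res = solve_fba(assemble_constraints(anaer, ThermoConfig()), "EX_P")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_aerobic_restores_bounds(self):
        model = self._aerobic_toy()
        back = apply_scenario(apply_scenario(model, "anaerobic"), "aerobic")
        assert back.reaction("EX_o2").flux_ub == pytest.approx(20.0)
        res = solve_fba(assemble_constraints(back, ThermoConfig()), "EX_P")
        assert res.objective_value == pytest.approx(10.0)

    def test_fermentative_network_unaffected(self, chain_distributed):
        # an O2 exchange exists but the pathway never uses it
        model, config = chain_distributed
        model.metabolites.append(_met("o2_c"))
        model.metabolites.append(_met("O2_ext", boundary=True))
        model.reactions.append(Reaction("EX_o2", {"O2_ext": -1.0, "o2_c": 1.0}, flux_ub=20.0))
        model.exchanges.add("EX_o2")
        anaer = apply_scenario(model, "anaerobic")
        res = solve_fba(assemble_constraints(anaer, config), "EX_sink")
        assert res.objective_value == pytest.approx(10.0)

    def test_missing_oxygen_exchange_raises(self, chain_distributed):
        model, _ = chain_distributed
        with pytest.raises(KeyError, match="oxygen"):
            apply_scenario(model, "anaerobic")


class TestMergeHints:
    def test_shared_gene_pair_flagged(self, motif):
        model, _ = motif
        hints = shared_gene_merge_hints(model)
        assert ("U", "F", ["gUF"]) in hints


class TestMDFMonotonicityUnderMerging:
    @pytest.mark.parametrize("seed", range(12))
    def test_merging_active_adjacent_pair_never_lowers_mdf(self, seed):
        model, config = gen_random_model(GeneratorConfig(seed=seed, n_reactions=6))
        problem = assemble_constraints(model, config, thermo_on=True)
        pre = solve_max_mdf(problem, "EX_sink", 0.5)
        assert pre.optimal and pre.mdf >= 0.1 - config.mdf_tol
        rng = np.random.default_rng(seed)
        backbone = [r.id for r in model.reactions if r.id.startswith("R")]
        i = int(rng.integers(0, len(backbone) - 1))
        a, b = model.reaction(backbone[i]), model.reaction(backbone[i + 1])
        shared = set(a.products) & set(b.substrates)
        assert shared
        met = shared.pop()
        mult_a, mult_b = int(abs(b.stoich[met])), int(abs(a.stoich[met]))
        res = merge_reactions(
            model, MergeSpec("MERGED", [(a.id, mult_a), (b.id, mult_b)])
        )
        post = solve_max_mdf(
            assemble_constraints(res.new_model, config, thermo_on=True), "EX_sink", 0.5
        )
        assert post.optimal
        assert post.mdf >= pre.mdf - config.mdf_tol
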