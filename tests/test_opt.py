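import math

import numpy as np
import pytest

from mdflux.bruteforce import grid_max_min_driving_force
from mdflux.generate import GeneratorConfig, gen_linear_chain, gen_random_model
from mdflux.merge import shut_reactions
from mdflux.model import CompartModel, Metabolite, Reaction, ThermoConfig
from mdflux.opt import (
    ConfigurationError,
    assemble_constraints,
    driving_force,
    solve_fba,
    solve_max_flux_at_mdf,
    solve_max_mdf,
    solve_pfba,
)

RT = 2.579


class TestDrivingForce:
    def test_unit_concentrations_give_minus_dG0(self):
        # SerA-style combined reaction with dG0 = 2.1 kJ/mol
        r = Reaction("SerA", {"pg3_c": -3.0, "akg_c": -1.0, "php3_c": 3.0, "s2hglut_c": 1.0}, dG0=2.1)
        log_conc = {m: 0.0 for m in r.stoich}  # 1 M everywhere
        assert driving_force(r, log_conc, ThermoConfig()) == pytest.approx(-2.1)

    def test_thousandfold_substrate_raises_force_by_RT_ln1000(self):
        r = Reaction("R", {"co2_c": -1.0, "for_c": 1.0}, dG0=5.0)
        config = ThermoConfig()
        base = {"co2_c": math.log(1e-5), "for_c": math.log(1e-4)}
        up = dict(base, co2_c=math.log(1e-2))
        gain = driving_force(r, up, config) - driving_force(r, base, config)
        assert gain == pytest.approx(RT * math.log(1000), abs=1e-9)
        assert gain == pytest.approx(17.8, abs=0.05)

    def test_equal_concentrations(self):
        r = Reaction("R", {"A": -1.0, "B": 1.0}, dG0=-5.0)
        lc = {"A": math.log(1e-3), "B": math.log(1e-3)}
        assert driving_force(r, lc, ThermoConfig()) == pytest.approx(5.0)

    def test_boundary_metabolites_contribute_no_term(self):
        r = Reaction("R", {"A_ext": -1.0, "B": 1.0}, dG0=-5.0)
        lc = {"B": 0.0}
        f = driving_force(r, lc, ThermoConfig(), boundary={"A_ext"})
        assert f == pytest.approx(5.0)

    def test_errors(self):
        config = ThermoConfig()
        with pytest.raises(ValueError, match="exempt"):
            driving_force(Reaction("R", {"A": -1.0}), {"A": 0.0}, config)
        with pytest.raises(KeyError, match="B"):
            driving_force(Reaction("R", {"A": -1.0, "B": 1.0}, dG0=1.0), {"A": 0.0}, config)


class TestAssemble:
    def test_structure_counts_bare_chain(self):
        model = CompartModel(
            metabolites=[
                Metabolite("A", is_boundary=True),
                Metabolite("B", conc_lb=1e-6, conc_ub=1e-2),
                Metabolite("C", is_boundary=True),
            ],
            reactions=[
                Reaction("R1", {"A": -1.0, "B": 1.0}, dG0=-5.0),
                Reaction("R2", {"B": -1.0, "C": 1.0}, dG0=10.0),
            ],
        )
        problem = assemble_constraints(model, ThermoConfig(), thermo_on=True)
        assert problem.n_binaries() == 2
        asm = problem.assembly
        assert asm.n_m == 1  # one balanced internal metabolite
        assert asm.n_var == 2 + 1 + 2 + 1  # v, x, z, B

    def test_enzyme_cost_arithmetic(self):
        # v = 10 mmol/gDW/h at kcat/MW 3540 1/h/kDa -> 10/3540 g/gDW
        assert 10.0 / 3540.0 == pytest.approx(0.002825, abs=5e-6)

    def test_degenerate_ratio_forces_equal_concentrations(self, gcfg):
        model, config = gen_linear_chain(gcfg, [-5.0, 10.0])
        config.ratio_constraints = [("M0", "M2", 1.0, 1.0)]
        problem = assemble_constraints(model, config, thermo_on=True)
        res = solve_max_mdf(problem, "EX_sink", 1.0)
        assert res.optimal
        assert res.log_conc["M0"] == pytest.approx(res.log_conc["M2"], abs=1e-6)

    def test_bigM_audit(self, gcfg):
        model, config = gen_linear_chain(gcfg, [-5.0, 10.0])
        config.bigM = 10.0
        with pytest.raises(ConfigurationError, match="bigM"):
            assemble_constraints(model, config, thermo_on=True)


class TestFBA:
    def test_chain_conservation(self, chain_distributed):
        model, config = chain_distributed
        res = solve_fba(assemble_constraints(model, config), "EX_sink")
        assert res.optimal and res.objective_value == pytest.approx(10.0)

    def test_shut_internal_reaction_cuts_flux(self, chain_distributed):
        model, config = chain_distributed
        cut = shut_reactions(model, ["R1"])
        res = solve_fba(assemble_constraints(cut, config), "EX_sink")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_enzyme_bound_caps_flux(self):
        # 2 steps at kcat/MW 1000 -> cost 2v/1000 = E_total = 0.014 at v = 7
        gcfg = GeneratorConfig(E_total=0.014)
        model, config = gen_linear_chain(gcfg, [-5.0, -5.0])
        res = solve_fba(assemble_constraints(model, config, enzyme_on=True), "EX_sink")
        assert res.objective_value == pytest.approx(7.0, abs=1e-6)
        assert sum(res.enzyme_costs.values()) <= model.total_enzyme_bound + 1e-9


class TestPFBA:
    def _parallel(self, short_extra=0):
        mets = [
            Metabolite("S_ext", is_boundary=True),
            Metabolite("A"), Metabolite("X"), Metabolite("B"),
            Metabolite("P_ext", is_boundary=True),
        ]
        rxns = [
            Reaction("EX_up", {"S_ext": -1.0, "A": 1.0}, flux_ub=10.0),
            Reaction("SHORT", {"A": -1.0, "B": 1.0}),
            Reaction("LONG1", {"A": -1.0, "X": 1.0}),
            Reaction("LONG2", {"X": -1.0, "B": 1.0}),
            Reaction("EX_sink", {"B": -1.0, "P_ext": 1.0}),
        ]
        return CompartModel(metabolites=mets, reactions=rxns,
                            exchanges={"EX_up", "EX_sink"})

    def test_prefers_short_route(self):
        model = self._parallel()
        res = solve_pfba(assemble_constraints(model, ThermoConfig()), "EX_sink")
        assert res.fluxes["SHORT"] == pytest.approx(10.0)
        assert res.fluxes["LONG1"] == pytest.approx(0.0, abs=1e-9)

    def test_single_path_equals_fba(self, chain_distributed):
        model, config = chain_distributed
        problem = assemble_constraints(model, config)
        fba = solve_fba(problem, "EX_sink")
        pfba = solve_pfba(problem, "EX_sink")
        assert pfba.objective_value == pytest.approx(fba.objective_value)
        for rid, v in fba.fluxes.items():
            assert pfba.fluxes[rid] == pytest.approx(v, abs=1e-6)

    def test_diamond_matches_vertex_enumeration(self):
        """Total-flux minimum over the diamond equals the best vertex
        (all flux on one route) from brute-force enumeration."""
        model = self._parallel()
        res = solve_pfba(assemble_constraints(model, ThermoConfig()), "EX_sink")
        # enumerate flux splits v_short in {0..10}: total internal flux
        # is 10 + v_short + 2*(10 - v_short) + 10, minimised at v_short=10
        totals = {v: 20.0 + v + 2 * (10.0 - v) for v in np.linspace(0, 10, 11)}
        best = min(totals, key=totals.get)
        assert res.fluxes["SHORT"] == pytest.approx(best)
        got_total = sum(res.fluxes.values())
        # within the pFBA objective-fixing slack
        assert got_total == pytest.approx(totals[best], abs=1e-5)


class TestMaxMDF:
    def test_distributed_chain_matches_grid_oracle(self, chain_distributed):
        model, config = chain_distributed
        res = solve_max_mdf(assemble_constraints(model, config, thermo_on=True), "EX_sink", 1.0)
        assert res.optimal
        B_oracle, _ = grid_max_min_driving_force(model, config, ["R1", "R2"], 200)
        assert res.mdf == pytest.approx(9.377, abs=0.005)
        assert res.mdf == pytest.approx(B_oracle, abs=0.05)

    def test_localized_chain_analytic(self, chain_localized):
        model, config = chain_localized
        res = solve_max_mdf(assemble_constraints(model, config, thermo_on=True), "EX_sink", 1.0)
        # pinned by R2 alone: -30 + RT ln(1e4)
        assert res.mdf == pytest.approx(-30.0 + RT * math.log(1e4), abs=1e-6)
        assert res.mdf == pytest.approx(-6.25, abs=0.05)

    def test_zero_demand_picks_best_single_reaction(self, chain_distributed):
        model, config = chain_distributed
        res = solve_max_mdf(assemble_constraints(model, config, thermo_on=True), "EX_sink", 0.0)
        # with all indicators free, B is the best single driving force:
        # R1 at max substrate / min product: 5 + RT ln(1e4)
        assert res.mdf == pytest.approx(5.0 + RT * math.log(1e4), abs=1e-6)

    def test_demand_beyond_capacity_infeasible(self, chain_distributed):
        model, config = chain_distributed
        res = solve_max_mdf(assemble_constraints(model, config, thermo_on=True), "EX_sink", 11.0)
        assert res.status == "infeasible"

    def test_active_reactions_reach_B(self, chain_distributed):
        model, config = chain_distributed
        res = solve_max_mdf(assemble_constraints(model, config, thermo_on=True), "EX_sink", 1.0)
        boundary = model.boundary_ids()
        for r in model.reactions:
            if r.dG0 is None or not res.active[r.id]:
                continue
            f = driving_force(r, res.log_conc, config, boundary)
            assert f >= res.mdf - config.mdf_tol


class TestMaxFluxAtMDF:
    def test_vacuous_bound_recovers_fba(self, chain_distributed):
        model, config = chain_distributed
        problem = assemble_constraints(model, config, thermo_on=True)
        res = solve_max_flux_at_mdf(problem, "EX_sink", -config.bigM)
        assert res.objective_value == pytest.approx(10.0)

    def test_at_exact_optimum_reaches_uptake_bound(self, chain_distributed):
        model, config = chain_distributed
        problem = assemble_constraints(model, config, thermo_on=True)
        B = solve_max_mdf(problem, "EX_sink", 1.0).mdf
        res = solve_max_flux_at_mdf(problem, "EX_sink", B - 1e-7)
        assert res.objective_value == pytest.approx(10.0)

    def test_above_optimum_infeasible(self, chain_distributed):
        model, config = chain_distributed
        problem = assemble_constraints(model, config, thermo_on=True)
        B = solve_max_mdf(problem, "EX_sink", 0.0).mdf  # global max over the curve
        res = solve_max_flux_at_mdf(problem, "EX_sink", B + 1.0)
        assert res.status == "infeasible" or res.objective_value <= 1e-9


def test_lp_export_lists_all_variables(tmp_path, chain_distributed):
    from mdflux.opt import write_lp

    model, config = chain_distributed
    problem = assemble_constraints(model, config, thermo_on=True)
    path = tmp_path / "chain.lp"
    write_lp(problem, path, "EX_sink")
    text = path.read_text()
    assert "Binaries" in text and "z_R1" in text and "z_R2" in text
    assert "lnc_M1" in text and " B" in text
    assert text.strip().endswith("End")


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_monotonicity_and_duality(self, seed):
        model, config = gen_random_model(GeneratorConfig(seed=seed, n_reactions=6))
        problem = assemble_constraints(model, config, thermo_on=True)
        prev = None
        for f in (0.5, 2.0, 5.0):
            res = solve_max_mdf(problem, "EX_sink", f)
            if not res.optimal:
                break
            if prev is not None:
                assert res.mdf <= prev + config.mdf_tol
            prev = res.mdf
        # duality of steps 1-2 at the first demand level
        B = solve_max_mdf(problem, "EX_sink", 0.5).mdf
        vmax = solve_max_flux_at_mdf(problem, "EX_sink", B - 1e-7).objective_value
        B2 = solve_max_mdf(problem, "EX_sink", vmax - 1e-6).mdf
        assert B2 == pytest.approx(B, abs=config.mdf_tol + 1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_mass_balance_residual(self, seed):
        model, config = gen_random_model(GeneratorConfig(seed=seed, n_reactions=7))
        problem = assemble_constraints(model, config, enzyme_on=True, thermo_on=True)
        res = solve_max_mdf(problem, "EX_sink", 1.0)
        assert res.optimal
        S, _, rxn_ids = model.stoichiometric_matrix()
        v = np.array([res.fluxes[r] for r in rxn_ids])
        assert np.abs(S @ v).max() <= 1e-6
        assert sum(res.enzyme_costs.values()) <= model.total_enzyme_bound + 1e-9
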