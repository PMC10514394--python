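"""Seeded toy-network generators.

Every generator returns ``(CompartModel, ThermoConfig)`` with the
thermodynamic/enzymatic structure the pathway analysis assumes: linear
chains with assigned dG0, a coupled-enzyme motif (one unfavorable and one
favorable reaction sharing a gene and a redox cofactor pair whose
concentration ratio is constrained), a two-route branched network whose
MDF staircase has at least two stages, and random feasible-by-construction
networks for property testing.  Identical configurations produce
bit-identical models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import CompartModel, Metabolite, Reaction, ThermoConfig

__all__ = [
    "GeneratorConfig",
    "gen_linear_chain",
    "gen_coupled_motif",
    "gen_branched_network",
    "gen_random_model",
]


@dataclass
class GeneratorConfig:
    """Knobs shared by the generators.

    ``conc_bounds`` are applied uniformly to internal metabolites (mol/L);
    ``uptake_ub`` caps the source exchange (mmol/gDW/h); ``E_total`` is
    the proteome budget (g/gDW).  ``efficiency_range`` (h^-1/kDa)
    brackets typical kcat/MW magnitudes of central-metabolic enzymes.
    """

    seed: int = 0
    n_reactions: int = 6
    dG0_range: tuple = (-30.0, 30.0)
    efficiency_range: tuple = (100.0, 4000.0)
    conc_bounds: tuple = (1e-6, 1e-2)
    uptake_ub: float = 10.0
    E_total: float = 0.13
    default_efficiency: float = 1000.0


def _thermo_config(gcfg: GeneratorConfig, ratio_constraints=()) -> ThermoConfig:
    return ThermoConfig(
        default_conc_lb=gcfg.conc_bounds[0],
        default_conc_ub=gcfg.conc_bounds[1],
        special_bounds={},
        ratio_constraints=list(ratio_constraints),
    )


def _met(mid, gcfg, boundary=False):
    return Metabolite(
        id=mid,
        conc_lb=gcfg.conc_bounds[0],
        conc_ub=gcfg.conc_bounds[1],
        is_boundary=boundary,
    )


def gen_linear_chain(gcfg: GeneratorConfig, dG0_list) -> tuple:
    """Source exchange -> M0 -> M1 -> ... -> sink, one reaction per dG0.

    The uptake and sink exchanges involve boundary metabolites and carry
    no dG0 (thermodynamically exempt); internal steps get the listed dG0
    values and the default efficiency.
    """
    if len(dG0_list) < 1:
        raise ValueError("dG0_list must contain at least one value")
    n = len(dG0_list)
    mets = [_met("SRC_ext", gcfg, boundary=True)]
    mets += [_met(f"M{i}", gcfg) for i in range(n + 1)]
    mets.append(_met("PROD_ext", gcfg, boundary=True))
    rxns = [
        Reaction(
            id="EX_uptake",
            stoich={"SRC_ext": -1.0, "M0": 1.0},
            flux_ub=gcfg.uptake_ub,
        )
    ]
    for i, g in enumerate(dG0_list):
        rxns.append(
            Reaction(
                id=f"R{i + 1}",
                stoich={f"M{i}": -1.0, f"M{i + 1}": 1.0},
                dG0=float(g),
                efficiency=gcfg.default_efficiency,
                genes=frozenset({f"g{i + 1}"}),
            )
        )
    rxns.append(
        Reaction(id="EX_sink", stoich={f"M{n}": -1.0, "PROD_ext": 1.0})
    )
    model = CompartModel(
        metabolites=mets,
        reactions=rxns,
        exchanges={"EX_uptake", "EX_sink"},
        total_enzyme_bound=gcfg.E_total,
        provenance=f"gen_linear_chain(dG0={list(dG0_list)})",
    )
    return model, _thermo_config(gcfg)


def gen_coupled_motif(
    gcfg: GeneratorConfig,
    dG0_unfavorable: float = 30.0,
    dG0_favorable: float = -34.0,
    dG0_reference: float = 18.0,
    ratio_bounds: tuple = (0.5, 2.0),
) -> tuple:
    """Two reactions catalysed by one enzyme, coupled through a cofactor.

    Reaction U (unfavorable, dG0 > 0) reduces cofactor X_ox -> X_red while
    converting A -> B; reaction F (favorable, dG0 < 0) re-oxidises the
    cofactor while converting B -> C.  Both carry the same gene, and the
    X_red/X_ox concentration ratio is constrained to ``ratio_bounds``
    (a narrow physiological redox window).  An independent parallel
    branch D -> E (reaction V) joins C at the product step and pins the
    network MDF once the cofactor ratio no longer limits U, so that
    merging U+F (which cancels the cofactor pair and B) raises the
    achievable MDF up to V's ceiling and no further.
    """
    mets = [
        _met("A_ext", gcfg, boundary=True),
        _met("D_ext", gcfg, boundary=True),
        _met("P_ext", gcfg, boundary=True),
        _met("A", gcfg),
        _met("B", gcfg),
        _met("C", gcfg),
        _met("D", gcfg),
        _met("E", gcfg),
        _met("X_red", gcfg),
        _met("X_ox", gcfg),
        _met("P", gcfg),
    ]
    eff = gcfg.default_efficiency
    rxns = [
        Reaction(id="EX_A", stoich={"A_ext": -1.0, "A": 1.0}, flux_ub=gcfg.uptake_ub),
        Reaction(id="EX_D", stoich={"D_ext": -1.0, "D": 1.0}, flux_ub=gcfg.uptake_ub),
        Reaction(
            id="U",
            stoich={"A": -1.0, "X_ox": -1.0, "B": 1.0, "X_red": 1.0},
            dG0=dG0_unfavorable,
            efficiency=eff,
            genes=frozenset({"gUF"}),
        ),
        Reaction(
            id="F",
            stoich={"B": -1.0, "X_red": -1.0, "C": 1.0, "X_ox": 1.0},
            dG0=dG0_favorable,
            efficiency=eff,
            genes=frozenset({"gUF"}),
        ),
        Reaction(
            id="V",
            stoich={"D": -1.0, "E": 1.0},
            dG0=dG0_reference,
            efficiency=eff,
            genes=frozenset({"gV"}),
        ),
        Reaction(
            id="PROD",
            stoich={"C": -1.0, "E": -1.0, "P": 1.0},
            efficiency=eff,
            genes=frozenset({"gP"}),
        ),
        Reaction(id="EX_P", stoich={"P": -1.0, "P_ext": 1.0}),
    ]
    model = CompartModel(
        metabolites=mets,
        reactions=rxns,
        exchanges={"EX_A", "EX_D", "EX_P"},
        total_enzyme_bound=gcfg.E_total,
        provenance="gen_coupled_motif",
    )
    config = _thermo_config(
        gcfg, ratio_constraints=[("X_red", "X_ox", ratio_bounds[0], ratio_bounds[1])]
    )
    return model, config


def gen_branched_network(
    gcfg: GeneratorConfig,
    capacity_a: float = 3.0,
    dG0_a: float = -10.0,
    dG0_b: tuple = (5.0, 5.0),
) -> tuple:
    """Two routes from source to product sharing the endpoints.

    Route A: one favorable step with a small flux capacity (high MDF, low
    yield).  Route B: two unfavorable steps with no extra cap (low MDF,
    high yield).  The MDF staircase therefore drops at route A's capacity.
    """
    mets = [
        _met("SRC_ext", gcfg, boundary=True),
        _met("PROD_ext", gcfg, boundary=True),
        _met("M0", gcfg),
        _met("N", gcfg),
        _met("MP", gcfg),
    ]
    eff = gcfg.default_efficiency
    rxns = [
        Reaction(id="EX_uptake", stoich={"SRC_ext": -1.0, "M0": 1.0}, flux_ub=gcfg.uptake_ub),
        Reaction(
            id="RA",
            stoich={"M0": -1.0, "MP": 1.0},
            dG0=dG0_a,
            flux_ub=capacity_a,
            efficiency=eff,
            genes=frozenset({"gA"}),
        ),
        Reaction(
            id="RB1",
            stoich={"M0": -1.0, "N": 1.0},
            dG0=dG0_b[0],
            efficiency=eff,
            genes=frozenset({"gB1"}),
        ),
        Reaction(
            id="RB2",
            stoich={"N": -1.0, "MP": 1.0},
            dG0=dG0_b[1],
            efficiency=eff,
            genes=frozenset({"gB2"}),
        ),
        Reaction(id="EX_sink", stoich={"MP": -1.0, "PROD_ext": 1.0}),
    ]
    model = CompartModel(
        metabolites=mets,
        reactions=rxns,
        exchanges={"EX_uptake", "EX_sink"},
        total_enzyme_bound=gcfg.E_total,
        provenance="gen_branched_network",
    )
    return model, _thermo_config(gcfg)


def gen_random_model(gcfg: GeneratorConfig) -> tuple:
    """Random backbone chain with dead-end side branches, feasible by
    construction.

    A log-concentration vector is sampled inside the bounds first; each
    backbone dG0 is then drawn so that the sampled vector gives that
    reaction a driving force of at least 0.1 kJ/mol, which guarantees a
    pre-merge MDF >= 0.1.  Backbone stoichiometric coefficients are
    occasionally 2 to exercise integer merge multipliers.  Side branches
    hang off backbone metabolites and dead-end (they can never carry
    flux), adding structural variety without touching the feasibility
    guarantee.  Fully deterministic given the config.
    """
    if gcfg.n_reactions < 2:
        raise ValueError("n_reactions must be >= 2")
    rng = np.random.default_rng(gcfg.seed)
    n_backbone = max(2, gcfg.n_reactions - gcfg.n_reactions // 4)
    n_side = gcfg.n_reactions - n_backbone

    lo, hi = gcfg.conc_bounds
    mets = [_met("SRC_ext", gcfg, boundary=True)]
    mets += [_met(f"M{i}", gcfg) for i in range(n_backbone + 1)]
    mets.append(_met("PROD_ext", gcfg, boundary=True))
    # sampled interior concentration vector (log-uniform, away from bounds)
    x_star = {
        f"M{i}": rng.uniform(math.log(lo) * 0.9 + math.log(hi) * 0.1,
                             math.log(lo) * 0.1 + math.log(hi) * 0.9)
        for i in range(n_backbone + 1)
    }

    RT = 2.579
    rxns = [
        Reaction(id="EX_uptake", stoich={"SRC_ext": -1.0, "M0": 1.0}, flux_ub=gcfg.uptake_ub)
    ]
    for i in range(n_backbone):
        coef_in = 2.0 if rng.random() < 0.15 else 1.0
        coef_out = 2.0 if rng.random() < 0.15 else 1.0
        stoich = {f"M{i}": -coef_in, f"M{i + 1}": coef_out}
        target_f = rng.uniform(0.1, 5.0)
        sum_sx = -coef_in * x_star[f"M{i}"] + coef_out * x_star[f"M{i + 1}"]
        dG0 = -target_f - RT * sum_sx
        rxns.append(
            Reaction(
                id=f"R{i + 1}",
                stoich=stoich,
                dG0=float(dG0),
                efficiency=float(rng.uniform(*gcfg.efficiency_range)),
                genes=frozenset({f"g{i + 1}"}),
            )
        )
    for k in range(n_side):
        attach = int(rng.integers(0, n_backbone + 1))
        side_id = f"S{k}"
        mets.append(_met(side_id, gcfg))
        rxns.append(
            Reaction(
                id=f"SIDE{k}",
                stoich={f"M{attach}": -1.0, side_id: 1.0},
                dG0=float(rng.uniform(*gcfg.dG0_range)),
                efficiency=float(rng.uniform(*gcfg.efficiency_range)),
                genes=frozenset({f"gs{k}"}),
            )
        )
    rxns.append(Reaction(id="EX_sink", stoich={f"M{n_backbone}": -1.0, "PROD_ext": 1.0}))
    model = CompartModel(
        metabolites=mets,
        reactions=rxns,
        exchanges={"EX_uptake", "EX_sink"},
        total_enzyme_bound=gcfg.E_total,
        provenance=f"gen_random_model(seed={gcfg.seed}, n={gcfg.n_reactions})",
    )
    return model, _thermo_config(gcfg)
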