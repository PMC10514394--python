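"""Bottleneck reactions, limiting metabolites and key enzymes.

The bottleneck procedure runs five steps in order: (1) maximise the
pathway MDF B* at a required product flux; (2) maximise the product flux
with B >= B*; (3) solve the parsimonious flux distribution at that flux
and MDF; (4) with the fluxes fixed to the pFBA witness, maximise each
active reaction's driving force individually while all active reactions
keep f >= B*; (5) reactions whose individual maximum equals B* (within
tolerance) are the bottlenecks.  A single bottleneck is *localized*;
several are *distributed* and are coupled through shared limiting
metabolites.

A *limiting metabolite* shows no concentration variability at the MDF
optimum — either pinned at a concentration bound, or balanced because it
appears with opposite signs in different bottleneck reactions.

*Key enzymes* are found by enzyme-cost variability: with the product
flux and MDF held, a reaction whose cost e_i = v_i / (kcat/MW) has no
room to move while the proteome budget is binding marks an enzyme whose
amount the cell cannot trade away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import CompartModel, ThermoConfig, ln_bounds
from .opt import (
    SolveResult,
    assemble_constraints,
    solve_max_flux_at_mdf,
    solve_max_mdf,
    solve_pfba,
)

__all__ = [
    "BottleneckReport",
    "LimitingMetabolite",
    "EnzymeCostRecord",
    "reaction_max_driving_forces",
    "identify_bottlenecks",
    "concentration_variability",
    "identify_limiting_metabolites",
    "enzyme_cost_variability",
]

_EPS = 1e-7  # slack when re-imposing an optimum as a constraint


@dataclass
class BottleneckReport:
    product: str
    min_flux: float
    mdf: float
    max_flux_at_mdf: float
    per_reaction_max_df: dict = field(default_factory=dict)
    bottlenecks: set = field(default_factory=set)
    classification: str = ""
    shared_limiting_mets: dict = field(default_factory=dict)
    limiting_metabolites: list = field(default_factory=list)
    flux_fixture: SolveResult | None = None


@dataclass
class LimitingMetabolite:
    id: str
    conc_min: float
    conc_max: float
    reason: str  # at_lower_bound | at_upper_bound | balanced


@dataclass
class EnzymeCostRecord:
    id: str
    cost_min: float
    cost_max: float
    is_key: bool


class _ConcentrationLP:
    """LP over log-concentrations with all active reactions held at
    driving force >= B*; shared by steps 4-5 and the variability scans."""

    def __init__(self, model: CompartModel, config: ThermoConfig, active_ids, B_lb):
        self.model = model
        self.config = config
        self.boundary = model.boundary_ids()
        self.mets = model.internal_metabolites
        self.index = {m.id: i for i, m in enumerate(self.mets)}
        n = len(self.mets)
        lo = np.empty(n)
        hi = np.empty(n)
        for i, m in enumerate(self.mets):
            lo[i], hi[i] = ln_bounds(m)
        self.bounds = Bounds(lo, hi)
        rows, rlo, rhi = [], [], []
        self.active = [model.reaction(rid) for rid in active_ids]
        for r in self.active:
            rows.append(self._df_row(r))
            rlo.append(-np.inf)
            rhi.append(-r.dG0 - B_lb)  # RT*sum(s x) <= -dG0 - B
        for met_a, met_b, ratio_lb, ratio_ub in config.ratio_constraints:
            if met_a in self.index and met_b in self.index:
                row = np.zeros(n)
                row[self.index[met_a]] = 1.0
                row[self.index[met_b]] = -1.0
                rows.append(row)
                rlo.append(math.log(ratio_lb))
                rhi.append(math.log(ratio_ub))
        self.A = np.array(rows) if rows else np.zeros((0, n))
        self.rlo = np.array(rlo)
        self.rhi = np.array(rhi)

    def _df_row(self, r) -> np.ndarray:
        row = np.zeros(len(self.mets))
        for met, coef in r.stoich.items():
            if met in self.boundary:
                continue
            row[self.index[met]] += self.config.RT * coef
        return row

    def optimize(self, c, maximize=False) -> tuple[float, np.ndarray]:
        keep_hi = np.isfinite(self.rhi)
        keep_lo = np.isfinite(self.rlo)
        res = linprog(
            -c if maximize else c,
            A_ub=np.vstack([self.A[keep_hi], -self.A[keep_lo]]),
            b_ub=np.concatenate([self.rhi[keep_hi], -self.rlo[keep_lo]]),
            bounds=list(zip(self.bounds.lb, self.bounds.ub)),
            method="highs",
        )
        if res.status != 0:
            raise RuntimeError(
                f"concentration LP not optimal (status {res.status}): {res.message}"
            )
        return (-res.fun if maximize else res.fun), res.x

    def max_driving_force(self, rxn_id: str) -> float:
        r = self.model.reaction(rxn_id)
        val, _ = self.optimize(self._df_row(r), maximize=False)
        return -r.dG0 - val

    def conc_range(self, met_id: str) -> tuple[float, float]:
        c = np.zeros(len(self.mets))
        c[self.index[met_id]] = 1.0
        lo, _ = self.optimize(c, maximize=False)
        hi, _ = self.optimize(c, maximize=True)
        return math.exp(lo), math.exp(hi)


def _active_thermo_ids(model: CompartModel, fixture: SolveResult, tol: float):
    out = []
    for r in model.reactions:
        if r.dG0 is None or r.id in model.exchanges:
            continue
        if abs(fixture.fluxes.get(r.id, 0.0)) > tol:
            out.append(r.id)
    return out


def reaction_max_driving_forces(
    model: CompartModel,
    config: ThermoConfig,
    product: str,
    min_flux: float,
    B_star: float,
    flux_fixture: SolveResult,
) -> dict:
    """Step 4: per-reaction maximum driving force at fixed fluxes.

    For each reaction active in the fixture, maximise its driving force
    over log-concentrations subject to every active reaction keeping
    f >= B*.  Reactions outside the active pathway are absent from the
    returned map.
    """
    active = _active_thermo_ids(model, flux_fixture, config.flux_tol)
    lp = _ConcentrationLP(model, config, active, B_star - _EPS)
    return {rid: lp.max_driving_force(rid) for rid in active}


def concentration_variability(
    model: CompartModel,
    config: ThermoConfig,
    product: str,
    min_flux: float,
    B_star: float,
    flux_fixture: SolveResult,
    metabolites,
) -> dict:
    """Concentration range of each listed metabolite at the MDF optimum
    (all active reactions held at f >= B*, fluxes fixed to the fixture)."""
    active = _active_thermo_ids(model, flux_fixture, config.flux_tol)
    lp = _ConcentrationLP(model, config, active, B_star - _EPS)
    boundary = model.boundary_ids()
    out = {}
    for mid in metabolites:
        if mid in boundary:
            continue
        out[mid] = lp.conc_range(mid)
    return out


def identify_limiting_metabolites(
    model: CompartModel,
    config: ThermoConfig,
    bottlenecks,
    conc_ranges: dict,
) -> list:
    """Metabolites with no concentration variability, with the reason.

    A metabolite is limiting when conc_max/conc_min <= 1 + var_tol.  The
    reason is the bound it sits on when within var_tol of a concentration
    bound (the bound reason wins even if the metabolite is also
    balanced); otherwise it is balanced between bottleneck reactions in
    which it appears with opposite signs.
    """
    out = []
    for mid, (cmin, cmax) in conc_ranges.items():
        if cmax / cmin > 1.0 + config.var_tol:
            continue
        met = model.metabolite(mid)
        if cmin <= met.conc_lb * (1.0 + config.var_tol):
            reason = "at_lower_bound"
        elif cmax >= met.conc_ub / (1.0 + config.var_tol):
            reason = "at_upper_bound"
        else:
            # pinned away from both bounds: balanced between bottleneck
            # reactions using it with opposite signs
            reason = "balanced"
        out.append(LimitingMetabolite(id=mid, conc_min=cmin, conc_max=cmax, reason=reason))
    return out


def identify_bottlenecks(
    model: CompartModel,
    config: ThermoConfig,
    product: str,
    min_flux: float,
    enzyme_on: bool = False,
) -> BottleneckReport:
    """Run the full five-step bottleneck procedure at one demand level."""
    problem = assemble_constraints(model, config, enzyme_on=enzyme_on, thermo_on=True)
    step1 = solve_max_mdf(problem, product, min_flux)
    if not step1.optimal:
        raise ValueError(
            f"product flux {min_flux} for {product!r} is infeasible ({step1.status})"
        )
    B_star = step1.mdf
    step2 = solve_max_flux_at_mdf(problem, product, B_star - _EPS)
    vmax = step2.objective_value
    fixture = solve_pfba(problem, product, mdf_lb=B_star - _EPS)
    if not fixture.optimal:
        raise ValueError("pFBA at the MDF optimum is infeasible")

    max_df = reaction_max_driving_forces(model, config, product, vmax, B_star, fixture)
    bottlenecks = {
        rid for rid, f in max_df.items() if f <= B_star + config.mdf_tol
    }
    classification = "localized" if len(bottlenecks) == 1 else "distributed"

    touched = sorted({
        m for rid in bottlenecks for m in model.reaction(rid).stoich
        if m not in model.boundary_ids()
    })
    conc_ranges = concentration_variability(
        model, config, product, vmax, B_star, fixture, touched
    )
    limiting = identify_limiting_metabolites(model, config, bottlenecks, conc_ranges)
    shared = {}
    for lm in limiting:
        rxns = {
            rid for rid in bottlenecks if lm.id in model.reaction(rid).stoich
        }
        shared[lm.id] = rxns
    return BottleneckReport(
        product=product,
        min_flux=min_flux,
        mdf=B_star,
        max_flux_at_mdf=vmax,
        per_reaction_max_df=max_df,
        bottlenecks=bottlenecks,
        classification=classification if bottlenecks else "",
        shared_limiting_mets=shared,
        limiting_metabolites=limiting,
        flux_fixture=fixture,
    )


def enzyme_cost_variability(
    model: CompartModel,
    config: ThermoConfig,
    product: str,
    min_flux: float,
    B_star: float,
) -> list:
    """Enzyme-cost range per reaction at fixed product flux and MDF.

    Fluxes are otherwise free.  ``is_key`` marks reactions whose cost
    range is below ``key_tol`` while the proteome budget is binding
    (minimum total cost within ``bind_tol`` of E_total).
    """
    problem = assemble_constraints(model, config, enzyme_on=True, thermo_on=True)
    asm = problem.assembly
    with_eff = [
        r for r in model.reactions
        if r.efficiency is not None and r.id not in model.exchanges and r.status != "shut"
    ]
    if not with_eff:
        raise ValueError("no reaction carries an enzyme efficiency parameter")
    j = problem.rxn_var(product)
    lb = asm.lb.copy()
    lb[asm.off_B] = max(lb[asm.off_B], B_star - _EPS)
    extra = [({j: 1.0}, min_flux - _EPS, np.inf)]

    # is the proteome budget binding anywhere in the fixed-flux/MDF slice?
    c_total = np.zeros(asm.n_var)
    for r in with_eff:
        c_total[problem.rxn_var(r.id)] = 1.0 / r.efficiency
    res = asm.solve_raw(c_total, maximize=False, extra_rows=extra, lb_over=lb)
    if res.status != 0:
        raise ValueError("enzyme-cost problem infeasible at the given flux and MDF")
    binding = float(res.fun) >= model.total_enzyme_bound - config.bind_tol

    records = []
    for r in with_eff:
        c = np.zeros(asm.n_var)
        c[problem.rxn_var(r.id)] = 1.0
        lo = asm.solve_raw(c, maximize=False, extra_rows=extra, lb_over=lb)
        hi = asm.solve_raw(c, maximize=True, extra_rows=extra, lb_over=lb)
        if lo.status != 0 or hi.status != 0:
            raise ValueError(f"enzyme-cost variability infeasible for {r.id}")
        cost_min = float(lo.x[problem.rxn_var(r.id)]) / r.efficiency
        cost_max = float(hi.x[problem.rxn_var(r.id)]) / r.efficiency
        is_key = binding and (cost_max - cost_min) <= config.key_tol
        records.append(
            EnzymeCostRecord(id=r.id, cost_min=cost_min, cost_max=cost_max, is_key=is_key)
        )
    return records
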