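"""Stoichiometric / enzymatic / thermodynamic optimization problems.

The central quantity is the *driving force* of a reaction at a
concentration vector,

    f_i = -(dG0_i + RT * sum_j s_ij * ln c_j),

and the pathway-level *max-min driving force* (MDF): the largest B such
that concentrations within bounds give every active reaction f_i >= B.
Activity is encoded with binary indicators z_i coupled to fluxes by
``v_i <= ub_i * z_i`` and to driving forces by the big-M relaxation
``f_i >= B - M * (1 - z_i)``, so inactive reactions impose no
thermodynamic constraint.  This mixed-integer formulation is solved with
HiGHS through :func:`scipy.optimize.milp`.

Four solve modes are provided: plain FBA, parsimonious FBA (lexicographic
two-stage: fix the objective optimum, then minimise total flux),
max-MDF at a required product flux, and max product flux at a required
MDF.  All modes share one constraint assembly
(:func:`assemble_constraints`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import CompartModel, Reaction, ThermoConfig, ln_bounds

__all__ = [
    "OptProblem",
    "SolveResult",
    "driving_force",
    "assemble_constraints",
    "solve_fba",
    "solve_pfba",
    "solve_max_mdf",
    "solve_max_flux_at_mdf",
    "flux_variability",
    "ConfigurationError",
]

# slack used when re-imposing an optimal value as a constraint, to absorb
# solver round-off without affecting reported quantities
_REFIX_EPS = 1e-7


class ConfigurationError(ValueError):
    """Raised when the problem setup is numerically unsound (e.g. big-M
    smaller than an attainable driving-force magnitude)."""


def driving_force(
    reaction: Reaction,
    log_conc: dict,
    config: ThermoConfig,
    boundary: frozenset | set = frozenset(),
) -> float:
    """Driving force f = -(dG0 + RT * sum_j s_ij ln c_j) in kJ/mol.

    ``log_conc`` maps metabolite id to ln(concentration in mol/L).
    Boundary metabolites contribute no term.  Raises if the reaction has
    no dG0 (thermodynamically exempt) or a concentration is missing.
    """
    if reaction.dG0 is None:
        raise ValueError(f"reaction {reaction.id} is thermodynamically exempt (no dG0)")
    total = reaction.dG0
    for met, coef in reaction.stoich.items():
        if met in boundary:
            continue
        if met not in log_conc:
            raise KeyError(f"missing log-concentration for metabolite {met!r}")
        total += config.RT * coef * log_conc[met]
    return -total


@dataclass
class SolveResult:
    """Outcome of one optimization.

    ``fluxes`` are in mmol/gDW/h, ``log_conc`` in ln(mol/L), ``mdf`` (B)
    in kJ/mol, ``enzyme_costs`` (flux / efficiency) in g enzyme/gDW and
    ``active`` flags reactions with flux above the activity tolerance.
    """

    status: str
    objective_value: float | None = None
    fluxes: dict = field(default_factory=dict)
    log_conc: dict = field(default_factory=dict)
    mdf: float | None = None
    active: dict = field(default_factory=dict)
    enzyme_costs: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class _Assembly:
    """Variable layout and base constraint rows for one model/config."""

    def __init__(self, model: CompartModel, config: ThermoConfig,
                 enzyme_on: bool, thermo_on: bool):
        self.model = model
        self.config = config
        self.enzyme_on = enzyme_on
        self.thermo_on = thermo_on

        self.reactions = model.reactions
        self.rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        self.mets = model.internal_metabolites
        self.met_index = {m.id: i for i, m in enumerate(self.mets)}
        self.boundary = model.boundary_ids()
        self.n_r = len(self.reactions)
        self.n_m = len(self.mets) if thermo_on else 0

        self.thermo_rxns = []
        if thermo_on:
            for j, r in enumerate(self.reactions):
                if r.dG0 is not None and r.id not in model.exchanges:
                    self.thermo_rxns.append(j)
        self.z_index = {j: k for k, j in enumerate(self.thermo_rxns)}
        self.n_z = len(self.thermo_rxns)

        # variable layout: [v | x | z | B]
        self.off_x = self.n_r
        self.off_z = self.off_x + self.n_m
        self.off_B = self.off_z + self.n_z
        self.n_var = self.n_r + self.n_m + self.n_z + (1 if thermo_on else 0)

        self._build_bounds()
        self._audit_bigM()
        self._build_rows()

    # -- construction ----------------------------------------------------
    def _build_bounds(self):
        lb = np.zeros(self.n_var)
        ub = np.zeros(self.n_var)
        for j, r in enumerate(self.reactions):
            lo, hi = r.effective_bounds
            lb[j], ub[j] = lo, hi
        for m in self.mets if self.thermo_on else []:
            i = self.off_x + self.met_index[m.id]
            lb[i], ub[i] = ln_bounds(m)
        for k in range(self.n_z):
            lb[self.off_z + k], ub[self.off_z + k] = 0.0, 1.0
        if self.thermo_on:
            lb[self.off_B], ub[self.off_B] = -self.config.bigM, self.config.bigM
        self.lb, self.ub = lb, ub
        self.integrality = np.zeros(self.n_var)
        self.integrality[self.off_z:self.off_z + self.n_z] = 1

    def _audit_bigM(self):
        if not self.thermo_on:
            return
        RT = self.config.RT
        for j in self.thermo_rxns:
            r = self.reactions[j]
            span = 0.0
            for met, coef in r.stoich.items():
                if met in self.boundary or met not in self.met_index:
                    continue
                lo, hi = ln_bounds(self.model.metabolite(met))
                span += abs(coef) * max(abs(lo), abs(hi))
            if abs(r.dG0) + RT * span >= self.config.bigM:
                raise ConfigurationError(
                    f"bigM={self.config.bigM} too small for reaction {r.id}: "
                    f"|dG0| + RT*span = {abs(r.dG0) + RT * span:.1f} kJ/mol"
                )

    def _build_rows(self):
        """Base rows shared by all objectives: (coefs, lo, hi) triples."""
        rows = []
        # mass balance over internal metabolites
        for m in self.model.internal_metabolites:
            coefs = {}
            for j, r in enumerate(self.reactions):
                c = r.stoich.get(m.id)
                if c:
                    coefs[j] = c
            if coefs:
                rows.append((coefs, 0.0, 0.0))
        # enzyme budget
        if self.enzyme_on:
            coefs = {}
            for j, r in enumerate(self.reactions):
                if r.efficiency is not None and r.id not in self.model.exchanges:
                    if r.effective_bounds[0] < 0:
                        raise ConfigurationError(
                            f"enzyme constraint needs a direction-split model; "
                            f"reaction {r.id} has negative flux lower bound"
                        )
                    coefs[j] = 1.0 / r.efficiency
            if coefs:
                rows.append((coefs, -np.inf, self.model.total_enzyme_bound))
        if self.thermo_on:
            RT, M = self.config.RT, self.config.bigM
            for j in self.thermo_rxns:
                r = self.reactions[j]
                zk = self.off_z + self.z_index[j]
                # v_j <= ub_eff * z_j
                ub_eff = min(r.effective_bounds[1], self.config.flux_cap)
                rows.append(({j: 1.0, zk: -ub_eff}, -np.inf, 0.0))
                # f_j >= B - M(1-z_j)  <=>  RT*sum(s x) + B + M z <= -dG0 + M
                coefs = {zk: M, self.off_B: 1.0}
                for met, coef in r.stoich.items():
                    if met in self.boundary:
                        continue
                    xi = self.off_x + self.met_index[met]
                    coefs[xi] = coefs.get(xi, 0.0) + RT * coef
                rows.append((coefs, -np.inf, -r.dG0 + M))
            for met_a, met_b, rlb, rub in self.config.ratio_constraints:
                if met_a not in self.met_index or met_b not in self.met_index:
                    continue
                xa = self.off_x + self.met_index[met_a]
                xb = self.off_x + self.met_index[met_b]
                rows.append(({xa: 1.0, xb: -1.0}, math.log(rlb), math.log(rub)))
        self.base_rows = rows

    # -- solving ---------------------------------------------------------
    def solve_raw(self, c, maximize=False, extra_rows=(), lb_over=None, ub_over=None):
        rows = list(self.base_rows) + list(extra_rows)
        data, ri, ci = [], [], []
        lo = np.empty(len(rows))
        hi = np.empty(len(rows))
        for k, (coefs, l, h) in enumerate(rows):
            lo[k], hi[k] = l, h
            for idx, val in coefs.items():
                ri.append(k)
                ci.append(idx)
                data.append(val)
        A = sparse.csc_array((data, (ri, ci)), shape=(len(rows), self.n_var))
        lb = self.lb if lb_over is None else lb_over
        ub = self.ub if ub_over is None else ub_over
        cvec = -np.asarray(c, dtype=float) if maximize else np.asarray(c, dtype=float)
        res = milp(
            cvec,
            constraints=[LinearConstraint(A, lo, hi)],
            integrality=self.integrality,
            bounds=Bounds(lb, ub),
        )
        return res

    def extract(self, res, maximize=False) -> SolveResult:
        status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")
        if status != "optimal":
            return SolveResult(status=status)
        x = res.x
        tol = self.config.flux_tol
        fluxes = {r.id: float(x[j]) for j, r in enumerate(self.reactions)}
        log_conc = {}
        mdf = None
        if self.thermo_on:
            log_conc = {
                m.id: float(x[self.off_x + self.met_index[m.id]]) for m in self.mets
            }
            mdf = float(x[self.off_B])
        active = {r.id: int(abs(fluxes[r.id]) > tol) for r in self.reactions}
        costs = {
            r.id: fluxes[r.id] / r.efficiency
            for r in self.reactions
            if r.efficiency is not None and r.id not in self.model.exchanges
        }
        obj = float(-res.fun if maximize else res.fun)
        return SolveResult(
            status=status,
            objective_value=obj,
            fluxes=fluxes,
            log_conc=log_conc,
            mdf=mdf,
            active=active,
            enzyme_costs=costs,
        )


@dataclass
class OptProblem:
    """An assembled optimization problem over a model.

    Holds the model, the thermodynamic configuration and the constraint
    switches; the variable layout and base constraint matrix are built
    once and shared by the solve functions.
    """

    model: CompartModel
    config: ThermoConfig
    enzyme_on: bool = False
    thermo_on: bool = False

    def __post_init__(self):
        self._asm = _Assembly(self.model, self.config, self.enzyme_on, self.thermo_on)

    @property
    def assembly(self) -> _Assembly:
        return self._asm

    def n_binaries(self) -> int:
        return self._asm.n_z

    def rxn_var(self, rxn_id: str) -> int:
        if rxn_id not in self._asm.rxn_index:
            raise KeyError(f"unknown reaction {rxn_id!r}")
        return self._asm.rxn_index[rxn_id]


def assemble_constraints(
    model: CompartModel,
    config: ThermoConfig,
    enzyme_on: bool = False,
    thermo_on: bool = False,
) -> OptProblem:
    """Build the FBA / enzyme-constrained / thermodynamic problem.

    Always: mass balance ``S v = 0`` over non-boundary metabolites and
    flux bounds.  With ``enzyme_on``: ``sum_i v_i / efficiency_i <=
    E_total`` over reactions carrying an efficiency.  With ``thermo_on``:
    log-concentration variables within bounds, ratio constraints, binary
    activity indicators and the big-M driving-force coupling to the free
    MDF variable B.
    """
    return OptProblem(model=model, config=config, enzyme_on=enzyme_on, thermo_on=thermo_on)


def solve_fba(problem: OptProblem, objective_reaction: str, sense: str = "max") -> SolveResult:
    """Maximise (or minimise) the flux of one reaction."""
    asm = problem.assembly
    j = problem.rxn_var(objective_reaction)
    c = np.zeros(asm.n_var)
    c[j] = 1.0
    res = asm.solve_raw(c, maximize=(sense == "max"))
    return asm.extract(res, maximize=(sense == "max"))


def solve_pfba(
    problem: OptProblem, objective_reaction: str, mdf_lb: float | None = None
) -> SolveResult:
    """Parsimonious FBA: fix the FBA optimum, then minimise total flux.

    Requires a direction-split model (all flux lower bounds >= 0) so that
    total flux is a linear objective.  With ``mdf_lb`` (thermo problems
    only), both stages additionally require B >= mdf_lb.
    """
    asm = problem.assembly
    if any(r.effective_bounds[0] < 0 for r in asm.reactions):
        raise ConfigurationError("pFBA requires a direction-split model (v >= 0)")
    lb = None
    if mdf_lb is not None:
        if not problem.thermo_on:
            raise ConfigurationError("mdf_lb requires thermo constraints")
        lb = asm.lb.copy()
        lb[asm.off_B] = max(lb[asm.off_B], mdf_lb)
    j = problem.rxn_var(objective_reaction)
    c1 = np.zeros(asm.n_var)
    c1[j] = 1.0
    first = asm.extract(asm.solve_raw(c1, maximize=True, lb_over=lb), maximize=True)
    if not first.optimal:
        return first
    opt = first.objective_value
    fix = ({j: 1.0}, opt - max(asm.config.flux_tol, _REFIX_EPS), np.inf)
    c = np.zeros(asm.n_var)
    c[: asm.n_r] = 1.0
    res = asm.solve_raw(c, maximize=False, extra_rows=[fix], lb_over=lb)
    out = asm.extract(res, maximize=False)
    if out.optimal:
        out.objective_value = out.fluxes[objective_reaction]
    return out


def solve_max_mdf(problem: OptProblem, product_reaction: str, min_flux: float) -> SolveResult:
    """Maximise the pathway MDF B subject to v_product >= min_flux."""
    asm = problem.assembly
    if not problem.thermo_on:
        raise ConfigurationError("solve_max_mdf requires thermo constraints")
    j = problem.rxn_var(product_reaction)
    extra = [({j: 1.0}, min_flux, np.inf)]
    if asm.n_z:
        # at least one reaction must be thermodynamically active, otherwise
        # B is vacuously unbounded at min_flux = 0
        extra.append(({asm.off_z + k: 1.0 for k in range(asm.n_z)}, 1.0, np.inf))
    c = np.zeros(asm.n_var)
    c[asm.off_B] = 1.0
    res = asm.solve_raw(c, maximize=True, extra_rows=extra)
    out = asm.extract(res, maximize=True)
    if out.optimal:
        out.mdf = out.objective_value
    return out


def solve_max_flux_at_mdf(problem: OptProblem, product_reaction: str, mdf_lb: float) -> SolveResult:
    """Maximise product flux subject to B >= mdf_lb."""
    asm = problem.assembly
    if not problem.thermo_on:
        raise ConfigurationError("solve_max_flux_at_mdf requires thermo constraints")
    j = problem.rxn_var(product_reaction)
    lb = asm.lb.copy()
    lb[asm.off_B] = max(lb[asm.off_B], mdf_lb)
    c = np.zeros(asm.n_var)
    c[j] = 1.0
    res = asm.solve_raw(c, maximize=True, lb_over=lb)
    return asm.extract(res, maximize=True)


def write_lp(problem: OptProblem, path, objective_reaction: str | None = None) -> None:
    """Export the assembled problem as CPLEX-LP text for debugging."""
    asm = problem.assembly

    def vname(i: int) -> str:
        if i < asm.n_r:
            return f"v_{asm.reactions[i].id}"
        if i < asm.off_z:
            return f"lnc_{asm.mets[i - asm.off_x].id}"
        if asm.thermo_on and i == asm.off_B:
            return "B"
        return f"z_{asm.reactions[asm.thermo_rxns[i - asm.off_z]].id}"

    lines = ["\\ mdflux problem export", "Maximize", " obj: "
             + (f"v_{objective_reaction}" if objective_reaction else ("B" if asm.thermo_on else "0 v_" + asm.reactions[0].id))]
    lines.append("Subject To")
    for k, (coefs, lo, hi) in enumerate(asm.base_rows):
        expr = " + ".join(f"{val:.12g} {vname(i)}" for i, val in sorted(coefs.items()))
        expr = expr.replace("+ -", "- ")
        if lo == hi:
            lines.append(f" c{k}: {expr} = {lo:.12g}")
        else:
            if np.isfinite(hi):
                lines.append(f" c{k}u: {expr} <= {hi:.12g}")
            if np.isfinite(lo):
                lines.append(f" c{k}l: {expr} >= {lo:.12g}")
    lines.append("Bounds")
    for i in range(asm.n_var):
        lines.append(f" {asm.lb[i]:.12g} <= {vname(i)} <= {asm.ub[i]:.12g}")
    if asm.n_z:
        lines.append("Binaries")
        lines.append(" " + " ".join(vname(asm.off_z + k) for k in range(asm.n_z)))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def flux_variability(
    problem: OptProblem,
    rxn_ids=None,
    fixed: dict | None = None,
) -> dict:
    """Min/max flux per reaction under the problem's constraints.

    ``fixed`` maps reaction ids to (lb, ub) overrides (e.g. to pin the
    objective at its optimum).  Returns ``{rxn_id: (vmin, vmax)}``.
    """
    asm = problem.assembly
    ids = rxn_ids if rxn_ids is not None else [r.id for r in asm.reactions]
    extra = []
    for rid, (lo, hi) in (fixed or {}).items():
        extra.append(({problem.rxn_var(rid): 1.0}, lo, hi))
    out = {}
    for rid in ids:
        j = problem.rxn_var(rid)
        c = np.zeros(asm.n_var)
        c[j] = 1.0
        lo_res = asm.solve_raw(c, maximize=False, extra_rows=extra)
        hi_res = asm.solve_raw(c, maximize=True, extra_rows=extra)
        vmin = float(lo_res.x[j]) if lo_res.status == 0 else math.nan
        vmax = float(hi_res.x[j]) if hi_res.status == 0 else math.nan
        out[rid] = (vmin, vmax)
    return out
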