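"""MDF-versus-required-yield staircase curves.

As the required product flux grows, fewer pathway combinations remain
admissible and the achievable max-min driving force can only decrease,
producing a non-increasing staircase.  Flat plateaus are *stages* (one
dominant pathway set); the flux where the MDF drops is a *turning
point*, where the network is forced onto a thermodynamically worse
route to buy more yield.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .model import CompartModel, ThermoConfig
from .opt import OptProblem, assemble_constraints, solve_fba, solve_max_mdf

__all__ = ["MDFCurve", "Stage", "sweep_mdf_curve", "detect_stages", "yield_percentage"]

#: flux resolution to which turning points are localised by bisection
FLUX_RESOLUTION = 1e-3

#: default MDF plateau tolerance (kJ/mol) separating distinct stages
STAGE_TOL = 0.01


@dataclass
class Stage:
    """One MDF plateau: flux range (lo, hi], its MDF level, and the
    bottleneck reactions pinning it (filled in by diagnostics)."""

    index: int
    flux_lo: float
    flux_hi: float
    mdf: float
    bottlenecks: list = field(default_factory=list)


@dataclass
class MDFCurve:
    product: str
    grid: list
    mdf_values: list
    stages: list = field(default_factory=list)
    max_flux: float = 0.0

    @property
    def turning_points(self) -> list:
        """Last feasible flux of each stage."""
        return [s.flux_hi for s in self.stages]

    def mdf_at(self, flux: float) -> float:
        """MDF of the grid point at or just above ``flux``."""
        i = bisect.bisect_left(self.grid, flux - 1e-12)
        i = min(i, len(self.grid) - 1)
        return self.mdf_values[i]


def sweep_mdf_curve(
    model: CompartModel,
    config: ThermoConfig,
    product: str,
    n_points: int = 50,
    refine: bool = True,
    enzyme_on: bool = False,
    stage_tol: float = STAGE_TOL,
) -> MDFCurve:
    """Evaluate max-MDF on a uniform required-flux grid from 0 to the
    FBA maximum, optionally bisecting each MDF drop to localise the
    turning point within :data:`FLUX_RESOLUTION`.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    problem = assemble_constraints(model, config, enzyme_on=enzyme_on, thermo_on=True)
    fba = solve_fba(problem, product)
    if not fba.optimal or fba.objective_value <= config.flux_tol:
        raise ValueError(f"product reaction {product!r} can never carry flux")
    max_flux = fba.objective_value

    grid = list(np.linspace(0.0, max_flux, n_points))
    values = [_mdf_at(problem, product, f) for f in grid]

    if refine:
        i = 0
        while i < len(grid) - 1:
            lo_f, hi_f = grid[i], grid[i + 1]
            lo_v, hi_v = values[i], values[i + 1]
            if abs(lo_v - hi_v) > stage_tol and hi_f - lo_f > FLUX_RESOLUTION:
                mid = 0.5 * (lo_f + hi_f)
                grid.insert(i + 1, mid)
                values.insert(i + 1, _mdf_at(problem, product, mid))
                continue  # re-examine the narrowed left interval
            i += 1

    curve = MDFCurve(product=product, grid=grid, mdf_values=values, max_flux=max_flux)
    curve.stages = detect_stages(curve, stage_tol=stage_tol)
    return curve


def _mdf_at(problem: OptProblem, product: str, min_flux: float) -> float:
    # the staircase profiles the product pathway, so even the zero-demand
    # grid point requires an infinitesimal product flux (a literal zero
    # demand would profile the best single reaction anywhere in the
    # network instead)
    # (the epsilon sits well above the solver's integer-feasibility
    # tolerance so the demand cannot be rounded away)
    min_flux = max(min_flux, 100 * problem.config.flux_tol)
    res = solve_max_mdf(problem, product, min_flux)
    if not res.optimal:
        return float("nan")
    return res.mdf


def detect_stages(curve: MDFCurve, stage_tol: float = STAGE_TOL) -> list:
    """Greedy left-to-right grouping of grid points into MDF plateaus.

    A point joins the current stage while its MDF differs from the
    stage's first point by at most ``stage_tol``; the turning point is
    the last flux of each stage.  Flux ranges are half-open (lo, hi], so
    each turning point belongs to the stage it terminates.
    """
    stages: list[Stage] = []
    start = None
    for flux, mdf in zip(curve.grid, curve.mdf_values):
        if mdf != mdf:  # NaN: infeasible tail
            break
        if start is None or abs(mdf - start) > stage_tol:
            lo = stages[-1].flux_hi if stages else curve.grid[0]
            stages.append(Stage(index=len(stages) + 1, flux_lo=lo, flux_hi=flux, mdf=mdf))
            start = mdf
        else:
            stages[-1].flux_hi = flux
    return stages


def yield_percentage(flux: float, max_flux: float, ndigits: int = 1) -> float:
    """Flux as a percentage of the maximal (stoichiometric) flux,
    rounded for reporting (pass ``ndigits=None`` for the raw value)."""
    if max_flux <= 0:
        raise ValueError(f"max_flux must be positive, got {max_flux}")
    pct = 100.0 * flux / max_flux
    return pct if ndigits is None else round(pct, ndigits)
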