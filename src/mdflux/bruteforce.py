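"""Brute-force grid evaluation of max-min driving force problems.

These routines evaluate driving forces directly from ``dG0`` and a dense
grid of log-concentrations, with no linear programming involved.  They
are exponential in the number of metabolites and only usable on very
small networks (<= 5 internal metabolites), where they serve as an
independent numerical cross-check of the MILP solutions.  Memory is kept
at ``n_grid^(k-1)`` by iterating over the first concentration axis.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .model import CompartModel, ThermoConfig, ln_bounds

__all__ = ["grid_max_min_driving_force", "grid_concentration_ranges"]

_MAX_METS = 5


def _grid_setup(model: CompartModel, config: ThermoConfig, reaction_ids, n_grid):
    rxns = [model.reaction(rid) for rid in reaction_ids]
    for r in rxns:
        if r.dG0 is None:
            raise ValueError(f"reaction {r.id} has no dG0; cannot grid-search")
    boundary = model.boundary_ids()
    met_ids = sorted({m for r in rxns for m in r.stoich if m not in boundary})
    if len(met_ids) > _MAX_METS:
        raise ValueError(
            f"grid oracle supports at most {_MAX_METS} internal metabolites, "
            f"got {len(met_ids)}"
        )
    axes = [np.linspace(*ln_bounds(model.metabolite(m)), n_grid) for m in met_ids]
    return rxns, met_ids, axes


def _block(rxns, met_ids, axes, config, fixed):
    """(min driving force, ratio-feasibility mask) over the grid of
    ``axes`` for metabolites ``met_ids``, with ``fixed`` log-concs."""
    index = {m: i for i, m in enumerate(met_ids)}
    grids = np.meshgrid(*axes, indexing="ij") if axes else []
    shape = tuple(len(a) for a in axes) or (1,)
    min_f = None
    for r in rxns:
        f = -float(r.dG0)
        for m, coef in r.stoich.items():
            if m in fixed:
                f = f - config.RT * coef * fixed[m]
        term = np.full(shape, f)
        for m, coef in r.stoich.items():
            if m in index:
                term = term - config.RT * coef * grids[index[m]]
        min_f = term if min_f is None else np.minimum(min_f, term)
    mask = np.ones(shape, dtype=bool)
    for met_a, met_b, rlb, rub in config.ratio_constraints:
        known_a = met_a in index or met_a in fixed
        known_b = met_b in index or met_b in fixed
        if not (known_a and known_b):
            continue
        xa = grids[index[met_a]] if met_a in index else fixed[met_a]
        xb = grids[index[met_b]] if met_b in index else fixed[met_b]
        diff = xa - xb
        mask &= (diff >= math.log(rlb) - 1e-12) & (diff <= math.log(rub) + 1e-12)
    return min_f, mask


def _iter_blocks(rxns, met_ids, axes, config):
    """Yield ``(fixed_first_value_or_None, min_f, mask, grids_rest)``
    blocks, chunking over the first axis when there are > 3 axes."""
    if len(axes) <= 3:
        min_f, mask = _block(rxns, met_ids, axes, config, {})
        yield None, min_f, mask, axes, met_ids
        return
    first, rest = met_ids[0], met_ids[1:]
    for x0 in axes[0]:
        min_f, mask = _block(rxns, rest, axes[1:], config, {first: float(x0)})
        yield float(x0), min_f, mask, axes[1:], rest


def grid_max_min_driving_force(
    model: CompartModel,
    config: ThermoConfig,
    reaction_ids,
    n_grid: int = 200,
):
    """Max over a log-concentration grid of the min driving force.

    Returns ``(B, log_conc)`` where ``log_conc`` maps the internal
    metabolites of the given reactions to the grid point attaining B.
    All listed reactions are treated as active; they must carry a dG0.
    """
    rxns, met_ids, axes = _grid_setup(model, config, reaction_ids, n_grid)
    if not met_ids:
        return min(-float(r.dG0) for r in rxns), {}
    best_B = -np.inf
    best_point: dict = {}
    for x0, min_f, mask, block_axes, block_mets in _iter_blocks(rxns, met_ids, axes, config):
        vals = np.where(mask, min_f, -np.inf)
        flat = int(np.argmax(vals))
        if vals.ravel()[flat] > best_B:
            best_B = float(vals.ravel()[flat])
            idx = np.unravel_index(flat, vals.shape)
            best_point = {
                m: float(block_axes[i][idx[i]]) for i, m in enumerate(block_mets)
            }
            if x0 is not None:
                best_point[met_ids[0]] = x0
    if not np.isfinite(best_B):
        raise ValueError("no grid point satisfies the ratio constraints")
    return best_B, best_point


def grid_concentration_ranges(
    model: CompartModel,
    config: ThermoConfig,
    reaction_ids,
    B_star: float,
    tol: float = 1e-6,
    n_grid: int = 200,
):
    """Concentration ranges over grid points with min driving force >= B* - tol.

    Returns ``{met_id: (conc_min, conc_max)}`` in mol/L for the internal
    metabolites of the listed reactions.
    """
    rxns, met_ids, axes = _grid_setup(model, config, reaction_ids, n_grid)
    lo = {m: np.inf for m in met_ids}
    hi = {m: -np.inf for m in met_ids}
    any_feasible = False
    for x0, min_f, mask, block_axes, block_mets in _iter_blocks(rxns, met_ids, axes, config):
        feasible = mask & (min_f >= B_star - tol)
        if not feasible.any():
            continue
        any_feasible = True
        grids = np.meshgrid(*block_axes, indexing="ij")
        for i, m in enumerate(block_mets):
            vals = grids[i][feasible]
            lo[m] = min(lo[m], float(vals.min()))
            hi[m] = max(hi[m], float(vals.max()))
        if x0 is not None:
            first = met_ids[0]
            lo[first] = min(lo[first], x0)
            hi[first] = max(hi[first], x0)
    if not any_feasible:
        raise ValueError(f"no grid point reaches min driving force {B_star}")
    return {m: (math.exp(lo[m]), math.exp(hi[m])) for m in met_ids}


def enumerate_pathway_flux_splits(capacities, step: float, total: float):
    """All splits of ``total`` flux over parallel routes at ``step``
    resolution, within per-route capacities; helper for tiny pFBA
    cross-checks by exhaustive enumeration."""
    ticks = [np.arange(0.0, cap + step / 2, step) for cap in capacities]
    for combo in itertools.product(*ticks):
        if abs(sum(combo) - total) < step / 2:
            yield combo
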