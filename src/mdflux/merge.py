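"""Merging partial reactions catalysed within one enzyme microcompartment.

Multifunctional enzymes, enzyme complexes and substrate channels carry
out several partial reactions without releasing the intermediates into
the cytoplasm.  Modeling the partials as independent reactions exposes
those intermediates to the network's concentration bounds and can make a
jointly feasible catalytic cycle look thermodynamically infeasible.  The
correction is to replace the partials by their stoichiometric sum: the
intermediate log-concentration terms cancel algebraically, so at any
concentration vector the merged driving force equals the
multiplier-weighted sum of the partial driving forces, and the merged
dG0 is the weighted sum of the partial dG0 values.

The kinetic parameter of the merged reaction is the minimum kcat/MW over
the parts (the catalytic cycle is limited by its weakest step), the gene
set is the union, and the dG0 uncertainty combines as a root-sum-square.
The partial reactions are shut, not deleted, so the correction remains
visible and reversible data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import CompartModel, Reaction

__all__ = [
    "MergeSpec",
    "MergeResult",
    "merge_reactions",
    "shut_reactions",
    "find_redundant_reactions",
    "apply_scenario",
    "shared_gene_merge_hints",
]


@dataclass
class MergeSpec:
    """Instruction to merge >= 2 irreversible partial reactions.

    ``parts`` is a list of ``(reaction_id, multiplier)`` with positive
    integer multipliers.  ``declared_intermediates`` (optional) must each
    cancel exactly in the weighted sum, as an audit.  ``dG0_override``
    replaces the additivity value (the additivity value is still computed
    and logged).  With ``reversible_pair``, a mirrored reaction
    ``<merged_id>_r`` with negated stoichiometry and dG0 is added too.
    """

    merged_id: str
    parts: list
    declared_intermediates: set | None = None
    dG0_override: float | None = None
    reversible_pair: bool = False

    def __post_init__(self):
        if len(self.parts) < 2:
            raise ValueError("a merge needs at least two parts")
        for rid, mult in self.parts:
            if int(mult) != mult or mult < 1:
                raise ValueError(f"multiplier for {rid} must be a positive integer")


@dataclass
class MergeResult:
    new_model: CompartModel
    merged_reaction: Reaction
    cancelled: set = field(default_factory=set)
    shut: list = field(default_factory=list)
    audit: str = ""


def merge_reactions(model: CompartModel, spec: MergeSpec) -> MergeResult:
    """Apply one merge: weighted-sum stoichiometry, shut the parts.

    Metabolites whose net coefficient vanishes are cancelled
    (automatically detected); a declared intermediate that does not
    cancel is an error.  If nothing cancels and nothing was declared,
    the merge is a pure lumping and only noted in the audit trail.
    """
    parts = []
    for rid, mult in spec.parts:
        r = model.reaction(rid)
        if r.reversible:
            raise ValueError(
                f"part {rid} is reversible; merge operates on direction-split models"
            )
        parts.append((r, int(mult)))
    if model.has_reaction(spec.merged_id):
        raise ValueError(f"merged id {spec.merged_id!r} already exists")

    stoich: dict[str, float] = {}
    for r, mult in parts:
        for met, coef in r.stoich.items():
            stoich[met] = stoich.get(met, 0.0) + mult * coef
    cancelled = {met for met, coef in stoich.items() if abs(coef) < 1e-9}
    stoich = {met: coef for met, coef in stoich.items() if abs(coef) >= 1e-9}
    if not stoich:
        raise ValueError("merged stoichiometry is empty (all metabolites cancel)")

    audit_lines = [f"merge {spec.merged_id} = " + " + ".join(
        f"{mult}*{r.id}" for r, mult in parts
    )]
    if spec.declared_intermediates is not None:
        for met in spec.declared_intermediates:
            if met not in cancelled:
                residual = stoich.get(met, 0.0)
                raise ValueError(
                    f"declared intermediate {met!r} does not cancel "
                    f"(residual coefficient {residual})"
                )
        audit_lines.append(f"declared intermediates cancel: {sorted(spec.declared_intermediates)}")
    elif not cancelled:
        audit_lines.append("warning: no metabolite cancels (pure lumping)")
    else:
        audit_lines.append(f"cancelled intermediates: {sorted(cancelled)}")

    dG0_sum = None
    if all(r.dG0 is not None for r, _ in parts):
        dG0_sum = sum(mult * r.dG0 for r, mult in parts)
        audit_lines.append(f"additivity dG0 = {dG0_sum:.6g} kJ/mol")
    dG0 = spec.dG0_override if spec.dG0_override is not None else dG0_sum
    if spec.dG0_override is not None:
        audit_lines.append(f"dG0 overridden to {spec.dG0_override}")

    sds = [(mult, r.dG0_uncertainty) for r, mult in parts if r.dG0_uncertainty is not None]
    dG0_sd = math.sqrt(sum((mult * sd) ** 2 for mult, sd in sds)) if sds else None

    effs = [r.efficiency for r, _ in parts if r.efficiency is not None]
    efficiency = min(effs) if effs else None
    genes = frozenset().union(*(r.genes for r, _ in parts))

    flux_ub = min(r.flux_ub / mult for r, mult in parts)
    merged = Reaction(
        id=spec.merged_id,
        stoich=stoich,
        flux_lb=0.0,
        flux_ub=flux_ub,
        dG0=dG0,
        dG0_uncertainty=dG0_sd,
        efficiency=efficiency,
        genes=genes,
        status="added",
    )

    new_model = model.copy()
    new_model.reactions.append(merged)
    shut_ids = [r.id for r, _ in parts]
    for r in new_model.reactions:
        if r.id in shut_ids:
            r.status = "shut"
    if spec.reversible_pair:
        mirrored = merged.copy()
        mirrored.id = spec.merged_id + "_r"
        mirrored.stoich = {m: -c for m, c in stoich.items()}
        mirrored.dG0 = None if dG0 is None else -dG0
        new_model.reactions.append(mirrored)
        audit_lines.append(f"reversible pair: added {mirrored.id}")
    return MergeResult(
        new_model=new_model,
        merged_reaction=merged,
        cancelled=cancelled,
        shut=shut_ids,
        audit="\n".join(audit_lines),
    )


def shut_reactions(model: CompartModel, ids) -> CompartModel:
    """Mark the listed reactions shut (effective flux bounds (0, 0))."""
    out = model.copy()
    known = {r.id for r in out.reactions}
    for rid in ids:
        if rid not in known:
            raise KeyError(f"unknown reaction {rid!r}")
    for r in out.reactions:
        if r.id in set(ids):
            r.status = "shut"
    return out


def find_redundant_reactions(model: CompartModel) -> list:
    """Flag structurally unusable reactions on a direction-split model.

    Three reasons are reported: ``orphan-substrate`` (the reaction
    consumes a metabolite nothing produces), ``dead-end-product`` (it
    produces a metabolite nothing consumes) and ``blocked`` (its flux
    range under variability analysis with open exchanges and no demand is
    zero, and neither structural reason applies).  Boundary metabolites
    are exempt.  Returns ``[(reaction_id, reason), ...]``.
    """
    from .model import ThermoConfig
    from .opt import assemble_constraints, flux_variability

    from .model import REVERSE_SUFFIX

    boundary = model.boundary_ids()
    producers: dict[str, set] = {}
    consumers: dict[str, set] = {}
    for r in model.reactions:
        if r.status == "shut":
            continue
        for met, coef in r.stoich.items():
            if met in boundary:
                continue
            if coef > 0 or (coef < 0 and r.reversible):
                producers.setdefault(met, set()).add(r.id)
            if coef < 0 or (coef > 0 and r.reversible):
                consumers.setdefault(met, set()).add(r.id)

    def _sibling(rid: str) -> str:
        # the mirror direction of a split reversible pair can only run a
        # futile cycle with its partner, so it does not count as an
        # independent producer/consumer
        if rid.endswith(REVERSE_SUFFIX):
            return rid[: -len(REVERSE_SUFFIX)]
        return rid + REVERSE_SUFFIX

    flagged: dict[str, str] = {}
    for r in model.reactions:
        if r.status == "shut":
            continue
        ignore = {r.id, _sibling(r.id)}
        for met in r.substrates:
            if met not in boundary and not (producers.get(met, set()) - ignore):
                flagged.setdefault(r.id, f"orphan-substrate: {met}")
        for met in r.products:
            if met not in boundary and not (consumers.get(met, set()) - ignore):
                flagged.setdefault(r.id, f"dead-end-product: {met}")

    problem = assemble_constraints(model, ThermoConfig())
    remaining = [
        r.id for r in model.reactions if r.id not in flagged and r.status != "shut"
    ]
    fva = flux_variability(problem, remaining)
    for rid, (vmin, vmax) in fva.items():
        if max(abs(vmin), abs(vmax)) <= 1e-9:
            flagged.setdefault(rid, "blocked")
    return sorted(flagged.items())


def apply_scenario(
    model: CompartModel, scenario: str, oxygen_exchange_id: str | None = None
) -> CompartModel:
    """Switch between aerobic and anaerobic growth scenarios.

    ``anaerobic`` closes the oxygen exchange reaction (bounds (0, 0)),
    remembering the aerobic bounds; ``aerobic`` restores them.  The
    oxygen exchange is found by id, or among exchanges whose id contains
    ``o2`` (case-insensitive) but not ``co2``.
    """
    if scenario not in ("aerobic", "anaerobic"):
        raise ValueError(f"unknown scenario {scenario!r}")
    out = model.copy()
    if oxygen_exchange_id is None:
        candidates = [
            rid for rid in out.exchanges
            if "o2" in rid.lower() and "co2" not in rid.lower()
        ]
        if scenario == "anaerobic" and not candidates:
            raise KeyError("no oxygen exchange reaction found")
        oxygen_exchange_id = candidates[0] if candidates else None
    if oxygen_exchange_id is None:
        return out
    rxn = out.reaction(oxygen_exchange_id)
    if scenario == "anaerobic":
        out.aerobic_bounds.setdefault(rxn.id, (rxn.flux_lb, rxn.flux_ub))
        rxn.flux_lb, rxn.flux_ub = 0.0, 0.0
    else:
        if rxn.id in out.aerobic_bounds:
            rxn.flux_lb, rxn.flux_ub = out.aerobic_bounds.pop(rxn.id)
    return out


def shared_gene_merge_hints(model: CompartModel) -> list:
    """Pairs of active reactions sharing at least one gene — merge
    candidates to review by hand, never merged automatically."""
    hints = []
    rxns = [r for r in model.reactions if r.genes and r.status != "shut"]
    for i, a in enumerate(rxns):
        for b in rxns[i + 1:]:
            shared = a.genes & b.genes
            if shared:
                hints.append((a.id, b.id, sorted(shared)))
    return hints
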