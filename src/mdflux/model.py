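"""Data model for multi-constraint metabolic networks.

A :class:`CompartModel` couples an ordinary stoichiometric network with the
two extra parameter layers needed for thermodynamic and enzyme-cost
analysis:

* per-reaction standard transformed Gibbs energies ``dG0`` (kJ/mol) with an
  optional uncertainty, and catalytic efficiencies ``kcat/MW``
  (h^-1/kDa);
* per-metabolite concentration bounds (mol/L) within which the
  log-concentration variables of the max-min driving force (MDF) problem
  may move.

Concentrations are stored in mol/L and all logarithms are natural logs of
the numeric value in mol/L (reference state 1 M), so that the transformed
reaction energy equals ``dG0`` exactly at unit concentrations.

Reactions without a ``dG0`` (exchanges, biomass, lumped sinks) are exempt
from thermodynamic constraints; reactions without an ``efficiency`` are
exempt from the enzyme-cost constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "CompartModel",
    "ThermoConfig",
    "validate_model",
    "split_reversible",
    "REVERSE_SUFFIX",
]

REVERSE_SUFFIX = "_reverse"

#: reaction bookkeeping states mirroring a curation table's "Notes" column
VALID_STATUS = ("keep", "shut", "added")


@dataclass
class Metabolite:
    """A metabolite with concentration bounds.

    Parameters
    ----------
    id:
        Identifier, conventionally with a compartment suffix
        (``ser__L_c``).
    conc_lb, conc_ub:
        Concentration bounds in mol/L. Must satisfy ``0 < lb <= ub`` for
        non-boundary metabolites (the log-concentration variable is
        otherwise undefined).
    is_boundary:
        Boundary metabolites (extracellular sinks/sources) are excluded
        from mass balance and carry no concentration variable.
    """

    id: str
    name: str = ""
    conc_lb: float = 0.5e-6
    conc_ub: float = 20e-3
    is_boundary: bool = False


@dataclass
class Reaction:
    """A (possibly reversible) reaction with thermodynamic and kinetic data.

    ``stoich`` maps metabolite id to a signed coefficient (negative =
    substrate).  ``dG0`` is the standard transformed reaction Gibbs energy
    in kJ/mol; ``efficiency`` is kcat/MW in h^-1/kDa, so that
    ``flux / efficiency`` is an enzyme cost in g enzyme / gDW.  ``status``
    is a curation flag: ``keep`` (normal), ``shut`` (excluded — effective
    flux bounds are (0, 0)) or ``added`` (introduced by a merge).
    """

    id: str
    stoich: dict[str, float]
    reversible: bool = False
    flux_lb: float = 0.0
    flux_ub: float = 1000.0
    dG0: float | None = None
    dG0_uncertainty: float | None = None
    efficiency: float | None = None
    genes: frozenset = field(default_factory=frozenset)
    gene_rule: str = ""
    status: str = "keep"

    @property
    def effective_bounds(self) -> tuple[float, float]:
        """Flux bounds with the ``shut`` status applied."""
        if self.status == "shut":
            return (0.0, 0.0)
        return (self.flux_lb, self.flux_ub)

    @property
    def substrates(self) -> list[str]:
        return [m for m, s in self.stoich.items() if s < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, s in self.stoich.items() if s > 0]

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich), genes=frozenset(self.genes))


@dataclass
class CompartModel:
    """A metabolic network with thermodynamic and enzymatic parameters.

    ``exchanges`` lists the reactions crossing the system boundary (these
    are never thermodynamically constrained).  ``total_enzyme_bound`` is
    the proteome budget E_total in g enzyme / gDW that caps the summed
    enzyme cost when the enzyme constraint is switched on.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    exchanges: set = field(default_factory=set)
    total_enzyme_bound: float = 0.13
    provenance: str = ""
    # populated the first time an anaerobic scenario is applied, so the
    # aerobic bounds can be restored later
    aerobic_bounds: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"unknown metabolite {met_id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"unknown reaction {rxn_id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    def boundary_ids(self) -> set:
        return {m.id for m in self.metabolites if m.is_boundary}

    def stoichiometric_matrix(self, internal_only: bool = True):
        """Return ``(S, met_ids, rxn_ids)`` with S as a dense numpy array.

        Rows are metabolites (internal only by default), columns reactions.
        """
        import numpy as np

        mets = self.internal_metabolites if internal_only else self.metabolites
        met_ids = [m.id for m in mets]
        rxn_ids = [r.id for r in self.reactions]
        idx = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoich.items():
                i = idx.get(met)
                if i is not None:
                    S[i, j] = coef
        return S, met_ids, rxn_ids

    def copy(self) -> "CompartModel":
        return CompartModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            exchanges=set(self.exchanges),
            total_enzyme_bound=self.total_enzyme_bound,
            provenance=self.provenance,
            aerobic_bounds=dict(self.aerobic_bounds),
        )


@dataclass
class ThermoConfig:
    """Thermodynamic settings and numerical tolerances.

    ``RT`` defaults to 2.579 kJ/mol (310 K).  Default concentration
    bounds are 0.5 µM – 20 mM; dissolved gases and ammonia get tighter
    physiological windows (O2 0.5–200 µM, CO2 0.1–100 µM, NH4 10 µM–1 mM).
    ``ratio_constraints`` entries are ``(met_a, met_b, ratio_lb,
    ratio_ub)`` limiting the concentration ratio c_a/c_b (e.g. a redox
    cofactor pair).  ``bigM`` is the indicator relaxation constant of the
    MDF MILP in kJ/mol; ``flux_cap`` caps infinite flux upper bounds when
    linking fluxes to activity indicators.
    """

    RT: float = 2.579
    default_conc_lb: float = 0.5e-6
    default_conc_ub: float = 20e-3
    special_bounds: dict = field(
        default_factory=lambda: {
            "o2": (0.5e-6, 200e-6),
            "co2": (0.1e-6, 100e-6),
            "nh4": (10e-6, 1e-3),
        }
    )
    ratio_constraints: list = field(default_factory=list)
    bigM: float = 1000.0
    mdf_tol: float = 1e-4
    flux_tol: float = 1e-6
    flux_cap: float = 1000.0
    # diagnostics tolerances
    var_tol: float = 1e-3
    key_tol: float = 1e-6
    bind_tol: float = 1e-6

    def bounds_for(self, met_id: str) -> tuple[float, float]:
        """Concentration bounds for a metabolite id, honouring special
        bounds keyed by the id stripped of its compartment suffix."""
        stem = met_id.rsplit("_", 1)[0].lower() if "_" in met_id else met_id.lower()
        if stem in self.special_bounds:
            return tuple(self.special_bounds[stem])
        if met_id.lower() in self.special_bounds:
            return tuple(self.special_bounds[met_id.lower()])
        return (self.default_conc_lb, self.default_conc_ub)


# ---------------------------------------------------------------------------


def validate_model(model: CompartModel) -> list[str]:
    """Check every type invariant; return one finding string per violation.

    An empty list means the model is valid.  Findings name the offending
    reaction or metabolite; nothing is raised.
    """
    findings: list[str] = []
    seen_mets: set = set()
    for m in model.metabolites:
        if m.id in seen_mets:
            findings.append(f"metabolite {m.id}: duplicate id")
        seen_mets.add(m.id)
        if not m.is_boundary:
            if not (m.conc_lb > 0):
                findings.append(
                    f"metabolite {m.id}: conc_lb must be > 0 (log undefined), got {m.conc_lb}"
                )
            if m.conc_lb > m.conc_ub:
                findings.append(
                    f"metabolite {m.id}: conc_lb {m.conc_lb} > conc_ub {m.conc_ub}"
                )
    seen_rxns: set = set()
    for r in model.reactions:
        if r.id in seen_rxns:
            findings.append(f"reaction {r.id}: duplicate id")
        seen_rxns.add(r.id)
        if not r.stoich:
            findings.append(f"reaction {r.id}: empty stoichiometry")
        for met, coef in r.stoich.items():
            if coef == 0:
                findings.append(f"reaction {r.id}: zero coefficient for {met}")
            if met not in seen_mets and not any(m.id == met for m in model.metabolites):
                findings.append(f"reaction {r.id}: unknown metabolite {met}")
        if r.flux_lb > r.flux_ub:
            findings.append(
                f"reaction {r.id}: flux_lb {r.flux_lb} > flux_ub {r.flux_ub}"
            )
        if r.efficiency is not None and not (r.efficiency > 0):
            findings.append(f"reaction {r.id}: efficiency must be > 0, got {r.efficiency}")
        if r.status not in VALID_STATUS:
            findings.append(f"reaction {r.id}: unknown status {r.status!r}")
    if not (model.total_enzyme_bound > 0):
        findings.append(f"model: total_enzyme_bound must be > 0, got {model.total_enzyme_bound}")
    return findings


def split_reversible(model: CompartModel) -> CompartModel:
    """Replace every reversible reaction by an irreversible forward/reverse
    pair.

    The reverse direction is named ``<id>_reverse``, its stoichiometry is
    negated and its ``dG0`` sign-flipped; efficiency, uncertainty and gene
    associations are shared.  Both directions get non-negative flux
    bounds.  Idempotent on its own output.
    """
    out = model.copy()
    new_reactions: list[Reaction] = []
    existing = {r.id for r in out.reactions}
    for r in out.reactions:
        if not r.reversible:
            new_reactions.append(r)
            continue
        rev_id = r.id + REVERSE_SUFFIX
        if rev_id in existing:
            raise ValueError(
                f"cannot split {r.id}: id {rev_id!r} already exists in the model"
            )
        fwd = r.copy()
        fwd.reversible = False
        fwd.flux_lb = max(0.0, r.flux_lb)
        fwd.flux_ub = max(0.0, r.flux_ub)
        rev = r.copy()
        rev.id = rev_id
        rev.reversible = False
        rev.stoich = {m: -c for m, c in r.stoich.items()}
        rev.dG0 = None if r.dG0 is None else -r.dG0
        rev.flux_lb = 0.0
        rev.flux_ub = -r.flux_lb if r.flux_lb < 0 else max(0.0, r.flux_ub)
        new_reactions.append(fwd)
        new_reactions.append(rev)
        if r.id in out.exchanges:
            out.exchanges.add(rev_id)
    out.reactions = new_reactions
    return out


def ln_bounds(met: Metabolite) -> tuple[float, float]:
    """Natural-log concentration bounds of a metabolite (mol/L)."""
    return (math.log(met.conc_lb), math.log(met.conc_ub))
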