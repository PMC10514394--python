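"""Read/write models, parameter tables, configs and merge specs.

The network itself travels as a community (BiGG-style) JSON model file,
read and written through cobrapy so genome-scale reconstructions load
unchanged.  The thermodynamic/kinetic parameter layer is not part of that
dialect and lives in a tab-separated sidecar table with the header::

    reaction_id  dG0_kJ_mol  dG0_sd  kcat_per_MW_h_per_kDa  genes

Concentration bounds, boundary flags and curation statuses round-trip via
the JSON ``notes`` fields, so ``load_model(save_model(m))`` is the
identity on every field of the data model.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import pandas as pd
import yaml

from .model import CompartModel, Metabolite, Reaction, ThermoConfig, validate_model

__all__ = [
    "load_model",
    "save_model",
    "load_thermo_config",
    "save_thermo_config",
    "load_merge_specs",
    "ModelIOError",
]

PARAM_COLUMNS = ["reaction_id", "dG0_kJ_mol", "dG0_sd", "kcat_per_MW_h_per_kDa", "genes"]


class ModelIOError(ValueError):
    """Raised for malformed model or parameter files."""


def _default_params_path(model_path) -> Path:
    p = Path(model_path)
    return p.with_suffix(".params.tsv")


def load_model(
    model_path,
    params_path=None,
    thermo_config: ThermoConfig | None = None,
) -> CompartModel:
    """Load a BiGG-style JSON model plus an optional parameter table.

    Metabolites receive default or special concentration bounds from
    ``thermo_config`` unless the file carries explicit bounds in its
    notes.  Reactions lacking a dG0 entry are thermodynamically exempt;
    reactions lacking an efficiency are enzyme-exempt.
    """
    import cobra.io

    if not os.path.exists(model_path):
        raise FileNotFoundError(f"model file not found: {model_path}")
    config = thermo_config or ThermoConfig()
    try:
        cm = cobra.io.load_json_model(str(model_path))
    except Exception as exc:  # cobra raises various things on bad files
        raise ModelIOError(f"cannot parse model file {model_path}: {exc}") from exc

    metabolites = []
    for m in cm.metabolites:
        notes = m.notes or {}
        boundary = bool(notes.get("boundary", m.compartment == "e"))
        lb, ub = config.bounds_for(m.id)
        metabolites.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                conc_lb=float(notes.get("conc_lb", lb)),
                conc_ub=float(notes.get("conc_ub", ub)),
                is_boundary=boundary,
            )
        )

    reactions = []
    exchanges: set = set()
    boundary_rxns = {r.id for r in cm.boundary}
    for r in cm.reactions:
        notes = r.notes or {}
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxn = Reaction(
            id=r.id,
            stoich=stoich,
            reversible=r.lower_bound < 0,
            flux_lb=float(r.lower_bound),
            flux_ub=float(r.upper_bound),
            genes=frozenset(g.id for g in r.genes),
            gene_rule=r.gene_reaction_rule or "",
            status=notes.get("status", "keep"),
        )
        reactions.append(rxn)
        if bool(notes.get("exchange", r.id in boundary_rxns)):
            exchanges.add(r.id)

    model_notes = getattr(cm, "notes", None) or {}
    model = CompartModel(
        metabolites=metabolites,
        reactions=reactions,
        exchanges=exchanges,
        total_enzyme_bound=float(model_notes.get("total_enzyme_bound", 0.13)),
        provenance=str(model_notes.get("provenance", "")),
    )

    if params_path is None and _default_params_path(model_path).exists():
        params_path = _default_params_path(model_path)
    if params_path is not None:
        _apply_params(model, params_path)

    findings = validate_model(model)
    if findings:
        raise ModelIOError(
            f"model {model_path} failed validation: " + "; ".join(findings)
        )
    return model


def _apply_params(model: CompartModel, params_path) -> None:
    if not os.path.exists(params_path):
        raise FileNotFoundError(f"parameter file not found: {params_path}")
    try:
        df = pd.read_csv(params_path, sep="\t", dtype={"reaction_id": str, "genes": str})
    except Exception as exc:
        raise ModelIOError(f"cannot parse parameter table {params_path}: {exc}") from exc
    missing = [c for c in PARAM_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ModelIOError(
            f"parameter table {params_path} lacks required column(s) {missing}"
        )
    by_id = {r.id: r for r in model.reactions}
    for row_no, row in df.iterrows():
        rid = row["reaction_id"]
        rxn = by_id.get(rid)
        if rxn is None:
            raise ModelIOError(
                f"parameter table row {row_no}: unknown reaction {rid!r}"
            )
        for col, attr in [
            ("dG0_kJ_mol", "dG0"),
            ("dG0_sd", "dG0_uncertainty"),
            ("kcat_per_MW_h_per_kDa", "efficiency"),
        ]:
            if col not in df.columns:
                continue
            val = row[col]
            if pd.isna(val) or (isinstance(val, str) and val.strip() in ("", "/")):
                continue
            try:
                setattr(rxn, attr, float(val))
            except (TypeError, ValueError) as exc:
                raise ModelIOError(
                    f"parameter table row {row_no}, column {col}: "
                    f"non-numeric value {val!r} for reaction {rid}"
                ) from exc
        if "genes" in df.columns and isinstance(row.get("genes"), str) and row["genes"].strip():
            extra = {g.strip() for g in row["genes"].replace(";", ",").split(",") if g.strip()}
            rxn.genes = frozenset(rxn.genes | extra)


def save_model(model: CompartModel, model_path, params_path=None) -> None:
    """Write the model as BiGG-style JSON plus a parameter TSV sidecar.

    ``load_model(save_model(m))`` reproduces ``m`` field-for-field.
    """
    import cobra
    import cobra.io

    cm = cobra.Model("mdflux_model")
    cmets = {}
    for m in model.metabolites:
        suffix = m.id.rsplit("_", 1)[-1] if "_" in m.id else "c"
        compartment = suffix if suffix in ("c", "e", "p") else "c"
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=compartment)
        cmet.notes = {"conc_lb": m.conc_lb, "conc_ub": m.conc_ub, "boundary": m.is_boundary}
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.flux_lb, upper_bound=r.flux_ub)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[m]: c for m, c in r.stoich.items()})
        if r.gene_rule:
            # the flat gene set travels via the params TSV; only an explicit
            # boolean rule is stored on the reaction itself
            cr.gene_reaction_rule = r.gene_rule
        cr.notes = {"status": r.status, "exchange": r.id in model.exchanges}
    cm.notes = {
        "total_enzyme_bound": model.total_enzyme_bound,
        "provenance": model.provenance,
    }
    cobra.io.save_json_model(cm, str(model_path))

    if params_path is None:
        params_path = _default_params_path(model_path)
    rows = []
    for r in model.reactions:
        if r.dG0 is None and r.efficiency is None and not r.genes:
            continue
        rows.append(
            {
                "reaction_id": r.id,
                "dG0_kJ_mol": "" if r.dG0 is None else r.dG0,
                "dG0_sd": "" if r.dG0_uncertainty is None else r.dG0_uncertainty,
                "kcat_per_MW_h_per_kDa": "" if r.efficiency is None else r.efficiency,
                "genes": ";".join(sorted(r.genes)),
            }
        )
    pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(params_path, sep="\t", index=False)


# -- ThermoConfig YAML -------------------------------------------------------


def save_thermo_config(config: ThermoConfig, path) -> None:
    data = {
        "RT": config.RT,
        "default_conc_lb": config.default_conc_lb,
        "default_conc_ub": config.default_conc_ub,
        "special_bounds": {k: list(v) for k, v in config.special_bounds.items()},
        "ratio_constraints": [list(rc) for rc in config.ratio_constraints],
        "bigM": config.bigM,
        "mdf_tol": config.mdf_tol,
        "flux_tol": config.flux_tol,
        "flux_cap": config.flux_cap,
        "var_tol": config.var_tol,
        "key_tol": config.key_tol,
        "bind_tol": config.bind_tol,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_thermo_config(path) -> ThermoConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    config = ThermoConfig()
    for key, val in data.items():
        if not hasattr(config, key):
            raise ModelIOError(f"unknown ThermoConfig field {key!r} in {path}")
        if key == "special_bounds":
            val = {k: tuple(v) for k, v in val.items()}
        elif key == "ratio_constraints":
            val = [tuple(rc) for rc in val]
        setattr(config, key, val)
    if not config.RT > 0:
        raise ModelIOError("RT must be positive")
    for met_a, met_b, rlb, rub in config.ratio_constraints:
        if not (rlb > 0 and rub >= rlb):
            raise ModelIOError(
                f"ratio constraint ({met_a}, {met_b}): bounds must be positive with lb <= ub"
            )
    return config


def load_merge_specs(path) -> list:
    """Load a YAML batch of merge specifications (see merge.MergeSpec)."""
    from .merge import MergeSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    specs = []
    for entry in raw:
        specs.append(
            MergeSpec(
                merged_id=entry["merged_id"],
                parts=[(p["id"], int(p.get("multiplier", 1))) for p in entry["parts"]],
                declared_intermediates=set(entry.get("declared_intermediates", []) or [])
                or None,
                dG0_override=entry.get("dG0_override"),
                reversible_pair=bool(entry.get("reversible_pair", False)),
            )
        )
    return specs
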