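#!/usr/bin/env python
"""Structural redundancy scan on a tryptophan-synthesis-like fragment.

A hand-built fragment (synthetic stand-in for the relevant corner of a
genome-scale E. coli reconstruction) demonstrates the three redundancy
flags: an oxidase whose N-methylated substrate has no producer
(orphan-substrate), a reversible dehydrogenase pair whose stereoisomer
substrate is otherwise isolated (both directions flagged), and blocked
reactions found by flux variability.  The shared-gene scan also lists
merge candidates for manual review.
"""

from pathlib import Path

import pandas as pd

from mdflux.merge import find_redundant_reactions, shared_gene_merge_hints
from mdflux.model import CompartModel, Metabolite, Reaction, split_reversible

OUT = Path(__file__).resolve().parents[1] / "results" / "redundancy"


def _met(mid, boundary=False):
    return Metabolite(id=mid, conc_lb=1e-6, conc_ub=1e-2, is_boundary=boundary)


def trp_fragment() -> CompartModel:
    mets = [
        _met("3ig3p_c"), _met("ser__L_c"), _met("g3p_c"), _met("h2o_c"),
        _met("trp__L_c"), _met("indole_c"), _met("nmtrp_c"), _met("fald_c"),
        _met("h2o2_c"), _met("o2_c"), _met("r2hglut_c"), _met("akg_c"),
        _met("nadh_c"), _met("nad_c"),
    ]
    rxns = [
        Reaction("TRPS3", {"3ig3p_c": -1.0, "g3p_c": 1.0, "indole_c": 1.0},
                 genes=frozenset({"b1260", "b1261"})),
        Reaction("TRPS2", {"indole_c": -1.0, "ser__L_c": -1.0,
                           "h2o_c": 1.0, "trp__L_c": 1.0},
                 dG0=-49.7, genes=frozenset({"b1260", "b1261"})),
        Reaction("MTRPOXN", {"nmtrp_c": -1.0, "h2o_c": -1.0, "o2_c": -1.0,
                             "fald_c": 1.0, "h2o2_c": 1.0, "trp__L_c": 1.0},
                 dG0=-44.6, genes=frozenset({"b1059"})),
        Reaction("ARHGDx", {"akg_c": -1.0, "nadh_c": -1.0,
                            "r2hglut_c": 1.0, "nad_c": 1.0},
                 reversible=True, flux_lb=-1000.0, genes=frozenset({"b2913"})),
    ]
    return CompartModel(metabolites=mets, reactions=rxns)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    model = split_reversible(trp_fragment())
    flags = find_redundant_reactions(model)
    for rid, reason in flags:
        print(f"redundant: {rid} ({reason})")
    pd.DataFrame(flags, columns=["reaction", "reason"]).to_csv(
        OUT / "redundant_reactions.tsv", sep="\t", index=False
    )
    hints = shared_gene_merge_hints(model)
    for a, b, genes in hints:
        print(f"merge candidate: {a} + {b} share genes {genes}")
    pd.DataFrame(
        [{"reaction_a": a, "reaction_b": b, "shared_genes": ";".join(g)}
         for a, b, g in hints]
    ).to_csv(OUT / "merge_hints.tsv", sep="\t", index=False)
    print(f"wrote redundancy tables to {OUT}")


if __name__ == "__main__":
    main()
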