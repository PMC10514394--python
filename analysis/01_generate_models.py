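#!/usr/bin/env python
"""Generate the synthetic study networks and save them under results/models/.

Four families: the canonical two-step chains (one distributed and one
localized thermodynamic bottleneck), the coupled-enzyme motif (an
unfavorable and a favorable reaction sharing a gene and a redox cofactor
pair), the two-route branched network, and a seeded random corpus
sample.  All are deterministic and validate cleanly.
"""

from pathlib import Path

from mdflux.generate import (
    GeneratorConfig,
    gen_branched_network,
    gen_coupled_motif,
    gen_linear_chain,
    gen_random_model,
)
from mdflux.io import save_model, save_thermo_config
from mdflux.model import validate_model

OUT = Path(__file__).resolve().parents[1] / "results" / "models"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    gcfg = GeneratorConfig()
    models = {
        "chain_distributed": gen_linear_chain(gcfg, [-5.0, 10.0]),
        "chain_localized": gen_linear_chain(gcfg, [-30.0, 30.0]),
        "coupled_motif": gen_coupled_motif(gcfg),
        "branched": gen_branched_network(gcfg),
        "random_seed1": gen_random_model(GeneratorConfig(seed=1, n_reactions=6)),
    }
    for name, (model, thermo) in models.items():
        findings = validate_model(model)
        assert findings == [], findings
        save_model(model, OUT / f"{name}.json")
        save_thermo_config(thermo, OUT / f"{name}.thermo.yaml")
        print(
            f"{name}: {len(model.reactions)} reactions, "
            f"{len(model.metabolites)} metabolites, 0 validation findings"
        )
    print(f"wrote model/parameter/config files to {OUT}")


if __name__ == "__main__":
    main()
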