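"""Generate an example insulin dose-response plate experiment.

Writes the per-cell table, the well-condition map and the ground-truth
sidecar under results/, in the formats every downstream step consumes.
"""

import json
from pathlib import Path

from traffiq import design as design_mod
from traffiq import pipelines as P
from traffiq.synthetic_data import preset, simulate_plate

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    # a small demonstration plate; the fitting scripts regenerate their own
    # full-size data (~500 cells/well) at run time
    import dataclasses
    cfg = dataclasses.replace(preset("fig1e", seed=seed), n_plates=1,
                              cells_per_well=25)
    design = design_mod.make_dose_design(P.FIG1E_DOSES_NM,
                                         n_plates=cfg.n_plates)
    cells, truth = simulate_plate(cfg, design)
    OUT.mkdir(exist_ok=True)
    cells.to_csv(OUT / "example_cells.tsv", sep="\t", index=False)
    design.to_csv(OUT / "example_design.tsv", sep="\t", index=False)
    (OUT / "example_truth.json").write_text(json.dumps({
        "wells": truth.wells.to_dict(orient="records"),
        "plates": truth.plates.to_dict(orient="records"),
        "n_adipocytes": int(truth.is_adipocyte.sum()),
        "n_cells": int(len(cells)),
    }, indent=2))
    print(f"simulated {len(cells)} cells over {cfg.n_plates} plates, "
          f"{truth.is_adipocyte.mean():.0%} adipocytes; "
          f"tables in {OUT}")


if __name__ == "__main__":
    main()
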