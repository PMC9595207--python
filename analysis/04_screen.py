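"""siRNA knockdown screen summarization and the cross-cell-line regression
of knockdown effects (does a second line reproduce line A's effect sizes?).
"""

import json
from pathlib import Path

from traffiq import pipelines as P

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 9) -> None:
    summary, _ = P.run_screen(seed)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "screen_summary.tsv", sep="\t", index=False)
    g4 = summary[(summary["readout"] == "glut4")
                 & (summary["insulin_nM"] == 100.0)]
    print("surface GLUT4 at 100 nM insulin, fold over non-targeting control:")
    print(g4[["sirna", "mean", "sd", "n_wells", "foc", "p_adj"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    res = P.run_crossline_slope(seed + 1, shrink=0.5)
    (OUT / "crossline_regression.json").write_text(json.dumps(res, indent=2))
    print(f"\ncross-line regression (true shrinkage 0.5): "
          f"slope={res['slope']:.3f}, r2={res['r2']:.3f}, p={res['p_value']:.2g}")


if __name__ == "__main__":
    main()
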