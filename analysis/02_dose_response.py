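"""Dose-response analyses: insulin EC50, kinase-inhibitor IC50s and
insulin-resistance model IC50s, all through the full gate/normalize/fit
pipeline on synthetic plates.
"""

from pathlib import Path

import pandas as pd

from traffiq import pipelines as P

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    rows = []
    fit, _ = P.run_insulin_dose_response(seed=seed)
    rows.append(dict(analysis="insulin stimulation", parameter="EC50 (nM)",
                     value=fit.params["ec50"], se=fit.se["ec50"]))
    for inhibitor in ("GDC0941", "MK2206"):
        fit, _ = P.run_inhibitor_dose_response(seed + 1, inhibitor)
        rows.append(dict(analysis=f"{inhibitor} inhibition",
                         parameter="IC50 (nM)",
                         value=fit.params["ic50"], se=fit.se["ic50"]))
    for which, unit in (("fig2c", "nM"), ("fig2e", "ng/ml")):
        agent = {"fig2c": "chronic insulin", "fig2e": "TNF"}[which]
        fit, _ = P.run_resistance_dose_response(seed + 7, which)
        rows.append(dict(analysis=f"{agent} resistance model",
                         parameter=f"IC50 ({unit})",
                         value=fit.params["ic50"], se=fit.se["ic50"]))
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "dose_response.tsv", sep="\t", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
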