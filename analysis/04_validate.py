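#!/usr/bin/env python
"""Validate the predicted breeding values against the simulated truth.

For each EBV table written by 03_predict_ebv.py: accuracy (correlation of
EBV with TBV on the validation generation, separately for direct, maternal
and total effects), dispersion slope (whole-data EBV regressed on
reference-data EBV) and realized selection differentials (mean TBV of the
top 1% / 30% on total EBV).
"""

import argparse
import re
from pathlib import Path

import pandas as pd

from pigsurv import io
from pigsurv.evaluation import (
    accuracy,
    dispersion_regression,
    selection_differential,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", default="results/sim")
    ap.add_argument("--ebv", default="results/ebv")
    ap.add_argument("--validation-generation", type=int, default=8)
    ap.add_argument("--out", default="results/validation.csv")
    args = ap.parse_args()

    ph = io.read_phenotypes(Path(args.sim) / "phenotypes.csv")
    val = ph[ph["generation"] == args.validation_generation].set_index("id")

    rows = []
    for path in sorted(Path(args.ebv).glob("ebv_*.csv")):
        scenario, model = re.match(r"ebv_(.+)_([A-Z]+)$", path.stem).groups()
        ebv = pd.read_csv(path).set_index("id").loc[val.index]
        sel1 = selection_differential(
            ebv["ebv_total"], val[["tbv_a", "tbv_m"]], 0.01
        )
        sel30 = selection_differential(
            ebv["ebv_total"], val[["tbv_a", "tbv_m"]], 0.30
        )
        rows.append(
            dict(
                scenario=scenario, model=model,
                acc_a=accuracy(ebv["ebv_a"], val["tbv_a"]),
                acc_m=accuracy(ebv["ebv_m"], val["tbv_m"]),
                acc_t=accuracy(ebv["ebv_total"], val["tbv_a"] + val["tbv_m"]),
                slope_a=dispersion_regression(ebv["ebv_a_whole"], ebv["ebv_a"]),
                slope_m=dispersion_regression(ebv["ebv_m_whole"], ebv["ebv_m"]),
                slope_t=dispersion_regression(
                    ebv["ebv_a_whole"] + ebv["ebv_m_whole"], ebv["ebv_total"]
                ),
                top1_t=sel1["total"], top30_t=sel30["total"],
            )
        )
    table = pd.DataFrame(rows)
    print(table.round(3).to_string(index=False))
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
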