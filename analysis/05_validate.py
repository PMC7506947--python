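#!/usr/bin/env python
"""Cross-validate all four models and assess calibration.

10-fold cross-validation: per-fold R^2 and MAE (mean and SD across folds),
pooled out-of-fold calibration slope and mean calibration, plus one
calibration plot per model. Writes results/performance.csv and
results/calibration_<model>.png.
"""

import argparse
from pathlib import Path

import pandas as pd

from throwspeed import cross_validate
from throwspeed.models import MODEL_NAMES
from throwspeed.validation import render_calibration_plot, report_table


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--k", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = pd.read_csv(args.features)
    reports = {}
    for name in MODEL_NAMES:
        reports[name] = cross_validate(rows, name, k=args.k, seed=args.seed)
        render_calibration_plot(reports[name], args.out / f"calibration_{name}.png")

    args.out.mkdir(parents=True, exist_ok=True)
    table = report_table(reports)
    table.to_csv(args.out / "performance.csv", index_label="measure")

    print(f"{args.k}-fold cross-validation of {len(rows)} throws (seed {args.seed})")
    print(table.to_string())
    print(
        "\nAll models should show slope ~1.00 and mean calibration ~0.0; "
        "the Full model's MAE ~1.30 m/s and R^2 ~0.86 follow from the "
        "generator's residual SD (1.63 m/s) against the overall speed SD "
        "(~4.36 m/s)."
    )
    print(f"calibration plots -> {args.out}/calibration_<model>.png")


if __name__ == "__main__":
    main()
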