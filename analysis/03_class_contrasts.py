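"""Compare the two training classes variable by variable.

For each of the eight weather variables, tests whether the invasive
class's values at its collection sites differ from the pooled natives'
(unpaired two-sided Wilcoxon-Mann-Whitney), writes the test table to
results/contrasts.csv and, with --plot, violin plots of the class
distributions to results/figures/class_contrasts.png.
"""

import argparse
from pathlib import Path

import pandas as pd

from nichecontrast import contrast_table, read_feature_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path,
                        default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/contrasts.csv"))
    parser.add_argument("--plot", action="store_true")
    args = parser.parse_args()

    table = read_feature_table(args.features)
    train = table.subset(table.data["year"].between(2011, 2014).to_numpy())

    rows = []
    for res in contrast_table(train):
        rows.append({
            "variable": res["variable"], "U": res["U"],
            "p_value": res["p_value"], "method": res["method"],
            "invasive_median": res["classes"]["invasive"]["median"],
            "native_median": res["classes"]["native"]["median"],
        })
        print(f"{res['variable']}: invasive median "
              f"{rows[-1]['invasive_median']:.2f} vs native "
              f"{rows[-1]['native_median']:.2f}, p = {res['p_value']:.2e}")
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out, index=False)
    worst = frame["p_value"].max()
    print(f"largest p-value across the eight variables: {worst:.2e} "
          f"({'<' if worst < 0.02 else '>='} 0.02)")
    print(f"contrast table -> {args.out}")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 4, figsize=(14, 6))
        for ax, var in zip(axes.ravel(), train.variables):
            groups = [train.data.loc[train.data["label"] == lbl, var]
                      for lbl in ("invasive", "native")]
            ax.violinplot(groups, showmedians=True)
            ax.set_xticks([1, 2], ["invasive", "native"])
            ax.set_title(var)
        fig.tight_layout()
        out = Path("results/figures/class_contrasts.png")
        out.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out, dpi=120)
        print(f"violin plots -> {out}")


if __name__ == "__main__":
    main()
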