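"""Train the contrast-class separator and validate on the hold-out year.

Caps every species at 1000 rows, trains the calibrated RBF separator on
the 2011-2014 feature rows with the reference hyper-parameters
(gamma 0.0005, C 1.0, tolerance 1e-10), evaluates the 2015 hold-out
(confusion matrix, per-class and weighted precision/recall/f1, predicted
probabilities at the invasive presences), and writes the model bundle and
a validation report under results/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from nichecontrast import (TrainingConfig, build_training_set,
                           evaluate_labels, probability_summary,
                           read_feature_table, save_model, train)
from nichecontrast.evaluation import round_half_up


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path,
                        default=Path("results/features.csv"))
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = read_feature_table(args.features)
    train_tab = table.subset(table.data["year"].between(2011, 2014).to_numpy())
    test_tab = table.subset((table.data["year"] == 2015).to_numpy())

    config = TrainingConfig(subsample_seed=args.seed)
    capped = build_training_set(train_tab, config=config)
    print(f"training rows per species (cap {config.per_species_cap}): "
          f"{capped.species_counts()}")
    model = train(capped, config)
    save_model(model, args.out / "model.joblib")

    predicted = model.predict_class(test_tab)
    ev = evaluate_labels(test_tab.data["label"], predicted)
    cm = ev["confusion"]
    print(f"2015 hold-out confusion (invasive positive): "
          f"TP={cm.TP} FN={cm.FN} FP={cm.FP} TN={cm.TN}")
    print(f"{'class':<10} {'precision':>9} {'recall':>7} {'f1':>6} {'n':>5}")
    for name in ("invasive", "native", "weighted"):
        m = ev[name]
        n = m.n if hasattr(m, "n") else m.n_invasive + m.n_native
        print(f"{name:<10} {round_half_up(m.precision):>9.2f} "
              f"{round_half_up(m.recall):>7.2f} "
              f"{round_half_up(m.f1):>6.2f} {n:>5}")

    invasive_rows = test_tab.subset(
        (test_tab.data["label"] == "invasive").to_numpy())
    summary = probability_summary(model, invasive_rows)
    print(f"hold-out invasive presences (n={summary.n}): probability median "
          f"{summary.median:.2f}, IQR [{summary.q1:.2f}, {summary.q3:.2f}]")

    report = {
        "confusion": dataclasses.asdict(cm),
        "metrics": {k: dataclasses.asdict(ev[k])
                    for k in ("invasive", "native", "weighted")},
        "probability_summary": dataclasses.asdict(summary),
        "training_counts": capped.species_counts(),
        "seed": args.seed,
    }
    with open(args.out / "validation.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"model -> {args.out / 'model.joblib'}; "
          f"report -> {args.out / 'validation.json'}")


if __name__ == "__main__":
    main()
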