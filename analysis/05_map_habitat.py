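"""Map habitat suitability across the whole virtual country.

Applies the trained model to every grid cell of (a) the hold-out year's
weather and (b) the 2011-2015 average weather layers ("colonisation
potential"), writes both probability rasters as ESRI ASCII grids under
results/maps/, and prints the area share of each 20 %-probability class.
"""

import argparse
from pathlib import Path

import numpy as np

from nichecontrast import (classify_raster, load_model, predict_average_map,
                           predict_raster, read_stacks, write_ascii_grid)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", type=Path,
                        default=Path("results/model.joblib"))
    parser.add_argument("--world", type=Path, default=Path("results/world"))
    parser.add_argument("--out", type=Path, default=Path("results/maps"))
    args = parser.parse_args()

    model = load_model(args.model)
    stacks = read_stacks(args.world / "grids" / "manifest.yaml")
    args.out.mkdir(parents=True, exist_ok=True)

    rasters = {
        "probability_2015": predict_raster(model, stacks["2015"]),
        "colonisation_potential_2011_2015": predict_average_map(
            model, [stacks[k] for k in sorted(stacks)]),
    }
    for name, raster in rasters.items():
        write_ascii_grid(args.out / f"{name}.asc", raster.values,
                         raster.geometry)
        cats, labels = classify_raster(raster)
        valid = cats >= 0
        print(f"{name} ({raster.label}):")
        for code, label in enumerate(labels):
            share = 100 * np.mean(cats[valid] == code)
            print(f"  {label:>8}: {share:5.1f}% of cells")
    print(f"rasters -> {args.out}")


if __name__ == "__main__":
    main()
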