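"""Join occurrence points with their collection-year weather values.

Reads the per-species occurrence tables and the gridded weather layers
written by 01_simulate_world.py, looks up each point's grid cell in the
stack of its own collection year, labels rows invasive vs. native, and
writes the joined feature table to results/features.csv.
"""

import argparse
from pathlib import Path

from nichecontrast import (CANONICAL_VARIABLES, attach_features,
                           read_occurrences, read_stacks,
                           write_feature_table)
from nichecontrast.synthetic_world import species_role_map


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--world", type=Path, default=Path("results/world"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/features.csv"))
    args = parser.parse_args()

    manifest = args.world / "grids" / "manifest.yaml"
    if not manifest.exists():
        raise SystemExit(f"{manifest} not found - run 01_simulate_world.py "
                         "first")
    stacks = {int(lbl): s for lbl, s in read_stacks(manifest).items()}
    roles = species_role_map()
    records = []
    for path in sorted(args.world.glob("occurrences_*.csv")):
        species = path.stem.removeprefix("occurrences_")
        records.extend(read_occurrences(path, roles, species_id=species))

    table = attach_features(records, stacks, CANONICAL_VARIABLES, roles)
    write_feature_table(table, args.out)
    print(f"joined {len(table)} of {len(records)} records "
          f"({table.n_excluded_outside} outside extent, "
          f"{table.n_excluded_nodata} on nodata cells)")
    print(f"class counts: {table.class_counts()}")
    print(f"feature table -> {args.out}")


if __name__ == "__main__":
    main()
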