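#!/usr/bin/env python
"""Classify every environment into the nine drought TPE classes and check
the classification against the grid's designed regimes."""

from pathlib import Path

from ricetpe import io as tpio
from ricetpe.pipeline import best_seasons_and_slices
from ricetpe.tpe import class_proportions, classify_grid

OUT = Path("results/analysis")


def main() -> None:
    cubes = tpio.read_gei_long(OUT / "gei_long.csv")
    _, slices = best_seasons_and_slices(cubes)
    table = classify_grid(slices)

    coords = tpio.read_environments_csv(OUT / "environments.csv")
    tpio.write_classification(table, coords, OUT / "classification.csv")
    tpio.classification_geojson(
        table.merge(coords[["env_id", "lon", "lat"]], on="env_id"), OUT / "classification.geojson"
    )
    props = class_proportions(table)
    props.rename_axis("label").reset_index().to_csv(OUT / "class_proportions.csv", index=False)

    print("TPE class proportions:")
    print(props.round(3).to_string())
    merged = table.merge(coords[["env_id", "true_label"]], on="env_id")
    acc = (merged["label"] == merged["true_label"]).mean()
    print(f"designed-regime recovery: {100 * acc:.1f}% of {len(merged)} environments")


if __name__ == "__main__":
    main()
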