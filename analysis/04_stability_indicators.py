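#!/usr/bin/env python
"""Compute the five stability indicators per variety, over all environments
and per TPE scope (class, pooled severity, pooled timing)."""

from pathlib import Path

from ricetpe import io as tpio
from ricetpe.pipeline import best_seasons_and_slices
from ricetpe.stability import indicator_table
from ricetpe.synthetic import ARCHETYPE_LABELS

OUT = Path("results/analysis")


def main() -> None:
    cubes = tpio.read_gei_long(OUT / "gei_long.csv")
    _, slices = best_seasons_and_slices(cubes)
    cls = tpio.read_classification(OUT / "classification.csv")
    env_labels = dict(zip(cls["env_id"], cls["label"]))

    scopes = ["ALL", "S", "M", "L", "1", "2", "3", *ARCHETYPE_LABELS]
    table = indicator_table(slices, env_labels, scopes)
    tpio.write_indicators(table, OUT / "indicators.csv")

    overall = table[table["scope"] == "ALL"].set_index("variety")
    print("indicators over all environments (gamma t/ha; delta/lambda/phi/psi dimensionless):")
    print(overall[["gamma", "delta", "lambda", "phi", "psi"]].round(3).to_string())
    best = overall["gamma"].idxmax()
    print(f"\nhighest mean rainfed yield: {best} ({overall.loc[best, 'gamma']:.2f} t/ha)")


if __name__ == "__main__":
    main()
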