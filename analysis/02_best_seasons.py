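#!/usr/bin/env python
"""Clean unsuitable sowing dates and select each environment's best rainfed
season (smallest yield CV among the three highest mean rainfed yields)."""

from pathlib import Path

import pandas as pd

from ricetpe import io as tpio
from ricetpe.pipeline import best_seasons_and_slices

OUT = Path("results/analysis")


def main() -> None:
    cubes = tpio.read_gei_long(OUT / "gei_long.csv")
    best, _ = best_seasons_and_slices(cubes)
    tpio.write_best_seasons(best, OUT / "best_seasons.csv")

    df = pd.read_csv(OUT / "best_seasons.csv")
    print(f"best season selected for {len(df)} environments")
    print("selected sowing dates (day of year):")
    print(df["sowing_doy"].value_counts().to_string())
    print(f"mean best-season rainfed yield {df['ry'].mean():.2f} t/ha, mean CV {df['cv'].mean():.3f}")


if __name__ == "__main__":
    main()
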