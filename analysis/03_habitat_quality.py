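"""Habitat-quality surfaces and their six-level classification.

Reads the scenario's quality rasters, tabulates the area of each quality
level per date, and reports the mean habitat quality trajectory.
"""

from pathlib import Path

import pandas as pd

from habscape.quality import classify_hq, mean_hq
from habscape.raster import read_raster

ROOT = Path(__file__).resolve().parent.parent / "results"
SCENARIO = ROOT / "scenario"


def main() -> None:
    tables = []
    print("mean habitat quality and level shares by date:")
    for year in (1991, 2021, 2051):
        Q = read_raster(SCENARIO / f"quality_{year}.tif")
        _, table = classify_hq(Q)
        table.insert(0, "year", year)
        tables.append(table)
        total = table["area_ha"].sum()
        good = table[table["class"].isin(["Relatively good", "Good"])][
            "area_ha"].sum()
        poor = table[table["class"].isin(["No habitat", "Poor"])]["area_ha"].sum()
        print(f"  {year}: mean HQ {mean_hq(Q):.4f}; "
              f"good share {good / total:.1%}, poor share {poor / total:.1%}")
    pd.concat(tables, ignore_index=True).to_csv(
        ROOT / "hq_class_areas.csv", index=False
    )
    print(f"\nsix-level area table written to {ROOT / 'hq_class_areas.csv'}")


if __name__ == "__main__":
    main()
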