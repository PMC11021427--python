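"""Landscape-level pattern metrics across the three dates.

Computes NP, PD, SHDI and CONTAG for each dated land-cover map and
reports the fragmentation trend: under the habitat-to-agriculture
conversion regime the landscape gains patches and diversity while
losing contagion.
"""

from pathlib import Path

import pandas as pd

from habscape.metrics import metrics_report
from habscape.raster import read_raster

ROOT = Path(__file__).resolve().parent.parent / "results"
SCENARIO = ROOT / "scenario"


def main() -> None:
    rows = []
    for year in (1991, 2021, 2051):
        lc = read_raster(SCENARIO / f"landcover_{year}.tif")
        rows.append({"year": year, **metrics_report(lc).as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "landscape_metrics.csv", index=False)
    print(df.to_string(index=False))
    trend_up = df["NP"].is_monotonic_increasing
    trend_down = df["CONTAG"].is_monotonic_decreasing
    print(f"\nNP rising across dates: {trend_up}; CONTAG falling: {trend_down}")


if __name__ == "__main__":
    main()
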