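"""Habitat accounting and centroid migration between climate scenarios.

Reclassifies the current and warmed consensus suitability grids into the
four suitability classes, reports latitude-corrected class areas, maps
gain/loss/stable change, and measures the centroid displacement of the
potential distribution as a great-circle vector.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hydrotherm import dynamics
from hydrotherm.grids import Raster, read_ascii_grid, write_ascii_grid

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "dynamics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    current = read_ascii_grid(BASE / "sdm" / "suitability_current.asc")
    warmed = read_ascii_grid(BASE / "sdm" / "suitability_warmed.asc")

    rows = []
    for name, grid in [("current", current), ("warmed", warmed)]:
        classes = dynamics.classify_suitability(grid)
        for label, area in classes.areas_1e4_km2.items():
            rows.append({"scenario": name, "class": label,
                         "area_1e4_km2": round(area, 2)})
        print(f"{name}: potential distribution "
              f"{classes.total_potential_1e4_km2:.2f} ×10⁴ km² "
              f"({', '.join(f'{k} {v:.2f}' for k, v in classes.areas_1e4_km2.items())})")
    pd.DataFrame(rows).to_csv(OUT / "class_areas.csv", index=False)

    cm = dynamics.change_map(current, warmed)
    write_ascii_grid(OUT / "change_map.asc",
                     Raster(current.spec, cm.codes.astype(float), "change"))
    print("change areas (×10⁴ km²):",
          {k: round(v, 2) for k, v in cm.areas_1e4_km2.items()})

    c_cur = dynamics.centroid(current)
    c_fut = dynamics.centroid(warmed)
    vec = dynamics.migration_vector(c_cur, c_fut)
    print(f"centroid {c_cur[0]:.3f}E {c_cur[1]:.3f}N -> "
          f"{c_fut[0]:.3f}E {c_fut[1]:.3f}N: {vec.distance_km:.2f} km "
          f"toward {vec.cardinal} (bearing {vec.bearing_deg:.1f}°)")
    (OUT / "centroid_migration.json").write_text(json.dumps({
        "from": c_cur, "to": c_fut,
        "distance_km": round(vec.distance_km, 2),
        "bearing_deg": round(vec.bearing_deg, 1),
        "cardinal": vec.cardinal,
    }, indent=2))


if __name__ == "__main__":
    main()
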