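"""Generate the synthetic study region used by the downstream analyses.

Builds a seeded mid-latitude world (climate stations, DEM, analytic WI/CI/HI
ground truth) and two virtual Caragana-like species with known niche optima,
then writes stations and occurrences as CSV and the truth surfaces as ESRI
ASCII grids under results/synthetic/.
"""

from pathlib import Path

import numpy as np

from hydrotherm import synthetic_world as sw
from hydrotherm.grids import write_ascii_grid

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 42

# 10-arcminute cells keep the grids small enough to eyeball as text
WORLD = sw.WorldConfig(
    lon_min=95.0, lon_max=115.0, lat_min=35.0, lat_max=45.0,
    resolution_arcmin=10.0, n_stations=200, seed=SEED,
)

SPECIES = [
    # a warm-steppe species and a cold alpine-margin species
    sw.SpeciesSpec("V. campestris", wi_optimum=55.0, wi_tolerance=6.0,
                   hi_optimum=6.0, hi_tolerance=2.0, n_occurrences=300,
                   seed=SEED + 1),
    sw.SpeciesSpec("V. frigida", wi_optimum=30.0, wi_tolerance=5.0,
                   hi_optimum=12.0, hi_tolerance=4.0, n_occurrences=300,
                   seed=SEED + 2),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stations = sw.generate_station_network(WORLD)
    sw.stations_to_frame(stations).to_csv(OUT / "stations.csv", index=False)
    print(f"wrote {len(stations)} stations")

    dem = sw.generate_dem(WORLD)
    wi, ci, hi = sw.generate_true_index_surfaces(WORLD, dem)
    for layer in (dem, wi, ci, hi):
        write_ascii_grid(OUT / f"{layer.name}_true.asc", layer)
    print(f"true WI range {wi.values.min():.1f}..{wi.values.max():.1f} "
          f"°C·month on a {wi.spec.nrows}×{wi.spec.ncols} grid")

    frames = []
    for spec in SPECIES:
        occ = sw.generate_occurrences(spec, wi, hi)
        frames.append(occ)
        print(f"{spec.name}: {len(occ)} occurrences around "
              f"WI {spec.wi_optimum}, HI {spec.hi_optimum}")
    import pandas as pd

    pd.concat(frames).to_csv(OUT / "occurrences.csv", index=False)


if __name__ == "__main__":
    main()
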