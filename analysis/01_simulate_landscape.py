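#!/usr/bin/env python
"""Generate the study landscape and record its ground truth.

Builds the default synthetic scene — a 240 km square with 100 forest PAs
(10-600 km^2, 55-100% forest cover), baseline 12-year loss ~2% of forest,
and 5 injected PAs losing 20x the baseline — then writes the exact per-PA
truth table and the PA polygons under results/, and the full raster fixture
(land cover, AGB, BGB, fine loss) under scratch/fixture/ for inspection.
Downstream scripts regenerate the same scene from the seed instead of
re-reading the large rasters.
"""

from pathlib import Path

from pacarbon import SceneConfig, generate_scene, write_fixture
from pacarbon.io import write_pa_geojson

SEED = 42
RESULTS = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    cfg = SceneConfig(seed=SEED)
    scene, records, truth = generate_scene(cfg)

    RESULTS.mkdir(exist_ok=True)
    truth.to_csv(RESULTS / "scene_truth.csv", index=False)
    write_pa_geojson(records, RESULTS / "pa_polygons.geojson")
    write_fixture(scene, records, truth, SCRATCH / "fixture")

    inj = truth["outlier_injected"].sum()
    print(f"scene: {cfg.width} x {cfg.height} km, {cfg.n_pas} PAs, seed {SEED}")
    print(f"true total carbon stock : {truth['carbon_stock_mg'].sum() / 1e6:,.1f} Tg C")
    print(f"true total carbon loss  : {truth['carbon_loss_mg'].sum() / 1e6:,.2f} Tg C "
          f"over 12 yr")
    print(f"injected high-loss PAs  : {inj} "
          f"(loss x{cfg.outlier_multiplier:.0f} baseline)")
    print(f"wrote {RESULTS/'scene_truth.csv'}, {RESULTS/'pa_polygons.geojson'}, "
          f"and raster fixture under {SCRATCH/'fixture'}")


if __name__ == "__main__":
    main()
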