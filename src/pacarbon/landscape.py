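"""Synthetic tropical-landscape scenes with analytically known ground truth.

The generator emulates the four map layers a protected-area (PA) carbon
analysis consumes — a ~1 km categorical land-cover grid (forest classes 1-8,
non-forest 20), ~1 km above- and below-ground biomass (AGB/BGB) grids in
Mg ha^-1, and a fine (~30 m analog) binary forest-loss grid for a 12-year
window — together with PA polygons carrying WDPA-style attributes.

PAs are axis-aligned rectangles whose edges snap to the fine grid, so every
geometric quantity (recorded GIS area, forest area, loss area) is exact in
integer fine-cell units and the per-PA truth table is computed from the
construction itself, never through the analysis pipeline.  Forest is assigned
per PA by accumulating coarse cells (interior cells first) until a target
forest fraction of the PA's area is reached; loss is a per-PA proportion of
its forest fine cells drawn without replacement, with a configurable number
of injected high-loss "outlier" PAs.

The scene uses a planar equal-area frame in metres; it does not emulate
spatial autocorrelation of biomass, cloud/no-data gaps, or geographic
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .filters import IUCN_CATEGORIES, PARecord
from .grids import Grid, read_ascii_grid, write_ascii_grid
from .io import read_pa_geojson, write_pa_geojson

__all__ = ["SceneConfig", "Scene", "generate_scene", "write_fixture", "read_fixture"]

NONFOREST_CLASS = 20
FOREST_CLASSES = tuple(range(1, 9))

_COUNTRIES = (
    "Brazil", "Indonesia", "Cambodia", "Guatemala",
    "Honduras", "Mozambique", "Colombia", "Vietnam",
)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a 240 km x 240 km landscape holding 100 forest PAs of
    10-600 km^2 with 55-100% forest cover, a 12-year loss proportion drawn
    from a Beta distribution with mean 2% (matching the ~0.17% yr^-1 regime
    of tropical PAs), five injected PAs losing 20x the baseline, and tropical
    biomass levels (AGB ~ 250 +/- 75 Mg ha^-1, BGB = 0.28 AGB).
    """

    width: int = 240                      # coarse pixels
    height: int = 240
    coarse_pixel_size: float = 1000.0     # metres; the "1 km" grid
    subdivision: int = 32                 # fine cells per coarse cell per axis
    n_pas: int = 100
    pa_area_range_km2: tuple[float, float] = (10.0, 600.0)
    forest_fraction_range: tuple[float, float] = (0.55, 1.0)
    loss_mean: float = 0.02               # 12-year loss proportion of forest
    loss_concentration: float = 100.0     # Beta concentration (a+b)
    n_outliers: int = 5
    outlier_multiplier: float = 20.0
    agb_mean: float = 250.0               # Mg ha^-1
    agb_sd: float = 75.0
    bgb_ratio: float = 0.28
    background_forest_fraction: float = 0.2
    proposed_fraction: float = 0.1
    countries: tuple[str, ...] = _COUNTRIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subdivision < 1:
            raise ValueError("subdivision factor must be >= 1")
        if self.width < 1 or self.height < 1 or self.n_pas < 0:
            raise ValueError("scene dimensions and PA count must be positive")
        lo, hi = self.forest_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("forest fraction range must lie within [0, 1]")
        for name, p in (("loss_mean", self.loss_mean),
                        ("background_forest_fraction", self.background_forest_fraction),
                        ("proposed_fraction", self.proposed_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.pa_area_range_km2[0] <= 0:
            raise ValueError("PA areas must be positive")
        if self.n_outliers > self.n_pas:
            raise ValueError("cannot inject more outlier PAs than PAs")

    @property
    def fine_pixel_size(self) -> float:
        return self.coarse_pixel_size / self.subdivision


@dataclass
class Scene:
    """The aligned stack of synthetic raster layers on a common frame."""

    landcover: Grid   # coarse categorical, classes 1-8 forest / 20 non-forest
    agb: Grid         # coarse continuous, Mg ha^-1, 0 outside forest
    bgb: Grid         # coarse continuous, Mg ha^-1
    loss: Grid        # fine binary (0/1), 12-year loss
    config: SceneConfig = field(repr=False, default=None)  # type: ignore[assignment]


class PackingError(ValueError):
    """The requested PAs cannot be placed in the scene without overlap."""


def _place_rectangles(cfg: SceneConfig, rng: np.random.Generator) -> list[tuple[int, int, int, int]]:
    """Place non-overlapping PA rectangles, in integer fine-cell units.

    Returns (col0, col1, row0, row1) fine-index bounds per PA, ordered by the
    original (shuffled) PA identity.  Rectangles keep a one-coarse-cell margin
    from each other and the scene edge so no coarse cell intersects two PAs.
    """
    sub = cfg.subdivision
    W, H = cfg.width * sub, cfg.height * sub
    fine_m = cfg.fine_pixel_size
    lo, hi = cfg.pa_area_range_km2
    areas_m2 = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_pas)) * 1e6
    order = np.argsort(-areas_m2)  # biggest first packs far more reliably
    placed: list[tuple[int, int, int, int] | None] = [None] * cfg.n_pas
    occupied: list[tuple[int, int, int, int]] = []
    margin = sub  # one coarse cell
    for idx in order:
        area = areas_m2[idx]
        ok = False
        for _ in range(4000):
            aspect = math.exp(rng.uniform(math.log(0.5), math.log(2.0)))
            w = max(1, round(math.sqrt(area * aspect) / fine_m))
            h = max(1, round(area / (w * fine_m) / fine_m))
            if w + 2 * margin >= W or h + 2 * margin >= H:
                continue
            c0 = int(rng.integers(margin, W - w - margin + 1))
            r0 = int(rng.integers(margin, H - h - margin + 1))
            c1, r1 = c0 + w, r0 + h
            if all(c1 + margin <= oc0 or c0 >= oc1 + margin
                   or r1 + margin <= or0 or r0 >= or1 + margin
                   for oc0, oc1, or0, or1 in occupied):
                occupied.append((c0, c1, r0, r1))
                placed[idx] = (c0, c1, r0, r1)
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place a {area / 1e6:.0f} km^2 PA after 4000 attempts: "
                f"{cfg.n_pas} PAs of {lo}-{hi} km^2 do not fit in a "
                f"{cfg.width * cfg.coarse_pixel_size / 1e3:.0f} km scene "
                f"with one-coarse-cell separation"
            )
    return placed  # type: ignore[return-value]


def _coarse_overlaps(bounds: tuple[int, int, int, int], sub: int):
    """Per-axis fine-cell overlap of a fine-index rectangle with coarse cells.

    Returns (cols, ov_x, rows, ov_y): the coarse indices intersected along
    each axis and the integer number of fine cells of overlap in each.
    """
    c0, c1, r0, r1 = bounds
    cc0, cc1 = c0 // sub, -(-c1 // sub)
    rr0, rr1 = r0 // sub, -(-r1 // sub)
    cols = np.arange(cc0, cc1)
    rows = np.arange(rr0, rr1)
    ov_x = np.minimum((cols + 1) * sub, c1) - np.maximum(cols * sub, c0)
    ov_y = np.minimum((rows + 1) * sub, r1) - np.maximum(rows * sub, r0)
    return cols, ov_x, rows, ov_y


def generate_scene(config: SceneConfig) -> tuple[Scene, list[PARecord], pd.DataFrame]:
    """Build a scene, its PA records, and the exact per-PA truth table.

    The truth table (one row per PA) holds: true forest area (ha), forest
    fraction, area-weighted mean AGB/BGB over the forested part (Mg ha^-1),
    carbon stock (Mg C, half of total biomass), corrected loss proportion
    (loss area / forest area), carbon loss (Mg C), and the outlier-injection
    flag.  All values derive from the exact construction geometry.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sub = cfg.subdivision
    fine_m = cfg.fine_pixel_size
    cell_ha = cfg.coarse_pixel_size ** 2 / 1e4
    fine_ha = fine_m ** 2 / 1e4
    origin = (0.0, cfg.height * cfg.coarse_pixel_size)

    bounds = _place_rectangles(cfg, rng)

    landcover = np.full((cfg.height, cfg.width), NONFOREST_CLASS, dtype=np.int16)
    agb = np.zeros((cfg.height, cfg.width))
    loss_fine = np.zeros((cfg.height * sub, cfg.width * sub), dtype=np.int8)
    pa_touch = np.zeros((cfg.height, cfg.width), dtype=bool)

    f_lo, f_hi = cfg.forest_fraction_range

    # pass 1: geometry, forest assignment, biomass, stocks
    records: list[PARecord] = []
    truth_rows: list[dict] = []
    forest_cells_by_pa: list[tuple[np.ndarray, np.ndarray]] = []
    for i, (c0, c1, r0, r1) in enumerate(bounds):
        cols, ov_x, rows, ov_y = _coarse_overlaps((c0, c1, r0, r1), sub)
        cell_cells = np.multiply.outer(ov_y, ov_x)      # fine cells per coarse cell
        R, C = np.meshgrid(rows, cols, indexing="ij")
        pa_touch[R, C] = True
        total_cells = (c1 - c0) * (r1 - r0)
        gis_area_m2 = total_cells * fine_m ** 2

        # forest assignment: interior coarse cells first, boundary cells after,
        # accumulating exact overlap until the target fraction is reached
        flat_cells = cell_cells.ravel()
        interior = flat_cells == sub * sub
        idx_int = np.flatnonzero(interior)
        idx_bnd = np.flatnonzero(~interior)
        rng.shuffle(idx_int)
        rng.shuffle(idx_bnd)
        order_cells = np.concatenate([idx_int, idx_bnd])
        target_cells = round(rng.uniform(f_lo, f_hi) * total_cells)
        cum = np.cumsum(flat_cells[order_cells])
        k = int(np.searchsorted(cum, target_cells)) + 1 if target_cells > 0 else 0
        chosen = order_cells[:min(k, order_cells.size)]
        forest_cells = int(flat_cells[chosen].sum())
        rr, cc = R.ravel()[chosen], C.ravel()[chosen]
        landcover[rr, cc] = rng.integers(1, 9, size=chosen.size)
        cell_agb = np.clip(rng.normal(cfg.agb_mean, cfg.agb_sd, size=chosen.size), 10.0, None)
        agb[rr, cc] = cell_agb

        forest_area_ha = forest_cells * fine_ha
        forest_fraction = forest_cells / total_cells
        if forest_cells:
            w = flat_cells[chosen].astype(float)
            mean_agb = float(np.average(cell_agb, weights=w))
        else:
            mean_agb = 0.0
        mean_bgb = mean_agb * cfg.bgb_ratio
        stock = forest_area_ha * (mean_agb + mean_bgb) * 0.5
        forest_cells_by_pa.append((rr, cc))

        x0m, x1m = c0 * fine_m, c1 * fine_m
        ytop, ybot = origin[1] - r0 * fine_m, origin[1] - r1 * fine_m
        geom = box(x0m, ybot, x1m, ytop)
        pa_id = f"pa_{i:04d}"
        records.append(PARecord(
            pa_id=pa_id,
            name=f"Synthetic PA {i:03d}",
            country=str(rng.choice(cfg.countries)) if cfg.countries else "Nowhere",
            iucn_cat=str(rng.choice(IUCN_CATEGORIES)),
            status="proposed" if rng.random() < cfg.proposed_fraction else "designated",
            gis_area_km2=gis_area_m2 / 1e6,
            geometry=geom,
        ))
        truth_rows.append({
            "pa_id": pa_id,
            "forest_area_ha": forest_area_ha,
            "forest_fraction": forest_fraction,
            "mean_agb_mg_ha": mean_agb,
            "mean_bgb_mg_ha": mean_bgb,
            "carbon_stock_mg": stock,
            "corrected_loss_proportion": 0.0,
            "carbon_loss_mg": 0.0,
            "outlier_injected": False,
        })

    # outlier injection targets the analysable cohort: the scene's purpose is
    # to plant disproportionate emitters *among the PAs the analysis keeps*,
    # so injection prefers PAs meeting the inclusion rules (>= 10 km^2 of
    # forest, >= 50% cover), topped up by largest forest area if too few
    eligible = [i for i, row in enumerate(truth_rows)
                if row["forest_area_ha"] >= 1000.0 and row["forest_fraction"] >= 0.5]
    if len(eligible) < cfg.n_outliers:
        rest = sorted((i for i in range(cfg.n_pas) if i not in set(eligible)),
                      key=lambda i: -truth_rows[i]["forest_area_ha"])
        eligible = eligible + rest[:cfg.n_outliers - len(eligible)]
        outlier_ids = set(eligible)
    else:
        outlier_ids = set(rng.choice(np.array(eligible), cfg.n_outliers,
                                     replace=False).tolist())

    # pass 2: per-PA loss — a proportion of its forest fine cells, without
    # replacement, 20x (by default) for the injected outliers
    for i, ((c0, c1, r0, r1), (rr, cc)) in enumerate(zip(bounds, forest_cells_by_pa)):
        forest_cells = round(truth_rows[i]["forest_area_ha"] / fine_ha)
        injected = i in outlier_ids
        if cfg.loss_mean <= 0.0:
            p = 0.0
        else:
            # injected PAs draw from the same Beta family with the mean scaled
            # by the multiplier, so the injection strength is the multiplier
            # itself rather than multiplier x a lucky baseline draw
            mean = cfg.loss_mean * (cfg.outlier_multiplier if injected else 1.0)
            mean = min(mean, 0.95)
            a = mean * cfg.loss_concentration
            b = (1.0 - mean) * cfg.loss_concentration
            p = float(rng.beta(a, b))
        n_loss = round(p * forest_cells)
        if n_loss > 0:
            fine_idx = []
            for j in range(rr.size):
                r, c = rr[j], cc[j]
                fx0, fx1 = max(c * sub, c0), min((c + 1) * sub, c1)
                fy0, fy1 = max(r * sub, r0), min((r + 1) * sub, r1)
                fr, fc = np.meshgrid(np.arange(fy0, fy1), np.arange(fx0, fx1), indexing="ij")
                fine_idx.append(fr.ravel() * (cfg.width * sub) + fc.ravel())
            eligible_fine = np.concatenate(fine_idx)
            assert eligible_fine.size == forest_cells
            hit = rng.choice(eligible_fine, size=n_loss, replace=False)
            loss_fine.ravel()[hit] = 1
        loss_proportion = n_loss / forest_cells if forest_cells else 0.0
        truth_rows[i]["corrected_loss_proportion"] = loss_proportion
        truth_rows[i]["carbon_loss_mg"] = truth_rows[i]["carbon_stock_mg"] * loss_proportion
        truth_rows[i]["outlier_injected"] = injected

    # background forest outside every PA's footprint (no loss assigned there)
    free = np.flatnonzero(~pa_touch.ravel())
    n_bg = round(cfg.background_forest_fraction * free.size)
    if n_bg:
        bg = rng.choice(free, size=n_bg, replace=False)
        landcover.ravel()[bg] = rng.integers(1, 9, size=n_bg)
        agb.ravel()[bg] = np.clip(rng.normal(cfg.agb_mean, cfg.agb_sd, size=n_bg), 10.0, None)

    coarse = (cfg.coarse_pixel_size, cfg.coarse_pixel_size)
    scene = Scene(
        landcover=Grid(landcover, origin, coarse, kind="categorical"),
        agb=Grid(agb, origin, coarse, kind="continuous"),
        bgb=Grid(agb * cfg.bgb_ratio, origin, coarse, kind="continuous"),
        loss=Grid(loss_fine, origin, (fine_m, fine_m), kind="categorical"),
        config=cfg,
    )
    truth = pd.DataFrame(truth_rows)
    _check_truth(scene, truth, cell_ha)
    return scene, records, truth


def _check_truth(scene: Scene, truth: pd.DataFrame, cell_ha: float) -> None:
    # conservation: PA forest cannot exceed scene forest; loss stays in forest cells
    scene_forest_ha = int(np.isin(scene.landcover.values, FOREST_CLASSES).sum()) * cell_ha
    if truth["forest_area_ha"].sum() > scene_forest_ha + 1e-6:
        raise AssertionError("constructed PA forest area exceeds scene forest area")


def write_fixture(scene: Scene, pa_records: list[PARecord], truth: pd.DataFrame,
                  directory: str | Path) -> dict[str, Path]:
    """Write the scene to text formats: ASCII grids, GeoJSON polygons, CSV truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "landcover": write_ascii_grid(scene.landcover, directory / "landcover.asc"),
        "agb": write_ascii_grid(scene.agb, directory / "agb.asc"),
        "bgb": write_ascii_grid(scene.bgb, directory / "bgb.asc"),
        "loss": write_ascii_grid(scene.loss, directory / "loss.asc"),
        "pas": write_pa_geojson(pa_records, directory / "pas.geojson"),
        "truth": directory / "truth.csv",
    }
    truth.to_csv(paths["truth"], index=False)
    return paths


def read_fixture(directory: str | Path) -> tuple[Scene, list[PARecord], pd.DataFrame]:
    """Read a fixture written by :func:`write_fixture` (lossless round-trip)."""
    directory = Path(directory)
    scene = Scene(
        landcover=read_ascii_grid(directory / "landcover.asc", kind="categorical"),
        agb=read_ascii_grid(directory / "agb.asc"),
        bgb=read_ascii_grid(directory / "bgb.asc"),
        loss=read_ascii_grid(directory / "loss.asc", kind="categorical"),
    )
    records = read_pa_geojson(directory / "pas.geojson")
    truth = pd.read_csv(directory / "truth.csv")
    return scene, records, truth
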