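"""End-to-end orchestration: harmonise layers, filter PAs, account, analyse.

The working grid defaults to a 250 m pixel: an integer divisor of both the
1 km land-cover/biomass grid (each coarse cell tiles into 4x4 working cells,
so nearest-neighbour resampling changes no values and loses no area) and an
integer multiple of the ~31 m loss grid (so area-averaging is exact, with no
padding).  This keeps the polygon-edge quantisation error small while the
whole scene still fits comfortably in memory — the same compromise the
300 m grid of operational PA analyses makes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accounting import (ErrorBudget, PASummary, WorkingLayers, summaries_to_frame,
                         summarise_pa)
from .filters import (FilterOutcome, PARecord, apply_inclusion_filters,
                      outcomes_to_frame)
from .grids import aggregate_fraction, resample_nearest
from .landscape import Scene
from .stats import (ConcentrationResult, OutlierReport, RegressionFit,
                    classify_outliers, concentration, fit_loglog,
                    studentised_residuals)

__all__ = [
    "prepare_working", "run_analysis", "PipelineResult",
    "outlier_analysis", "OutlierAnalysis",
    "recovery_tolerances", "evaluate_recovery",
]

DEFAULT_WORKING_PIXEL = 250.0  # metres


def prepare_working(scene: Scene, working_pixel_size: float = DEFAULT_WORKING_PIXEL) -> WorkingLayers:
    """Resample/aggregate the scene's layers onto one working grid.

    Land cover and biomass are nearest-neighbour resampled (values
    unchanged); the fine binary loss grid is area-averaged into per-pixel
    loss fractions.  The working pixel must be an integer multiple of the
    fine pixel, or the loss aggregation would mis-register.
    """
    fine = scene.loss.pixel_size[0]
    factor = round(working_pixel_size / fine)
    if factor < 1 or abs(factor * fine - working_pixel_size) > 1e-6 * working_pixel_size:
        raise ValueError(
            f"working pixel {working_pixel_size} m is not an integer multiple of "
            f"the loss grid's {fine} m pixel")
    loss_fraction = aggregate_fraction(scene.loss, factor)
    return WorkingLayers(
        landcover=resample_nearest(scene.landcover, working_pixel_size),
        agb=resample_nearest(scene.agb, working_pixel_size),
        bgb=resample_nearest(scene.bgb, working_pixel_size),
        loss_fraction=loss_fraction,
    )


@dataclass
class PipelineResult:
    """Audit of the inclusion filters plus the per-PA results table."""

    outcomes: list[FilterOutcome]
    audit: pd.DataFrame
    summaries: list[PASummary]
    results: pd.DataFrame
    removal_counts: dict[str, int] = field(default_factory=dict)


def run_analysis(
    scene: Scene,
    records: list[PARecord],
    working_pixel_size: float = DEFAULT_WORKING_PIXEL,
    budget: ErrorBudget = ErrorBudget(),
    area_threshold_km2: float = 10.0,
    min_forest_pixels: int = 10,
    min_forest_fraction: float = 0.5,
    corrected: bool = True,
    years: float = 12.0,
    include_proposed: bool = True,
) -> PipelineResult:
    """Filter the cohort, then run the zonal carbon accounting on the keepers.

    The forest-pixel rule counts 1-km^2-equivalents of forest area, so the
    filters behave identically whether evaluated at the native or the
    working resolution.
    """
    layers = prepare_working(scene, working_pixel_size)
    coarse_km2 = scene.landcover.pixel_area / 1e6
    outcomes = apply_inclusion_filters(
        records, layers.landcover,
        area_threshold_km2=area_threshold_km2,
        min_forest_pixels=min_forest_pixels,
        min_forest_fraction=min_forest_fraction,
        coarse_pixel_area_km2=coarse_km2,
        include_proposed=include_proposed,
    )
    summaries = [
        summarise_pa(o.pa, layers, budget=budget, corrected=corrected, years=years)
        for o in outcomes if o.kept
    ]
    audit = outcomes_to_frame(outcomes)
    removal_counts = (
        audit.loc[~audit["kept"], "reason"].value_counts().to_dict()
    )
    return PipelineResult(
        outcomes=outcomes,
        audit=audit,
        summaries=summaries,
        results=summaries_to_frame(summaries),
        removal_counts=removal_counts,
    )


# ---------------------------------------------------------------------------
# Outlier / concentration analysis over a results table
# ---------------------------------------------------------------------------

@dataclass
class OutlierAnalysis:
    """Regression-based outlier report over a per-PA results table."""

    fit: RegressionFit
    studentised: np.ndarray
    report: OutlierReport
    conc: ConcentrationResult
    table: pd.DataFrame            # high emitters, largest loss rate first
    fitted_index: pd.Index         # rows of `results` that entered the fit
    n_zero_emission: int


def outlier_analysis(
    results: pd.DataFrame,
    threshold: float = 2.0,
    target_share: float = 0.8,
    residual_kind: str = "internal",
) -> OutlierAnalysis:
    """Fit log10(annual emissions) ~ log10(forest area) and flag outliers.

    Zero-emission PAs are excluded from the fit (and counted); the outlier
    flags are invariant to using annual or whole-window emissions, since the
    x12 rescaling only shifts the intercept.
    """
    usable = results[results["annual_carbon_loss_mg_yr"] > 0]
    n_zero = len(results) - len(usable)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 PAs with positive emissions, got {len(usable)}")
    areas_km2 = usable["forest_area_ha"].to_numpy() / 100.0
    emissions = usable["annual_carbon_loss_mg_yr"].to_numpy()
    fit = fit_loglog(areas_km2, emissions)
    stud = studentised_residuals(fit, kind=residual_kind)
    report = classify_outliers(stud, emissions, usable["forest_area_ha"].to_numpy(),
                               threshold=threshold)
    conc = concentration(emissions, target_share=target_share)
    high = usable.iloc[report.high_idx].copy()
    high["studentised_residual"] = stud[report.high_idx]
    high["corrected_loss_pct_2000_2012"] = 100.0 * high["corrected_loss_proportion"]
    cols = ["name", "mean_agb_mg_ha", "country", "forest_area_ha", "iucn_cat",
            "corrected_loss_pct_2000_2012", "carbon_stock_mg",
            "annual_carbon_loss_mg_yr", "studentised_residual"]
    table = (high[["pa_id"] + cols]
             .assign(forest_area_km2=lambda d: d["forest_area_ha"] / 100.0)
             .drop(columns="forest_area_ha")
             .sort_values("corrected_loss_pct_2000_2012", ascending=False,
                          ignore_index=True))
    return OutlierAnalysis(fit=fit, studentised=stud, report=report, conc=conc,
                           table=table, fitted_index=usable.index,
                           n_zero_emission=n_zero)


# ---------------------------------------------------------------------------
# Recovery against synthetic ground truth
# ---------------------------------------------------------------------------

def recovery_tolerances(records: list[PARecord], working_pixel_size: float) -> pd.DataFrame:
    """A-priori per-PA rasterisation tolerance for stock and loss recovery.

    Sampling a w x l rectangle with pixels of size h by the centre rule
    quantises each edge within h/2, so the zone area is exact to within
    h*(w+l); relative to the forest area (at least half the PA under the
    inclusion rules) that is at most 2h(w+l)/(wl).  Carbon loss compounds the
    stock and loss-area quantisations, so its bound is twice the stock's.
    These bounds depend only on the geometry, never on observed errors.
    """
    rows = []
    for r in records:
        xmin, ymin, xmax, ymax = r.geometry.bounds
        w, l = xmax - xmin, ymax - ymin
        rel = 2.0 * working_pixel_size * (w + l) / (w * l)
        rows.append({"pa_id": r.pa_id, "stock_rel_tol": rel, "loss_rel_tol": 2.0 * rel})
    return pd.DataFrame(rows)


def evaluate_recovery(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    records: list[PARecord],
    working_pixel_size: float = DEFAULT_WORKING_PIXEL,
) -> pd.DataFrame:
    """Per-PA relative errors of estimated stock/loss against scene truth.

    Returns one row per analysed PA with the relative errors, the a-priori
    tolerances from :func:`recovery_tolerances`, and within-tolerance flags.
    A zero-truth loss counts as recovered iff the estimate is also zero.
    """
    tol = recovery_tolerances(records, working_pixel_size)
    df = (results.merge(truth, on="pa_id", suffixes=("", "_true"))
                 .merge(tol, on="pa_id"))
    df["stock_rel_err"] = (df["carbon_stock_mg"] - df["carbon_stock_mg_true"]).abs() \
        / df["carbon_stock_mg_true"]
    truth_loss = df["carbon_loss_mg_true"]
    est_loss = df["carbon_loss_mg"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (est_loss - truth_loss).abs() / truth_loss
    df["loss_rel_err"] = np.where(truth_loss > 0, rel,
                                  np.where(est_loss == 0, 0.0, np.inf))
    df["stock_ok"] = df["stock_rel_err"] <= df["stock_rel_tol"]
    df["loss_ok"] = df["loss_rel_err"] <= df["loss_rel_tol"]
    return df
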