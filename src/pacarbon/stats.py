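"""Regression, outlier flagging, concentration, and cohort aggregates.

Gross emissions scale with how much forest a PA started with, so raw
emission totals cannot identify *disproportionate* emitters.  The model here
regresses log10(carbon emissions) on log10(year-2000 forest area) by
ordinary least squares and flags PAs whose internally studentised residuals
exceed +2 (strict inequality) as disproportionately high emitters, and below
-2 as unusually low ones.  Zero-emission PAs cannot enter a log regression;
they are excluded from the fit and reported separately rather than patched
in with an offset, which would distort the slope.

The module also measures how concentrated emissions are across the cohort
(the smallest set of PAs accounting for a target share of total emissions)
and aggregates loss rates and carbon densities by IUCN category and country.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegressionFit", "OutlierReport", "ConcentrationResult", "CategorySummary",
    "fit_loglog", "studentised_residuals", "classify_outliers",
    "concentration", "summarise_categories",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of log10(emissions) on log10(area), with intercept."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray       # raw residuals, log10 units
    n: int
    x: np.ndarray = field(repr=False)   # log10 predictor, kept for leverage
    y: np.ndarray = field(repr=False)

    def predict(self, areas: np.ndarray) -> np.ndarray:
        """Predicted log10(emissions) at the given (linear-scale) areas."""
        return self.intercept + self.slope * np.log10(np.asarray(areas, dtype=float))


def fit_loglog(areas: np.ndarray, emissions: np.ndarray) -> RegressionFit:
    """OLS of log10(emissions) on log10(area).

    Both inputs must be strictly positive (callers drop zero-emission PAs
    first); n >= 3 and a non-constant predictor are required.
    """
    areas = np.asarray(areas, dtype=float)
    emissions = np.asarray(emissions, dtype=float)
    if areas.shape != emissions.shape or areas.ndim != 1:
        raise ValueError("areas and emissions must be 1-D arrays of equal length")
    if areas.size < 3:
        raise ValueError(f"need at least 3 observations to fit, got {areas.size}")
    if (areas <= 0).any() or (emissions <= 0).any():
        raise ValueError("log-log fit requires strictly positive areas and emissions")
    x = np.log10(areas)
    y = np.log10(emissions)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate fit: predictor is constant")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r2,
                         residuals=resid, n=int(x.size), x=x, y=y)


def studentised_residuals(fit: RegressionFit, kind: str = "internal") -> np.ndarray:
    """Studentise the fit's residuals: e_i / (s * sqrt(1 - h_i)).

    ``internal`` uses s = sqrt(SSE / (n - 2)); ``external`` uses the
    leave-one-out estimate s_(i).  A perfectly fitted dataset studentises to
    all zeros; an exactly determined point (leverage 1) is undefined and
    returned as NaN.
    """
    x, e, n = fit.x, fit.residuals, fit.n
    sxx = float(np.sum((x - x.mean()) ** 2))
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    sse = float(np.sum(e ** 2))
    # an exact fit leaves only rounding residue; don't studentise noise
    if sse <= n * (1e-12 * max(1.0, float(np.abs(fit.y).max()))) ** 2:
        sse = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "internal":
            s2 = sse / (n - 2)
            out = np.where(h < 1.0, e / np.sqrt(s2 * (1.0 - h)), np.nan)
        elif kind == "external":
            if n < 4:
                raise ValueError("external studentisation needs n >= 4")
            s2_i = (sse - e ** 2 / (1.0 - h)) / (n - 3)
            out = np.where(h < 1.0, e / np.sqrt(s2_i * (1.0 - h)), np.nan)
        else:
            raise ValueError(f"kind must be 'internal' or 'external', got {kind!r}")
    if sse == 0.0:
        out = np.where(h < 1.0, 0.0, np.nan)
    return out


@dataclass(frozen=True)
class OutlierReport:
    """PAs with studentised residuals beyond +/- threshold, and their weight."""

    high_idx: np.ndarray        # indices into the fitted arrays, residual > +t
    low_idx: np.ndarray         # residual < -t
    n: int
    threshold: float
    high_share_of_cohort: float
    low_share_of_cohort: float
    high_share_of_forest_area: float
    low_share_of_forest_area: float
    high_share_of_emissions: float
    low_share_of_emissions: float


def classify_outliers(
    resids: np.ndarray,
    emissions: np.ndarray,
    forest_areas: np.ndarray,
    threshold: float = 2.0,
) -> OutlierReport:
    """Split the cohort at +/- threshold on the studentised residuals.

    The inequality is strict: a residual of exactly +2 is not flagged.  The
    report carries each set's share of the cohort, of the total forest area,
    and of total emissions.
    """
    resids = np.asarray(resids, dtype=float)
    emissions = np.asarray(emissions, dtype=float)
    forest_areas = np.asarray(forest_areas, dtype=float)
    n = resids.size
    with np.errstate(invalid="ignore"):
        high = np.flatnonzero(resids > threshold)
        low = np.flatnonzero(resids < -threshold)
    tot_e = emissions.sum()
    tot_a = forest_areas.sum()
    return OutlierReport(
        high_idx=high, low_idx=low, n=n, threshold=threshold,
        high_share_of_cohort=high.size / n,
        low_share_of_cohort=low.size / n,
        high_share_of_forest_area=forest_areas[high].sum() / tot_a if tot_a else 0.0,
        low_share_of_forest_area=forest_areas[low].sum() / tot_a if tot_a else 0.0,
        high_share_of_emissions=emissions[high].sum() / tot_e if tot_e else 0.0,
        low_share_of_emissions=emissions[low].sum() / tot_e if tot_e else 0.0,
    )


@dataclass(frozen=True)
class ConcentrationResult:
    """Smallest descending-sorted prefix of PAs reaching a target emission share."""

    cumulative_shares: np.ndarray   # over PAs sorted by descending emissions
    n_pas: int
    fraction_of_cohort: float
    subset_emissions: float
    subset_indices: np.ndarray      # original indices of the prefix
    target_share: float


def concentration(emissions: np.ndarray, target_share: float = 0.8) -> ConcentrationResult:
    """How few PAs carry ``target_share`` of total emissions.

    PAs are sorted by descending emissions (stable, so ties keep their
    original order) and the shortest prefix whose cumulative share reaches
    the target is returned.
    """
    emissions = np.asarray(emissions, dtype=float)
    if (emissions < 0).any():
        raise ValueError("emissions must be non-negative")
    total = emissions.sum()
    if total == 0:
        raise ValueError("cannot compute concentration of an all-zero emission vector")
    if not 0.0 < target_share <= 1.0:
        raise ValueError("target share must lie in (0, 1]")
    order = np.argsort(-emissions, kind="stable")
    shares = np.cumsum(emissions[order]) / total
    k = int(np.searchsorted(shares, target_share - 1e-12)) + 1
    return ConcentrationResult(
        cumulative_shares=shares,
        n_pas=k,
        fraction_of_cohort=k / emissions.size,
        subset_emissions=float(emissions[order[:k]].sum()),
        subset_indices=order[:k],
        target_share=target_share,
    )


@dataclass(frozen=True)
class CategorySummary:
    """Aggregates by IUCN category and by country."""

    by_category: pd.DataFrame
    by_country: pd.DataFrame


def _tukey_whiskers(v: np.ndarray) -> tuple[float, float, float, float, float]:
    """median, q1, q3, and Tukey whiskers (furthest points within 1.5 IQR)."""
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear (type-7) interpolation
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return float(med), float(q1), float(q3), float(inside.min()), float(inside.max())


def summarise_categories(results: pd.DataFrame) -> CategorySummary:
    """Per-IUCN-category loss-rate/density distributions and country totals.

    ``results`` is the per-PA results table (one row per kept PA).  Per
    category: PA count, mean carbon density over reported area, mean and
    median annual loss rate with quartiles and 1.5-IQR whiskers.  Per
    country: total stock, total and annual carbon loss, and the proportion
    of year-2000 protected carbon lost over the window.
    """
    if results.empty:
        raise ValueError("cannot summarise an empty cohort")
    cat_rows = []
    for cat, grp in results.groupby("iucn_cat", sort=True):
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"IUCN category {cat} has no PAs; omitted")
            continue
        rates = grp["annual_loss_rate_pct_yr"].to_numpy()
        med, q1, q3, wlo, whi = _tukey_whiskers(rates)
        cat_rows.append({
            "iucn_cat": cat,
            "n_pas": len(grp),
            "mean_carbon_density_mg_ha": grp["carbon_density_mg_ha"].mean(),
            "mean_loss_rate_pct_yr": rates.mean(),
            "median_loss_rate_pct_yr": med,
            "q1_loss_rate_pct_yr": q1,
            "q3_loss_rate_pct_yr": q3,
            "whisker_low_pct_yr": wlo,
            "whisker_high_pct_yr": whi,
        })
    country_rows = []
    for country, grp in results.groupby("country", sort=True):
        stock = grp["carbon_stock_mg"].sum()
        loss = grp["carbon_loss_mg"].sum()
        country_rows.append({
            "country": country,
            "n_pas": len(grp),
            "carbon_stock_mg": stock,
            "carbon_loss_mg": loss,
            "annual_carbon_loss_mg_yr": grp["annual_carbon_loss_mg_yr"].sum(),
            "proportional_carbon_loss": loss / stock if stock else 0.0,
        })
    cat_frame = pd.DataFrame(cat_rows)
    iucn_order = ("Ia", "Ib", "II", "III", "IV", "V", "VI")
    if set(cat_frame["iucn_cat"]) <= set(iucn_order):
        cat_frame = cat_frame.sort_values(
            "iucn_cat", key=lambda s: s.map(iucn_order.index), ignore_index=True)
    return CategorySummary(
        by_category=cat_frame,
        by_country=pd.DataFrame(country_rows).sort_values(
            "annual_carbon_loss_mg_yr", ascending=False, ignore_index=True),
    )
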