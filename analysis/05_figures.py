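#!/usr/bin/env python
"""Diagnostic figures: the outlier regression and loss-rate distributions.

Draws (1) the log-log scatter of annual emissions against year-2000 forest
area with the fitted line and the +/-2-sigma flagged PAs highlighted, and
(2) box plots of annual loss rates by IUCN category (1.5-IQR whiskers,
means marked).  PNGs go under scratch/figures/ — they are diagnostics, not
data products.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from pacarbon import outlier_analysis

RESULTS = Path("results")
FIGDIR = Path("scratch") / "figures"


def main() -> None:
    results = pd.read_csv(RESULTS / "per_pa_results.csv")
    ana = outlier_analysis(results)
    fitted = results.loc[ana.fitted_index]
    x = fitted["forest_area_ha"].to_numpy() / 100.0
    y = fitted["annual_carbon_loss_mg_yr"].to_numpy()

    FIGDIR.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.loglog(x, y, "o", ms=4, color="0.6", label="PAs")
    hi, lo = ana.report.high_idx, ana.report.low_idx
    ax.loglog(x[hi], y[hi], "o", ms=6, mfc="none", mec="red",
              label=f"> +2 sigma (n={hi.size})")
    if lo.size:
        ax.loglog(x[lo], y[lo], "o", ms=6, mfc="none", mec="green",
                  label=f"< -2 sigma (n={lo.size})")
    xs = np.logspace(np.log10(x.min()), np.log10(x.max()), 50)
    ax.loglog(xs, 10 ** ana.fit.predict(xs), "-", color="k",
              label=f"OLS (r$^2$={ana.fit.r_squared:.2f})")
    ax.set_xlabel("forest area in 2000 (km$^2$)")
    ax.set_ylabel("annual carbon emissions (Mg C yr$^{-1}$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(FIGDIR / "outlier_regression.png", dpi=150)

    fig, ax = plt.subplots(figsize=(6, 4))
    cats = sorted(results["iucn_cat"].unique())
    data = [results.loc[results["iucn_cat"] == c, "annual_loss_rate_pct_yr"]
            for c in cats]
    ax.boxplot(data, tick_labels=cats, whis=1.5, showmeans=True)
    ax.set_xlabel("IUCN category")
    ax.set_ylabel("forest loss rate (% yr$^{-1}$)")
    fig.tight_layout()
    fig.savefig(FIGDIR / "loss_rates_by_category.png", dpi=150)

    print(f"wrote figures under {FIGDIR}")


if __name__ == "__main__":
    main()
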