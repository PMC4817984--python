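#!/usr/bin/env python
"""Compare the size-structure projection with the metabolic-scaling model.

For each stand: RMA line through (D0^(2/3), DT^(2/3)) — the
metabolic-scaling model predicts slope 1 — plus variance explained by
the plug-in projection curve vs the best slope-one line, and the two
rate models on (D0, dD/dt) axes.
"""

from pathlib import Path

import pandas as pd

from ynstand import census_io, pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows, curves = [], []
    for plot in ("young", "mature"):
        series = census_io.read_census_wide(OUT / f"{plot}_stand.csv", plot_id=plot)
        ar = pipeline.run_assumptions(series)
        params = pipeline.derive_growth_params(series, ar.yn_fits, ar.ab_scaling)
        mc = pipeline.compare_models(series, params)
        rows.append(
            {
                "plot": plot,
                "rma_slope": mc.rma_fit.slope,
                "rma_slope_ci_lo": mc.rma_fit.slope_ci95[0],
                "rma_slope_ci_hi": mc.rma_fit.slope_ci95[1],
                "alt_r2": mc.alt_r2,
                "enquist_r2": mc.enquist_r2,
                "delta_r2": mc.delta_r2,
                "alt_rate_r2": mc.alt_rate_r2,
                "enquist_rate_r2": mc.enquist_rate_r2,
                "beta": mc.rate_model.beta,
                "n_pairs": mc.n_pairs,
            }
        )
        grid = pipeline.curve_grid(params)
        grid.insert(0, "plot", plot)
        curves.append(grid)
        print(
            f"{plot}: RMA slope {mc.rma_fit.slope:.3f} "
            f"[{mc.rma_fit.slope_ci95[0]:.3f}, {mc.rma_fit.slope_ci95[1]:.3f}]; "
            f"projection r2 {mc.alt_r2:.4f} vs slope-one r2 {mc.enquist_r2:.4f} "
            f"(+{100 * mc.delta_r2:.1f}%)"
        )
    pd.DataFrame(rows).to_csv(OUT / "model_comparison.csv", index=False)
    pd.concat(curves, ignore_index=True).to_csv(OUT / "prediction_curves.csv", index=False)
    print(f"tables in {OUT/'model_comparison.csv'} and {OUT/'prediction_curves.csv'}")


if __name__ == "__main__":
    main()
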