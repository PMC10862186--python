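#!/usr/bin/env python
"""Bias-correction recovery experiment on the decade of synthetic forcing.

Distorts the "observed" 2 m air temperature with a known smooth monotone
warp plus noise (the coarse-product stand-in), fits the quantile-mapping
transfer function, and measures how well the correction recovers the
truth. Repeats the exercise for daily precipitation with injected
drizzle and the wet-day adjustment. Requires 01_generate_weather.py.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ectotemp import biascorrect, metrics, weather

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

WARP = (2.0, 1.1, 0.0, 2e-5)  # 2 + 1.1·x + 2e-5·x³
NOISE_SD = 0.5  # °C
DRIZZLE_FRACTION = 0.30


def main() -> None:
    decade = weather.read_weather_csv(SCRATCH / "forcing_2010_2019.csv")
    t_obs = decade["T_air_2m"].to_numpy()
    t_coarse = weather.distort_series(t_obs, WARP, NOISE_SD, seed=11)

    tmap = biascorrect.fit_transfer(t_coarse, t_obs, variable_name="T_air_2m")
    tmap.to_csv(SCRATCH / "transfer_map_T_air_2m.csv")  # 10,000-row grid table
    corrected = biascorrect.apply_transfer(tmap, t_coarse)

    q = np.linspace(0.05, 0.95, 500)
    sup_err = float(np.max(np.abs(
        biascorrect.apply_transfer(tmap, np.quantile(t_coarse, q))
        - np.quantile(t_obs, q))))
    raw_rmse = metrics.rmse(t_coarse, t_obs)
    corrected_rmse = metrics.rmse(corrected, t_obs)

    daily = decade.set_index("timestamp")["precip"].resample("D").sum()
    coarse_precip = weather.distort_precip(daily.to_numpy(), DRIZZLE_FRACTION, seed=12)
    adjusted, wet = biascorrect.wet_day_adjust(coarse_precip, daily.to_numpy())

    report = {
        "n_hours": int(len(decade)),
        "warp": list(WARP),
        "noise_sd": NOISE_SD,
        "raw_rmse_vs_truth": raw_rmse,
        "corrected_rmse_vs_truth": corrected_rmse,
        "central90_sup_error": sup_err,
        "transfer_fit_rmse": tmap.fit_diagnostics["rmse"],
        "wet_day": {
            "observed_dry_fraction": wet.observed_dry_fraction,
            "coarse_dry_fraction_after": wet.coarse_dry_fraction,
            "days_zeroed": wet.n_days_zeroed,
        },
    }
    with open(RESULTS / "bias_correction_report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    print(f"warp {WARP}, noise SD {NOISE_SD} °C on {len(decade)} hours")
    print(f"raw coarse-vs-truth RMSE      : {raw_rmse:.2f} °C")
    print(f"corrected-vs-truth RMSE       : {corrected_rmse:.2f} °C")
    print(f"sup-norm error (central 90%)  : {sup_err:.3f} °C "
          f"(< 2σ = {2 * NOISE_SD:.1f} °C)")
    print(f"wet-day adjustment: zeroed {wet.n_days_zeroed} drizzle days; "
          f"dry fraction {wet.coarse_dry_fraction:.3f} vs observed "
          f"{wet.observed_dry_fraction:.3f}")
    print("The quantile map removes the distribution-level warp; the "
          "remaining RMSE is the irreducible hour-by-hour noise.")


if __name__ == "__main__":
    main()
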