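"""Survey-design power analysis for detecting occupancy declines.

Refits the reflectance model, extracts per-species occupancy and point-count
detection probabilities, then maps the mean power to detect proportional
occupancy reductions across station x replicate effort grids, and searches
for the cheapest design reaching mean power 0.7 for a 50% decline. Outputs:
results/power/power_grid.csv and effort-curve figures mirroring the
station-count line plots. Run 01_simulate_survey.py first.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from msocc import io, model, power, validation
from msocc.pipeline import _subset_history, _subset_landscape, _subset_species, model_designs

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "power"
SEED = 20260920


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    table = io.read_survey_table(
        ROOT / "survey" / "detections.csv", ROOT / "survey" / "stations.csv"
    )
    table, _ = io.filter_species(table, min_stations=10)
    history, landscape, _ = table.to_arrays()
    stations = table.stations.sort_values("station_id").reset_index(drop=True)
    split = validation.make_split(
        history, landscape.centre_of_station, per_centre=2, min_replicates=3,
        seed=SEED + 1,
    )
    train = split.train_station_ids
    history = _subset_species(
        history, np.nonzero(history.detected_at()[:, train].any(axis=1))[0]
    )
    x_all, names, _ = model_designs(stations, "rs")
    spec = model.ModelSpec(n_factors=3, n_iter=6_000, n_burn=3_000, thin=6, seed=SEED + 2)
    samples = model.fit(
        _subset_history(history, train),
        landscape=_subset_landscape(landscape, train),
        spec=spec,
        x=x_all[train],
        occ_names=names,
    )

    psi = samples.psi.mean(axis=(0, 2))
    p_point_am = samples.detection_prob_combo()[:, :, 2].mean(axis=0)
    species_params = list(zip(psi, p_point_am))

    n_st = history.y.shape[1]
    k_med = max(2, int(np.median(history.design.n_replicates)))
    current, _ = power.community_mean_power(species_params, R=0.5, S=n_st, K=k_med)
    print(
        f"current design ({n_st} stations x {k_med} replicates): "
        f"mean power for a 50% decline = {current:.2f}"
    )

    station_counts = [50, 100, 250, 500, 1_000, 2_500, 5_000, 10_000]
    replicate_counts = [2, 3, 4, 6, 8, 12, 16, 27]
    r_values = [0.25, 0.5, 0.75]
    grid = pd.DataFrame(
        power.effort_grid(species_params, r_values, station_counts, replicate_counts)
    )
    grid.to_csv(OUT / "power_grid.csv", index=False)

    rec = power.min_effort_for_target(
        species_params, 0.5, 0.7, station_counts, replicate_counts
    )
    if rec["recommended"]:
        b = rec["recommended"]
        print(
            f"cheapest design with mean power >= 0.7 for a 50% decline: "
            f"{b['S']} stations x {b['K']} replicates "
            f"= {b['total_surveys']} total surveys (power {b['mean_power']:.2f})"
        )
    else:
        print("no design in the searched range reaches mean power 0.7")

    fig, axes = plt.subplots(1, len(r_values), figsize=(4 * len(r_values), 3.5))
    for ax, r in zip(np.atleast_1d(axes), r_values):
        sub = grid[grid["R"] == r]
        for s_count, g in sub.groupby("S"):
            g = g.sort_values("total_surveys")
            ax.plot(g["total_surveys"], g["mean_power"], label=f"{s_count} stations")
        ax.set_xscale("log")
        ax.set_xlabel("total surveys (stations x replicates)")
        ax.set_ylabel("mean power across species")
        ax.set_title(f"{int(r * 100)}% occupancy reduction")
        ax.axhline(0.7, color="grey", ls=":")
    np.atleast_1d(axes)[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "effort_curves.png", dpi=120)
    print(f"wrote grid and figures to {OUT}")


if __name__ == "__main__":
    main()
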