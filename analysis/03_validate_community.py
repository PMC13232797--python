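"""Community-level validation of the spatial reflectance model.

Refits the best model variant (reflectance PCs + spatial factors), then
evaluates held-out stations: per-species AUC of detection-conditioned
scores, species-accumulation curves with ±2SD envelopes (observed vs
modelled), per-station Bray-Curtis dissimilarity, and the regression of
dissimilarity on observed richness. Figures and tables land in
results/validation/. Run 01_simulate_survey.py first.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from msocc import io, model, validation
from msocc.pipeline import _subset_history, _subset_landscape, _subset_species, model_designs

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "validation"
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

    pred = validation.predict_detected_community(
        samples, split, history, x_all, landscape.station_coords, seed=SEED + 3
    )
    obs = history.detected_at()[:, pred.station_ids]
    aucs = validation.species_auc(pred.score, obs)
    bc = validation.station_bray_curtis(pred, obs)
    richness = obs.sum(axis=0)
    reg = validation.richness_dissimilarity_regression(richness, bc)

    pd.DataFrame({"species": np.arange(len(aucs)), "auc": aucs}).to_csv(
        OUT / "species_auc.csv", index=False
    )
    pd.DataFrame(
        {"station_id": pred.station_ids, "richness": richness, "bray_curtis": bc}
    ).to_csv(OUT / "station_dissimilarity.csv", index=False)

    print(f"test stations: {len(pred.station_ids)}")
    print(f"mean predictive AUC: {np.nanmean(aucs):.3f} (SD {np.nanstd(aucs):.3f})")
    print(f"high-AUC species (>0.7): {int(np.nansum(aucs > 0.7))}")
    print(f"mean Bray-Curtis dissimilarity: {np.nanmean(bc):.3f}")
    print(
        f"dissimilarity ~ richness: slope {reg['slope']:.4f}, "
        f"R2 {reg['r2']:.2f}, p {reg['p_value']:.2g}"
    )

    # accumulation curves, observed vs modelled, with ±2SD envelopes
    curves = validation.accumulation_curves(
        obs, predicted=pred.detected, n_permutations=200, seed=SEED + 4
    )
    xs = np.arange(1, obs.shape[1] + 1)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    ax = axes[0]
    for key, color, label in (
        ("observed", "tab:blue", "observed"),
        ("predicted", "black", "modelled"),
    ):
        m, sd = curves[f"{key}_mean"], curves[f"{key}_sd"]
        ax.plot(xs, m, color=color, label=label)
        ax.fill_between(xs, m - 2 * sd, m + 2 * sd, color=color, alpha=0.2)
    ax.set_xlabel("stations surveyed")
    ax.set_ylabel("distinct species detected")
    ax.legend()
    ax.set_title("species accumulation (holdout)")

    ax = axes[1]
    ax.scatter(richness, bc, s=18)
    xs_line = np.linspace(richness.min(), richness.max(), 50)
    ax.plot(xs_line, reg["intercept"] + reg["slope"] * xs_line, "k-")
    ax.set_xlabel("observed species richness")
    ax.set_ylabel("Bray-Curtis dissimilarity")
    ax.set_title(f"R$^2$ = {reg['r2']:.2f}")
    fig.tight_layout()
    fig.savefig(OUT / "validation_figures.png", dpi=120)
    print(f"wrote tables and figures to {OUT}")


if __name__ == "__main__":
    main()
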