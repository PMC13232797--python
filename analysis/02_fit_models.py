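"""Fit and compare the four occupancy-model variants.

Reads the simulated survey from results/survey/, fits the reflectance-PC
model with and without spatial factors, the habitat-covariate model and the
intercept-only baseline, and writes the comparison table (WAIC, ΔWAIC,
Bayesian p-value, explanatory and predictive AUC, high-AUC species count)
to results/model_comparison.csv. Chains are shortened to desk scale; run
01_simulate_survey.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from msocc import diagnostics, io, model, validation
from msocc.pipeline import (
    _subset_history,
    _subset_landscape,
    _subset_species,
    model_designs,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260920
MCMC = dict(n_iter=6_000, n_burn=3_000, thin=6)


def main():
    table = io.read_survey_table(
        ROOT / "survey" / "detections.csv", ROOT / "survey" / "stations.csv"
    )
    table, _ = io.filter_species(table, min_stations=10)
    history, landscape, species_ids = table.to_arrays()
    stations = table.stations.sort_values("station_id").reset_index(drop=True)

    split = validation.make_split(
        history, landscape.centre_of_station, per_centre=2, min_replicates=3,
        seed=SEED + 1,
    )
    train = split.train_station_ids
    keep = history.detected_at()[:, train].any(axis=1)
    history = _subset_species(history, np.nonzero(keep)[0])

    rows = []
    for choice in ("rs", "rs_nonspatial", "habitat", "intercept"):
        x_all, names, spatial = model_designs(stations, choice)
        spec = model.ModelSpec(
            n_factors=3 if spatial else 0, seed=SEED + 2, **MCMC
        )
        samples = model.fit(
            _subset_history(history, train),
            landscape=_subset_landscape(landscape, train),
            spec=spec,
            x=x_all[train],
            occ_names=names,
        )
        train_hist = _subset_history(history, train)
        w = diagnostics.waic(samples, train_hist)
        bayes_p, _ = diagnostics.posterior_predictive_check(
            samples, train_hist, seed=SEED + 3
        )
        coords = landscape.station_coords if spatial else None
        pred_tr = validation.predict_detected_community(
            samples, validation.HoldoutSplit(train, train, 0, 0), history,
            x_all, coords, seed=SEED + 4,
        )
        expl = np.nanmean(
            validation.species_auc(pred_tr.score, history.detected_at()[:, train])
        )
        pred_te = validation.predict_detected_community(
            samples, split, history, x_all, coords, seed=SEED + 5
        )
        aucs = validation.species_auc(
            pred_te.score, history.detected_at()[:, pred_te.station_ids]
        )
        rows.append(
            {
                "model": choice,
                "spatial": spatial,
                "waic": w.waic,
                "bayes_p": bayes_p,
                "mean_explanatory_auc": expl,
                "mean_predictive_auc": np.nanmean(aucs),
                "high_auc_species": int(np.nansum(aucs > 0.7)),
            }
        )
        print(f"{choice}: WAIC {w.waic:.0f}, predictive AUC {np.nanmean(aucs):.3f}")

    out = pd.DataFrame(rows)
    out["delta_waic"] = out["waic"] - out["waic"].min()
    out = out.sort_values("waic")
    out.to_csv(ROOT / "model_comparison.csv", index=False)
    print("\n", out.to_string(index=False))
    print(f"\nbest model by WAIC: {out.iloc[0]['model']}")


if __name__ == "__main__":
    main()
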