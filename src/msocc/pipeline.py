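"""End-to-end orchestration: simulate → fit → validate → power.

A run is driven by a plain config dict (JSON on disk), executes the stages
with explicit seeds, and leaves every table needed to regenerate its
numbers in the run directory: config and seeds, the survey CSVs, coefficient
summaries, diagnostics, the model-comparison table (WAIC, ΔWAIC, mean
explanatory/predictive AUC, high-AUC species count) and the power grid.

Model choices mirror the four fitted variants: ``habitat`` (categorical
land class, forest type and deforestation proportions, with spatial
factors), ``rs`` (continuous reflectance PCs, with spatial factors),
``intercept`` (no occupancy covariates, with spatial factors) and
``rs_nonspatial`` (reflectance PCs, no factors).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, io, model, power, validation
from .simulate import simulate_dataset

__all__ = ["MODEL_CHOICES", "default_config", "run_pipeline", "model_designs"]

MODEL_CHOICES = ("habitat", "rs", "intercept", "rs_nonspatial")

HABITAT_TERMS = ["land_class", "forest_type", "defo_1km", "defo_2km", "defo_5km"]


def default_config(seed: int = 0) -> dict:
    """A desk-scale configuration exercising the full chain."""
    return {
        "seed": seed,
        "simulate": {
            "n_centres": 12,
            "stations_per_centre": 12,
            "n_species": 40,
            "q_occ": 3,
            "n_factors": 1,
            "mean_replicates": 3.5,
        },
        "filter_min_stations": 3,
        "models": ["rs", "rs_nonspatial"],
        "mcmc": {"n_iter": 3000, "n_burn": 1500, "thin": 6},
        "n_factors": 1,
        "validation": {"per_centre": 2, "min_replicates": 3},
        "power": {
            "R_values": [0.3, 0.5],
            "station_counts": [50, 100, 250, 500],
            "replicate_counts": [2, 4, 8, 12],
            "target_power": 0.7,
            "target_R": 0.5,
        },
        "high_auc_threshold": 0.7,
    }


def model_designs(stations: pd.DataFrame, choice: str):
    """Occupancy design matrix and factor usage for a model choice."""
    pc_cols = [c for c in stations.columns if c.startswith("pc")]
    if choice == "habitat":
        terms, spatial = HABITAT_TERMS, True
    elif choice == "rs":
        terms, spatial = pc_cols, True
    elif choice == "intercept":
        terms, spatial = [], True
    elif choice == "rs_nonspatial":
        terms, spatial = pc_cols, False
    else:
        raise ValueError(f"unknown model choice {choice!r}; options {MODEL_CHOICES}")
    terms = [t for t in terms if t in stations.columns]
    x, names = io.occupancy_design_matrix(stations, terms)
    return x, names, spatial


def _mean_auc(scores, observed):
    aucs = validation.species_auc(scores, observed)
    return float(np.nanmean(aucs)), aucs


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages; returns the summary dict it writes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    ss = np.random.SeedSequence(seed).spawn(8)
    seeds = {
        k: int(s.generate_state(1)[0] % 2**31)
        for k, s in zip(
            ["simulate", "split", "fit", "predict", "ppc", "power", "perm", "misc"],
            ss,
        )
    }
    (out / "config.json").write_text(json.dumps({**config, "derived_seeds": seeds}, indent=2))

    # --- simulate ---
    sim_cfg = config.get("simulate", {})
    landscape, covariates, hyper, params, latent, history = simulate_dataset(
        seed=seeds["simulate"], **sim_cfg
    )
    table = io.survey_table_from_arrays(history, landscape, covariates)
    io.write_survey_table(
        table, out / "detections.csv", out / "stations.csv"
    )
    table, dropped = io.filter_species(
        table, min_stations=config.get("filter_min_stations", 10)
    )
    table = io.cap_replicates(table, cap=12)
    dropped.to_csv(out / "dropped_species.csv", index=False)
    history_f, landscape_f, species_ids = table.to_arrays()
    stations = table.stations.sort_values("station_id").reset_index(drop=True)

    # --- holdout split ---
    val_cfg = config.get("validation", {})
    split = validation.make_split(
        history_f,
        landscape_f.centre_of_station,
        per_centre=val_cfg.get("per_centre", 2),
        min_replicates=val_cfg.get("min_replicates", 3),
        seed=seeds["split"],
    )
    train = split.train_station_ids

    # a species whose detections all fall on held-out stations cannot be
    # fitted; drop it from the analysis set
    has_train_det = history_f.detected_at()[:, train].any(axis=1)
    if not has_train_det.all():
        history_f = _subset_species(history_f, np.nonzero(has_train_det)[0])
        species_ids = species_ids[has_train_det]

    mcmc = config.get("mcmc", {})
    rows = []
    fits = {}
    for choice in config.get("models", ["rs"]):
        x_all, names, spatial = model_designs(stations, choice)
        spec = model.ModelSpec(
            n_factors=config.get("n_factors", 3) if spatial else 0,
            n_iter=mcmc.get("n_iter", 50_000),
            n_burn=mcmc.get("n_burn", 25_000),
            thin=mcmc.get("thin", 50),
            seed=seeds["fit"],
        )
        train_hist = _subset_history(history_f, train)
        samples = model.fit(
            train_hist,
            landscape=_subset_landscape(landscape_f, train),
            spec=spec,
            x=x_all[train],
            occ_names=names,
        )
        fits[choice] = samples
        w = diagnostics.waic(samples, train_hist)
        bayes_p, _ = diagnostics.posterior_predictive_check(
            samples, train_hist, seed=seeds["ppc"]
        )
        # explanatory: training stations, predictive: held-out stations
        pred_tr = validation.predict_detected_community(
            samples,
            validation.HoldoutSplit(train, train, 0, 0),
            history_f,
            x_all,
            landscape_f.station_coords if spatial else None,
            seed=seeds["predict"],
        )
        expl_auc, _ = _mean_auc(pred_tr.score, history_f.detected_at()[:, train])
        pred_te = validation.predict_detected_community(
            samples,
            split,
            history_f,
            x_all,
            landscape_f.station_coords if spatial else None,
            seed=seeds["predict"] + 1,
        )
        obs_te = history_f.detected_at()[:, pred_te.station_ids]
        pred_auc, aucs = _mean_auc(pred_te.score, obs_te)
        thr = config.get("high_auc_threshold", 0.7)
        rows.append(
            {
                "model": choice,
                "spatial_factors": spec.n_factors,
                "waic": w.waic,
                "bayes_p": bayes_p,
                "mean_explanatory_auc": expl_auc,
                "mean_predictive_auc": pred_auc,
                "high_auc_species": int(np.nansum(aucs > thr)),
            }
        )
    comparison = pd.DataFrame(rows)
    comparison["delta_waic"] = comparison["waic"] - comparison["waic"].min()
    comparison.to_csv(out / "model_comparison.csv", index=False)

    # --- validation detail for the first model ---
    first = config.get("models", ["rs"])[0]
    samples = fits[first]
    x_all, _, spatial = model_designs(stations, first)
    pred = validation.predict_detected_community(
        samples,
        split,
        history_f,
        x_all,
        landscape_f.station_coords if spatial else None,
        seed=seeds["predict"] + 2,
    )
    obs = history_f.detected_at()[:, pred.station_ids]
    bc = validation.station_bray_curtis(pred, obs)
    richness = obs.sum(axis=0)
    try:
        reg = validation.richness_dissimilarity_regression(richness, bc)
    except ValueError:
        reg = {"slope": np.nan, "intercept": np.nan, "r2": np.nan, "p_value": np.nan}
    val_table = pd.DataFrame(
        {
            "station_id": pred.station_ids,
            "observed_richness": richness,
            "bray_curtis": bc,
        }
    )
    val_table.to_csv(out / "validation_stations.csv", index=False)

    # --- power ---
    pw_cfg = config.get("power", {})
    p_combo = samples.detection_prob_combo().mean(axis=0)  # (n_sp, 4)
    psi_mean = samples.psi.mean(axis=(0, 2))
    species_params = list(zip(psi_mean, p_combo[:, 2]))  # point-count, morning
    grid = power.effort_grid(
        species_params,
        pw_cfg.get("R_values", [0.5]),
        pw_cfg.get("station_counts", [100, 250, 500]),
        pw_cfg.get("replicate_counts", [2, 4, 8, 12]),
    )
    pd.DataFrame(grid).to_csv(out / "power_grid.csv", index=False)
    rec = power.min_effort_for_target(
        species_params,
        pw_cfg.get("target_R", 0.5),
        pw_cfg.get("target_power", 0.7),
        pw_cfg.get("station_counts", [100, 250, 500]),
        pw_cfg.get("replicate_counts", [2, 4, 8, 12]),
    )

    summary = {
        "seeds": seeds,
        "n_species_fitted": int(len(species_ids)),
        "n_stations": int(landscape_f.n_stations),
        "n_test_stations": int(len(split.test_station_ids)),
        "comparison": comparison.to_dict(orient="records"),
        "mean_bray_curtis": float(np.nanmean(bc)),
        "richness_dissimilarity": reg,
        "power_recommendation": rec["recommended"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _subset_species(history, species_ix):
    from .simulate import DetectionHistory

    return DetectionHistory(y=history.y[species_ix], design=history.design)


def _subset_history(history, station_ix):
    from .simulate import DetectionHistory, ReplicateDesign

    d = history.design
    sub = ReplicateDesign(
        n_replicates=d.n_replicates[station_ix],
        method=d.method[station_ix],
        time=d.time[station_ix],
    )
    return DetectionHistory(y=history.y[:, station_ix, :], design=sub)


def _subset_landscape(landscape, station_ix):
    from .simulate import Landscape

    return Landscape(
        centre_coords=landscape.centre_coords,
        station_coords=landscape.station_coords[station_ix],
        centre_of_station=landscape.centre_of_station[station_ix],
    )
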