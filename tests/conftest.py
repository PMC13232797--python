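import numpy as np
import pytest

from msocc import model, simulate


@pytest.fixture(scope="session")
def small_nonspatial():
    """A small simulated dataset and its known hyperparameters."""
    hyper = simulate.CommunityHyperParams(
        mu_beta=np.array([-0.3, 0.5]),
        tau_beta=np.array([0.8, 0.3]),
        mu_alpha=np.array([-0.8, 0.6, -0.2]),
        tau_alpha=np.array([0.5, 0.2, 0.1]),
        n_factors=0,
    )
    land = simulate.generate_landscape(8, 15, extent=40_000, seed=10)
    cov = simulate.generate_station_covariates(land, q=1, seed=11)
    params = simulate.draw_community(hyper, n_species=25, seed=12)
    latent = simulate.simulate_occupancy(params, cov, land, seed=13)
    design = simulate.generate_replicate_design(
        land.n_stations, seed=14, fixed_replicates=4
    )
    history = simulate.simulate_detections(latent, params, design, seed=15)
    keep = history.detected_at().any(axis=1)
    history = simulate.DetectionHistory(y=history.y[keep], design=design)
    return {
        "hyper": hyper,
        "landscape": land,
        "covariates": cov,
        "params": params,
        "latent": latent,
        "history": history,
        "kept_species": keep,
    }


@pytest.fixture(scope="session")
def fitted_small(small_nonspatial):
    """A quick non-spatial fit reused by diagnostics/validation tests."""
    spec = model.ModelSpec(n_factors=0, n_iter=1600, n_burn=600, thin=4, seed=20)
    samples = model.fit(
        small_nonspatial["history"],
        covariates=small_nonspatial["covariates"],
        landscape=small_nonspatial["landscape"],
        spec=spec,
    )
    return samples
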