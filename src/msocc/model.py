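"""Bayesian multi-species occupancy model with spatial latent factors.

Model. For species i at station j with replicate k:

    z[i,j]   ~ Bernoulli(psi[i,j]),  logit psi = x_j' beta_i + lam_i' w_j
    y[i,j,k] ~ Bernoulli(z[i,j] * p[i,j,k]),  logit p = v_jk' alpha_i

with community hyperdistributions beta_i ~ N(mu_beta, diag tau_beta),
alpha_i ~ N(mu_alpha, diag tau_alpha) and, for each latent factor q, a
zero-mean unit-variance spatial process w[.,q] with correlation
exp(-phi_q * d). Detections imply presence (no false positives), so any
detection at a station forces z = 1 there. The whole study is treated as a
single closed season.

Inference is a single-chain Gibbs sampler. Logit-Bernoulli conditionals are
made Gaussian by Pólya-Gamma augmentation; the decay rates phi get
Metropolis random-walk updates under a Uniform(3/d_max, 3/d_min) prior.
Factor loadings are identified by the standard lower-triangular constraint
(unit diagonal, zeros above, first ``n_factors`` species as anchors).

Detection-layer augmentation is grouped: replicates sharing a species and a
(method, time) design row share a linear predictor, so their summed
auxiliary variable is drawn as a single PG(n, c) variate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

from .polyagamma import pg_draw, pg_sum_draw
from .simulate import DetectionHistory, Landscape, StationCovariates

__all__ = [
    "Priors",
    "ModelSpec",
    "PosteriorSamples",
    "fit",
    "effective_range",
    "predict_psi",
    "summarize_effects",
]

# Detection design rows for the four (method, time) combinations, coded
# c = 2*point + pm: columns (intercept, point, pm); net/am is the baseline.
V_COMBO = np.array(
    [
        [1.0, 0.0, 0.0],
        [1.0, 0.0, 1.0],
        [1.0, 1.0, 0.0],
        [1.0, 1.0, 1.0],
    ]
)


def effective_range(phi) -> np.ndarray | float:
    """Distance beyond which spatial autocorrelation is negligible, 3/phi."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    out = 3.0 / phi
    return float(out) if out.ndim == 0 else out


@dataclass
class Priors:
    """Hyperprior settings (weakly informative defaults for logit scales).

    ``fixed_mu_*`` / ``fixed_tau_*`` pin the community means/variances at
    known values and skip their updates — species coefficients then have an
    exact Normal prior, which is what the small-instance quadrature oracle
    assumes.
    """

    mu_mean: float = 0.0
    mu_var: float = 2.72
    tau_shape: float = 0.1
    tau_rate: float = 0.1
    loading_scale: float = 1.0
    phi_bounds: tuple | None = None  # default (3/d_max, 3/d_min) from data
    fixed_mu_beta: np.ndarray | None = None
    fixed_tau_beta: np.ndarray | None = None
    fixed_mu_alpha: np.ndarray | None = None
    fixed_tau_alpha: np.ndarray | None = None


@dataclass
class ModelSpec:
    """What to fit and how long to run the chain."""

    occupancy_terms: list | None = None  # station covariate columns; None =
    # intercept-only (ignored when a design matrix is passed to fit)
    n_factors: int = 3
    n_iter: int = 50_000
    n_burn: int = 25_000
    thin: int = 50
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    phi_proposal_sd: float = 0.3  # random-walk sd on log(phi)

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned MCMC draws plus the design information needed to predict."""

    beta: np.ndarray  # (S, n_sp, q_occ)
    alpha: np.ndarray  # (S, n_sp, 3)
    mu_beta: np.ndarray  # (S, q_occ)
    tau_beta: np.ndarray
    mu_alpha: np.ndarray
    tau_alpha: np.ndarray
    lam: np.ndarray  # (S, n_sp, m)
    phi: np.ndarray  # (S, m)
    w: np.ndarray  # (S, n_st, m)
    z: np.ndarray  # (S, n_sp, n_st) int8
    psi: np.ndarray  # (S, n_sp, n_st) float32
    x: np.ndarray  # (n_st, q_occ) occupancy design
    coords: np.ndarray  # (n_st, 2)
    occ_names: tuple = ()
    det_names: tuple = ("intercept", "point", "pm")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_species(self) -> int:
        return self.beta.shape[1]

    def detection_prob_combo(self) -> np.ndarray:
        """(S, n_sp, 4) per-survey detection probability by design combo."""
        return expit(np.einsum("siq,cq->sic", self.alpha, V_COMBO))

    def save(self, path) -> None:
        """Write all draws and design info to a columnar .npz archive."""
        arrays = {
            f: getattr(self, f)
            for f in (
                "beta", "alpha", "mu_beta", "tau_beta", "mu_alpha",
                "tau_alpha", "lam", "phi", "w", "z", "psi", "x", "coords",
            )
        }
        arrays["occ_names"] = np.asarray(self.occ_names)
        arrays["det_names"] = np.asarray(self.det_names)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as npz:
            kwargs = {k: npz[k] for k in npz.files}
        kwargs["occ_names"] = tuple(str(s) for s in kwargs["occ_names"])
        kwargs["det_names"] = tuple(str(s) for s in kwargs["det_names"])
        return cls(**kwargs)


def _combo_index(design) -> np.ndarray:
    return (2 * design.method + design.time).astype(np.int64)


def _detection_sufficients(history: DetectionHistory):
    """Per-station combo counts and per-(species, station, combo) detection
    counts for the grouped detection update."""
    d = history.design
    mask = d.mask()
    combo = _combo_index(d)
    n_st, k_max = mask.shape
    n_sp = history.y.shape[0]
    n_jc = np.zeros((n_st, 4), dtype=np.int64)
    jj, kk = np.nonzero(mask)
    np.add.at(n_jc, (jj, combo[jj, kk]), 1)
    ydet = np.zeros((n_sp, n_st, 4), dtype=np.int32)
    det = history.y == 1
    for c in range(4):
        sel = mask & (combo == c)
        ydet[:, :, c] = (det & sel[None, :, :]).sum(axis=2)
    return n_jc, ydet


def _batched_mvn_draw(prec, b, rng):
    """Draw x ~ N(prec^-1 b, prec^-1) for a batch of small systems."""
    chol = np.linalg.cholesky(prec)
    m1 = np.linalg.solve(chol, b[..., None])[..., 0]
    mean = np.linalg.solve(np.swapaxes(chol, -1, -2), m1[..., None])[..., 0]
    noise = rng.standard_normal(b.shape)
    return mean + np.linalg.solve(np.swapaxes(chol, -1, -2), noise[..., None])[
        ..., 0
    ]


class _SpatialState:
    """Per-factor correlation matrix state (Cholesky, inverse, logdet)."""

    def __init__(self, dists, phi, jitter=1e-6):
        self.dists = dists
        self.jitter = jitter
        self.set_phi(phi)

    def set_phi(self, phi):
        corr = np.exp(-phi * self.dists)
        corr[np.diag_indices_from(corr)] += self.jitter
        self.chol = np.linalg.cholesky(corr)
        self.inv = np.linalg.inv(corr)
        self.logdet = 2.0 * np.log(np.diag(self.chol)).sum()
        self.phi = phi

    def loglik(self, w):
        return -0.5 * (w @ self.inv @ w) - 0.5 * self.logdet


def fit(
    data: DetectionHistory,
    covariates=None,
    landscape: Landscape | None = None,
    spec: ModelSpec | None = None,
    x: np.ndarray | None = None,
    occ_names=None,
    progress: bool = False,
    allow_empty: bool = False,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned posterior draws.

    ``covariates`` may be a StationCovariates (default design: intercept +
    continuous columns) or omitted when ``x`` gives the occupancy design
    matrix directly. Every modelled species must have at least one
    detection (filter first otherwise).
    """
    from .simulate import occupancy_design

    spec = spec or ModelSpec()
    if x is None:
        if covariates is None:
            x = np.ones((data.y.shape[1], 1))
            occ_names = ("intercept",)
        elif isinstance(covariates, StationCovariates):
            x = occupancy_design(covariates)
            occ_names = ("intercept",) + tuple(covariates.continuous_names)
        else:
            x = np.asarray(covariates, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("occupancy design contains non-finite values")
    if occ_names is None:
        occ_names = tuple(f"x{i}" for i in range(x.shape[1]))

    y = data.y
    n_sp, n_st, k_max = y.shape
    if x.shape[0] != n_st:
        raise ValueError("design and detection history disagree on stations")
    det_at = data.detected_at()
    if not allow_empty:
        undetected = np.nonzero(det_at.sum(axis=1) == 0)[0]
        if undetected.size:
            raise ValueError(
                f"species with zero detections cannot be fitted: indices "
                f"{undetected.tolist()}; filter them out first"
            )
        if np.any(data.design.n_replicates < 1):
            raise ValueError("every station needs at least one replicate")

    m = spec.n_factors
    if m > n_sp:
        raise ValueError("n_factors cannot exceed the species count")
    pri = spec.priors
    rng = np.random.default_rng(spec.seed)

    def sub_seed():
        return int(rng.integers(2**31))

    coords = (
        landscape.station_coords
        if landscape is not None
        else np.zeros((n_st, 2))
    )

    n_jc, ydet = _detection_sufficients(data)
    q_occ = x.shape[1]
    q_det = 3

    # --- state ---
    mu_beta = (
        pri.fixed_mu_beta.copy()
        if pri.fixed_mu_beta is not None
        else np.zeros(q_occ)
    )
    tau_beta = (
        pri.fixed_tau_beta.copy()
        if pri.fixed_tau_beta is not None
        else np.ones(q_occ)
    )
    mu_alpha = (
        pri.fixed_mu_alpha.copy()
        if pri.fixed_mu_alpha is not None
        else np.zeros(q_det)
    )
    tau_alpha = (
        pri.fixed_tau_alpha.copy()
        if pri.fixed_tau_alpha is not None
        else np.ones(q_det)
    )
    beta = np.tile(mu_beta, (n_sp, 1))
    alpha = np.tile(mu_alpha, (n_sp, 1))
    z = det_at.astype(np.int8).copy()
    z[:] = np.where(det_at, 1, (rng.random((n_sp, n_st)) < 0.5)).astype(
        np.int8
    )

    lam = np.zeros((n_sp, m))
    w = np.zeros((n_st, m))
    spatial = []
    if m:
        for q_ in range(min(m, n_sp)):
            lam[q_, q_] = 1.0
        dists = cdist(coords, coords)
        pos = dists[dists > 0]
        if pri.phi_bounds is not None:
            phi_lo, phi_hi = pri.phi_bounds
        else:
            phi_lo, phi_hi = 3.0 / pos.max(), 3.0 / pos.min()
        phi = np.full(m, np.sqrt(phi_lo * phi_hi))
        w = rng.standard_normal((n_st, m))
        spatial = [_SpatialState(dists, phi[q_]) for q_ in range(m)]
    else:
        phi = np.empty(0)

    n_keep = spec.n_samples
    S = dict(
        beta=np.empty((n_keep, n_sp, q_occ)),
        alpha=np.empty((n_keep, n_sp, q_det)),
        mu_beta=np.empty((n_keep, q_occ)),
        tau_beta=np.empty((n_keep, q_occ)),
        mu_alpha=np.empty((n_keep, q_det)),
        tau_alpha=np.empty((n_keep, q_det)),
        lam=np.empty((n_keep, n_sp, m)),
        phi=np.empty((n_keep, m)),
        w=np.empty((n_keep, n_st, m)),
        z=np.empty((n_keep, n_sp, n_st), dtype=np.int8),
        psi=np.empty((n_keep, n_sp, n_st), dtype=np.float32),
    )
    keep = 0

    free_all = np.tril(np.ones((n_sp, m), dtype=bool), k=-1) if m else None

    iterator = range(spec.n_iter)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="mcmc")

    for it in iterator:
        # linear predictors
        eta_occ = x @ beta.T + (w @ lam.T if m else 0.0)  # (n_st, n_sp)
        psi_t = expit(eta_occ)  # (n_st, n_sp)
        eta_det = alpha @ V_COMBO.T  # (n_sp, 4)
        log1mp = -np.logaddexp(0.0, eta_det)  # log(1 - p) per combo
        log_prod_nodet = log1mp @ n_jc.T  # (n_sp, n_st)

        # z | rest (detections force z = 1)
        num = psi_t.T * np.exp(log_prod_nodet)
        pz = num / (num + (1.0 - psi_t.T))
        z = (rng.random((n_sp, n_st)) < pz).astype(np.int8)
        z[det_at] = 1

        # occupancy layer: PG weights and beta
        omega = pg_draw(eta_occ, sub_seed())  # (n_st, n_sp)
        offset = w @ lam.T if m else np.zeros_like(eta_occ)
        resid = z.T - 0.5 - omega * offset  # (n_st, n_sp)
        prec = np.einsum("jp,ji,jq->ipq", x, omega, x)
        prec[:, np.arange(q_occ), np.arange(q_occ)] += 1.0 / tau_beta
        b = x.T @ resid  # (q_occ, n_sp)
        b = b.T + mu_beta / tau_beta
        beta = _batched_mvn_draw(prec, b, rng)

        if m:
            xb = x @ beta.T  # (n_st, n_sp)
            # loadings (free lower-triangular entries)
            ls2 = pri.loading_scale**2
            if n_sp > m:
                idx = np.arange(m, n_sp)
                om = omega[:, idx]  # (n_st, |idx|)
                prec_l = np.einsum("jp,js,jq->spq", w, om, w)
                prec_l[:, np.arange(m), np.arange(m)] += 1.0 / ls2
                resid_l = z[idx].T - 0.5 - om * xb[:, idx]
                b_l = (w.T @ resid_l).T
                lam[idx] = _batched_mvn_draw(prec_l, b_l, rng)
            for i in range(1, min(m, n_sp)):
                wf = w[:, :i]
                om = omega[:, i]
                off_i = xb[:, i] + w[:, i]  # unit diagonal loading
                a_i = wf.T @ (wf * om[:, None]) + np.eye(i) / ls2
                b_i = wf.T @ (z[i] - 0.5 - om * off_i)
                lam[i, :i] = _batched_mvn_draw(
                    a_i[None], b_i[None], rng
                )[0]

            # factor values w, one factor at a time
            eta_fac = w @ lam.T  # (n_st, n_sp)
            for q_ in range(m):
                eta_minus = eta_fac - np.outer(w[:, q_], lam[:, q_])
                s_diag = omega @ (lam[:, q_] ** 2)
                prec_w = spatial[q_].inv + np.diag(s_diag)
                r = (z.T - 0.5 - omega * (xb + eta_minus)) @ lam[:, q_]
                chol = np.linalg.cholesky(prec_w)
                mean = np.linalg.solve(
                    chol.T, np.linalg.solve(chol, r)
                )
                w[:, q_] = mean + np.linalg.solve(
                    chol.T, rng.standard_normal(n_st)
                )
                eta_fac = eta_minus + np.outer(w[:, q_], lam[:, q_])

            # phi: random walk on log scale within the uniform prior box
            for q_ in range(m):
                cur = spatial[q_]
                prop = np.exp(
                    np.log(cur.phi)
                    + spec.phi_proposal_sd * rng.standard_normal()
                )
                if not (phi_lo <= prop <= phi_hi):
                    continue
                trial = _SpatialState(dists, prop, jitter=cur.jitter)
                # log-jacobian of the log-walk: log(prop) - log(cur)
                logr = (
                    trial.loglik(w[:, q_])
                    - cur.loglik(w[:, q_])
                    + np.log(prop)
                    - np.log(cur.phi)
                )
                if np.log(rng.random()) < logr:
                    spatial[q_] = trial
                    phi[q_] = prop

        # detection layer: grouped PG weights and alpha
        n_eff = z @ n_jc  # (n_sp, 4) replicate slots at occupied stations
        dcount = np.einsum("ij,ijc->ic", z, ydet)
        om_sum = pg_sum_draw(n_eff, eta_det, sub_seed())  # (n_sp, 4)
        prec_a = np.einsum("ic,cp,cq->ipq", om_sum, V_COMBO, V_COMBO)
        prec_a[:, np.arange(q_det), np.arange(q_det)] += 1.0 / tau_alpha
        b_a = (dcount - 0.5 * n_eff) @ V_COMBO + mu_alpha / tau_alpha
        alpha = _batched_mvn_draw(prec_a, b_a, rng)

        # community hyperparameters
        if pri.fixed_mu_beta is None:
            prec_mu = n_sp / tau_beta + 1.0 / pri.mu_var
            mean_mu = (beta.sum(axis=0) / tau_beta + pri.mu_mean / pri.mu_var) / prec_mu
            mu_beta = mean_mu + rng.standard_normal(q_occ) / np.sqrt(prec_mu)
        if pri.fixed_tau_beta is None:
            sse = ((beta - mu_beta) ** 2).sum(axis=0)
            tau_beta = 1.0 / rng.gamma(
                pri.tau_shape + 0.5 * n_sp, 1.0 / (pri.tau_rate + 0.5 * sse)
            )
        if pri.fixed_mu_alpha is None:
            prec_mu = n_sp / tau_alpha + 1.0 / pri.mu_var
            mean_mu = (alpha.sum(axis=0) / tau_alpha + pri.mu_mean / pri.mu_var) / prec_mu
            mu_alpha = mean_mu + rng.standard_normal(q_det) / np.sqrt(prec_mu)
        if pri.fixed_tau_alpha is None:
            sse = ((alpha - mu_alpha) ** 2).sum(axis=0)
            tau_alpha = 1.0 / rng.gamma(
                pri.tau_shape + 0.5 * n_sp, 1.0 / (pri.tau_rate + 0.5 * sse)
            )

        if it >= spec.n_burn and (it - spec.n_burn) % spec.thin == 0:
            if keep < n_keep:
                eta_now = x @ beta.T + (w @ lam.T if m else 0.0)
                S["beta"][keep] = beta
                S["alpha"][keep] = alpha
                S["mu_beta"][keep] = mu_beta
                S["tau_beta"][keep] = tau_beta
                S["mu_alpha"][keep] = mu_alpha
                S["tau_alpha"][keep] = tau_alpha
                S["lam"][keep] = lam
                S["phi"][keep] = phi
                S["w"][keep] = w
                S["z"][keep] = z
                S["psi"][keep] = expit(eta_now).T.astype(np.float32)
                keep += 1

    return PosteriorSamples(
        x=x, coords=np.asarray(coords, dtype=float), occ_names=tuple(occ_names), **S
    )


def predict_psi(
    samples: PosteriorSamples,
    x_new: np.ndarray,
    coords_new: np.ndarray | None = None,
    seed: int = 0,
):
    """Posterior draws of psi and z at unfitted stations.

    Spatial factors at new locations are drawn from their conditional
    Gaussian given each draw's factor values at the fitted stations
    (simple kriging under the draw's phi). Returns (psi, z) with shape
    (S, n_species, n_new).
    """
    rng = np.random.default_rng(seed)
    x_new = np.asarray(x_new, dtype=float)
    n_new = x_new.shape[0]
    S, n_sp, _ = samples.beta.shape
    m = samples.lam.shape[2]
    psi = np.empty((S, n_sp, n_new), dtype=np.float32)
    z = np.empty((S, n_sp, n_new), dtype=np.int8)
    if m:
        if coords_new is None:
            raise ValueError("spatial model prediction needs coordinates")
        d_no = cdist(coords_new, samples.coords)
        d_nn = cdist(coords_new, coords_new)
    for s in range(S):
        eta = x_new @ samples.beta[s].T  # (n_new, n_sp)
        if m:
            for q_ in range(m):
                ph = samples.phi[s, q_]
                c_no = np.exp(-ph * d_no)
                c_oo_inv = np.linalg.inv(
                    np.exp(-ph * cdist(samples.coords, samples.coords))
                    + 1e-6 * np.eye(samples.coords.shape[0])
                )
                a = c_no @ c_oo_inv
                mean = a @ samples.w[s, :, q_]
                cov = np.exp(-ph * d_nn) - a @ c_no.T
                cov[np.diag_indices_from(cov)] += 1e-8
                w_new = mean + np.linalg.cholesky(cov) @ rng.standard_normal(
                    n_new
                )
                eta = eta + np.outer(w_new, samples.lam[s, :, q_])
        ps = expit(eta).T
        psi[s] = ps
        z[s] = (rng.random(ps.shape) < ps).astype(np.int8)
    return psi, z


def summarize_effects(
    samples: PosteriorSamples, kind: str = "detection", contrast: str | None = None
):
    """Posterior summaries of a category's probability vs its baseline.

    Per draw and species, the relevant offset coefficient is added to the
    baseline intercept on the logit scale and inverse-logit transformed;
    the summary reports the posterior median and 95% credible interval
    (2.5%/97.5% quantiles) per species plus the community mean.
    """
    import pandas as pd

    if kind == "detection":
        draws, names = samples.alpha, samples.det_names
    elif kind == "occupancy":
        draws, names = samples.beta, samples.occ_names
    else:
        raise ValueError("kind must be 'detection' or 'occupancy'")
    eta = draws[:, :, 0].copy()
    if contrast is not None:
        if contrast not in names:
            raise ValueError(
                f"unknown contrast {contrast!r}; available: {names[1:]}"
            )
        eta = eta + draws[:, :, names.index(contrast)]
    prob = expit(eta)  # (S, n_sp)
    qs = np.quantile(prob, [0.025, 0.5, 0.975], axis=0)
    rows = pd.DataFrame(
        {
            "species": np.arange(prob.shape[1]),
            "median": qs[1],
            "lo": qs[0],
            "hi": qs[2],
        }
    )
    comm = np.quantile(prob.mean(axis=1), [0.025, 0.5, 0.975])
    summary = {"community_lo": comm[0], "community_median": comm[1], "community_hi": comm[2]}
    return rows, summary
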