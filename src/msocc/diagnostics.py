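"""Chain convergence diagnostics, WAIC and posterior-predictive checks.

The conventions follow standard single-chain MCMC practice: the Geweke
statistic compares the first 10% of a chain with the last 50% using
spectral-density variance estimates; effective sample size uses the initial
positive autocorrelation sum; WAIC marginalizes the latent occupancy state
analytically per species-station unit; the Bayesian p-value compares
chi-squared discrepancies of binned detection counts between observed and
replicated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PosteriorSamples, V_COMBO, _detection_sufficients
from .simulate import DetectionHistory

__all__ = [
    "geweke_z",
    "effective_sample_size",
    "WAICResult",
    "waic",
    "posterior_predictive_check",
    "convergence",
]


def _spectral0(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero (Newey-West/Bartlett)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    lag = min(n - 1, max(1, int(2 * n ** (1 / 3))))
    acov = np.array([x[: n - k] @ x[k:] / n for k in range(lag + 1)])
    weights = 1.0 - np.arange(1, lag + 1) / (lag + 1)
    return float(acov[0] + 2.0 * (weights * acov[1:]).sum())


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score between early and late chain segments."""
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    a = chain[: int(first * n)]
    b = chain[int((1 - last) * n):]
    if a.size < 2 or b.size < 2:
        raise ValueError("chain too short for the Geweke diagnostic")
    va, vb = _spectral0(a), _spectral0(b)
    denom = np.sqrt(va / a.size + vb / b.size)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def effective_sample_size(chain: np.ndarray) -> tuple[float, bool]:
    """ESS from the initial-positive autocorrelation sum.

    Returns (ess, zero_variance_flag); a constant chain reports its length
    with the flag set.
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    v = chain.var()
    if v == 0 or n < 3:
        return float(n), True
    x = chain - chain.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    # truncate at the first non-positive paired sum (Geyer)
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(n / tau), False


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    flagged_units: list = field(default_factory=list)


def _unit_loglik(samples: PosteriorSamples, data: DetectionHistory) -> np.ndarray:
    """(S, n_sp, n_st) log-likelihood with z marginalized analytically:
    L = psi * prod_k Bern(y | p) + (1 - psi) * 1[all y = 0]."""
    n_jc, ydet = _detection_sufficients(data)
    no_det = ~data.detected_at()  # (n_sp, n_st)
    S = samples.n_samples
    out = np.empty((S, ydet.shape[0], ydet.shape[1]))
    for s in range(S):
        eta = samples.alpha[s] @ V_COMBO.T  # (n_sp, 4)
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        ll_det = np.einsum("ijc,ic->ij", ydet, logp) + np.einsum(
            "jc,ic->ij", n_jc, log1mp
        ) - np.einsum("ijc,ic->ij", ydet, log1mp)
        psi = samples.psi[s].astype(float)
        lik = psi * np.exp(ll_det) + (1.0 - psi) * no_det
        out[s] = np.log(np.maximum(lik, 1e-300))
    return out


def waic(samples: PosteriorSamples, data: DetectionHistory) -> WAICResult:
    """Widely applicable information criterion over species-station units.

    lppd = sum log mean_s L, p_waic = sum var_s log L,
    WAIC = -2 (lppd - p_waic).
    """
    if samples.n_samples < 2:
        raise ValueError("WAIC needs at least 2 posterior samples")
    ll = _unit_loglik(samples, data)
    # log mean exp, stabilized
    mx = ll.max(axis=0)
    lppd_units = mx + np.log(np.mean(np.exp(ll - mx), axis=0))
    p_units = ll.var(axis=0, ddof=1)
    flagged = [
        (int(i), int(j)) for i, j in zip(*np.nonzero(lppd_units <= np.log(1e-290)))
    ]
    lppd = float(lppd_units.sum())
    p_waic = float(p_units.sum())
    return WAICResult(lppd, p_waic, -2.0 * (lppd - p_waic), flagged)


def posterior_predictive_check(
    samples: PosteriorSamples,
    data: DetectionHistory,
    bin_size: int = 10,
    seed: int = 0,
):
    """Bayesian p-value from chi-squared discrepancies of binned detections.

    For each posterior draw, replicate detection data are simulated from the
    draw's (z, p); detection counts per species are summed within station
    bins (consecutive groups of ``bin_size`` stations) and compared with
    their expectation under the draw via a chi-squared discrepancy. The
    p-value is the fraction of draws whose replicated discrepancy exceeds
    the observed one (ties count half).

    Returns (overall_p, per_species_p).
    """
    rng = np.random.default_rng(seed)
    n_jc, ydet = _detection_sufficients(data)
    n_sp, n_st = ydet.shape[0], ydet.shape[1]
    obs_counts = ydet.sum(axis=2)  # (n_sp, n_st)
    n_bins = max(1, n_st // bin_size)
    bins = np.array_split(np.arange(n_st), n_bins)
    S = samples.n_samples
    exceed = np.zeros(n_sp)
    exceed_tot = 0.0
    eps = 1e-10
    for s in range(S):
        p = expit(samples.alpha[s] @ V_COMBO.T)  # (n_sp, 4)
        z = samples.z[s].astype(float)
        e_counts = z * (p @ n_jc.T)  # (n_sp, n_st)
        rep = rng.binomial(
            n_jc[None, :, :], p[:, None, :] * samples.z[s][:, :, None]
        ).sum(axis=2)
        chi_obs = np.zeros(n_sp)
        chi_rep = np.zeros(n_sp)
        for b in bins:
            e_b = e_counts[:, b].sum(axis=1)
            o_b = obs_counts[:, b].sum(axis=1)
            r_b = rep[:, b].sum(axis=1)
            chi_obs += (o_b - e_b) ** 2 / (e_b + eps)
            chi_rep += (r_b - e_b) ** 2 / (e_b + eps)
        exceed += (chi_rep > chi_obs) + 0.5 * (chi_rep == chi_obs)
        tot_o, tot_r = chi_obs.sum(), chi_rep.sum()
        exceed_tot += (tot_r > tot_o) + 0.5 * (tot_r == tot_o)
    return float(exceed_tot / S), exceed / S


def convergence(
    samples: PosteriorSamples, z_threshold: float = 1.96, min_ess: float = 100.0
):
    """Geweke z and ESS for every stored parameter chain.

    Returns (table, summary): a DataFrame with one row per scalar parameter
    and a dict with the share of parameters passing the Geweke gate, the
    median ESS, and whether both configured gates pass.
    """
    if samples.n_samples < 100:
        raise ValueError("convergence diagnostics need >= 100 samples")
    chains = {}
    S = samples.n_samples
    for name, arr in (
        ("beta", samples.beta),
        ("alpha", samples.alpha),
        ("lam", samples.lam),
        ("mu_beta", samples.mu_beta),
        ("tau_beta", samples.tau_beta),
        ("mu_alpha", samples.mu_alpha),
        ("tau_alpha", samples.tau_alpha),
        ("phi", samples.phi),
    ):
        flat = arr.reshape(S, -1)
        for c in range(flat.shape[1]):
            chains[f"{name}[{c}]"] = flat[:, c]
    rows = []
    for name, chain in chains.items():
        ess, flag = effective_sample_size(chain)
        z = 0.0 if flag else geweke_z(chain)
        rows.append((name, z, ess, flag))
    table = pd.DataFrame(rows, columns=["parameter", "geweke_z", "ess", "zero_variance"])
    live = table[~table["zero_variance"]]
    share = float((live["geweke_z"].abs() < z_threshold).mean()) if len(live) else 1.0
    med_ess = float(live["ess"].median()) if len(live) else float(S)
    summary = {
        "geweke_pass_share": share,
        "median_ess": med_ess,
        "converged": share >= 0.75 and med_ess >= min_ess,
    }
    return table, summary
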