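"""Power to detect proportional occupancy declines between two surveys.

Follows the closed-form design method for single-season occupancy studies:
the asymptotic variance of the occupancy MLE with S stations and K
replicates at per-survey detection probability p is

    var(psi_hat) = psi/S * [ (1 - psi) + (1 - p*) / (p* - K p (1-p)^(K-1)) ]

with p* = 1 - (1-p)^K, and the power of a two-sided Wald test comparing two
occasions (psi1 vs psi2 = psi1 (1 - R)) is

    power = Phi(D/se - z*) + Phi(-D/se - z*),  D = psi1 - psi2,
    se = sqrt(var1 + var2).

A Monte-Carlo oracle (simulate both occasions, fit the occupancy MLE, apply
the same Wald test) verifies the approximation. K = 1 designs are refused by
the closed form — with a single replicate, occupancy and detection are
confounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .validation import cumulative_detection

__all__ = [
    "PowerQuery",
    "occupancy_mle_variance",
    "wald_power",
    "mc_power",
    "community_mean_power",
    "effort_grid",
    "min_effort_for_target",
]


@dataclass
class PowerQuery:
    psi1: float
    R: float  # proportional reduction; psi2 = psi1 * (1 - R)
    p: float
    S: int
    K: int
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.psi1 < 1:
            raise ValueError("psi1 must be in (0, 1)")
        if not 0 <= self.R < 1:
            raise ValueError("R must be in [0, 1)")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.S < 1 or self.K < 1:
            raise ValueError("S and K must be >= 1")


class IdentifiabilityError(ValueError):
    """Raised when the closed-form variance is undefined (e.g. K = 1)."""


def occupancy_mle_variance(psi: float, p: float, S: int, K: int) -> float:
    """Asymptotic variance of the occupancy MLE for an S x K design."""
    if K < 2:
        raise IdentifiabilityError(
            "K = 1 confounds occupancy and detection; the closed-form "
            "variance needs K >= 2 (use mc_power for single-replicate designs)"
        )
    p_star = float(cumulative_detection(p, K))
    denom = p_star - K * p * (1.0 - p) ** (K - 1)
    if denom <= 0:
        raise IdentifiabilityError(
            f"non-positive information denominator ({denom:.3g}) at p={p}, K={K}"
        )
    return psi / S * ((1.0 - psi) + (1.0 - p_star) / denom)


def wald_power(query: PowerQuery) -> float:
    """Closed-form power of the two-sided Wald test for a decline of R."""
    psi2 = query.psi1 * (1.0 - query.R)
    var1 = occupancy_mle_variance(query.psi1, query.p, query.S, query.K)
    var2 = occupancy_mle_variance(psi2, query.p, query.S, query.K)
    delta = query.psi1 - psi2
    se = np.sqrt(var1 + var2)
    zstar = norm.ppf(1.0 - query.alpha / 2.0)
    return float(norm.cdf(delta / se - zstar) + norm.cdf(-delta / se - zstar))


def _occupancy_mle(detections_per_station: np.ndarray, K: int):
    """ML estimate of (psi, p) from per-station detection counts.

    Profile likelihood in p; psi maximised analytically given p. Returns
    (psi_hat, p_hat, converged).
    """
    d = np.asarray(detections_per_station)
    S = d.size
    n_det = int((d > 0).sum())
    if n_det == 0:
        return 0.0, 0.5, True
    if n_det == S and np.all(d == K):
        return 1.0, 1.0, True
    total_det = int(d.sum())
    sum_k_minus_d = int((K - d[d > 0]).sum())

    def psi_given_p(p):
        q0 = (1.0 - p) ** K
        if q0 >= 1.0:
            return 1e-9
        # maximise n_det*log(psi) + (S-n_det)*log(psi*q0 + 1 - psi)
        psi = min(1.0, n_det / (S * (1.0 - q0)))
        return min(max(psi, 1e-9), 1 - 1e-12)

    def negll(logit_p):
        p = 1.0 / (1.0 + np.exp(-logit_p))
        psi = psi_given_p(p)
        q0 = (1.0 - p) ** K
        ll = (
            n_det * np.log(psi)
            + total_det * np.log(p)
            + sum_k_minus_d * np.log1p(-p)
            + (S - n_det) * np.log(psi * q0 + 1.0 - psi)
        )
        return -ll

    res = minimize_scalar(negll, bounds=(-10, 10), method="bounded")
    p_hat = 1.0 / (1.0 + np.exp(-res.x))
    return float(psi_given_p(p_hat)), float(p_hat), bool(res.success)


def mc_power(
    query: PowerQuery, n_sims: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo power: simulate both occasions, fit the occupancy MLE,
    apply the two-sided Wald test. Returns (power, binomial SE)."""
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    psi2 = query.psi1 * (1.0 - query.R)
    zstar = norm.ppf(1.0 - query.alpha / 2.0)
    reject = 0
    resampled = 0
    done = 0
    while done < n_sims:
        est = []
        ok = True
        for psi in (query.psi1, psi2):
            z = rng.random(query.S) < psi
            d = rng.binomial(query.K, query.p, size=query.S) * z
            psi_hat, p_hat, conv = _occupancy_mle(d, query.K)
            if not conv:
                ok = False
                break
            # plug-in variance at the estimates; guard degenerate fits
            try:
                v = occupancy_mle_variance(
                    min(max(psi_hat, 1e-6), 1 - 1e-6),
                    min(max(p_hat, 1e-6), 1 - 1e-6),
                    query.S,
                    query.K,
                )
            except IdentifiabilityError:
                ok = False
                break
            est.append((psi_hat, v))
        if not ok:
            resampled += 1
            if resampled > 10 * n_sims:
                raise RuntimeError("MLE failed to converge in most replicates")
            continue
        (e1, v1), (e2, v2) = est
        stat = (e1 - e2) / np.sqrt(max(v1 + v2, 1e-12))
        reject += abs(stat) > zstar
        done += 1
    power = reject / n_sims
    # shrunk (add-half) proportion for the SE so boundary estimates (0 or 1
    # rejections) still report a non-degenerate uncertainty
    pt = (reject + 0.5) / (n_sims + 1.0)
    return float(power), float(np.sqrt(pt * (1.0 - pt) / n_sims))


def community_mean_power(species_params, R, S, K, alpha=0.05):
    """Mean closed-form power across species.

    ``species_params``: iterable of (psi1, p) pairs. Species whose design is
    non-identifiable are reported with NaN power and excluded from the mean;
    if every species is infeasible an error is raised. Returns
    (mean_power, per_species_array).
    """
    powers = []
    for psi1, p in species_params:
        try:
            powers.append(
                wald_power(PowerQuery(psi1=psi1, R=R, p=p, S=S, K=K, alpha=alpha))
            )
        except IdentifiabilityError:
            powers.append(np.nan)
    powers = np.asarray(powers)
    if np.all(np.isnan(powers)):
        raise IdentifiabilityError(
            "no species has an identifiable design at this (S, K)"
        )
    return float(np.nanmean(powers)), powers


def effort_grid(
    species_params, R_values, station_counts, replicate_counts, alpha=0.05
):
    """Mean community power per (R, S, K) cell.

    Returns a tidy table (list of dicts) with columns R, S, K,
    total_surveys, mean_power; infeasible cells carry NaN power.
    """
    if not (len(station_counts) and len(replicate_counts) and len(R_values)):
        raise ValueError("grids must be non-empty")
    rows = []
    for R in R_values:
        for S in station_counts:
            for K in replicate_counts:
                try:
                    mean_p, _ = community_mean_power(
                        species_params, R, S, K, alpha
                    )
                except IdentifiabilityError:
                    mean_p = np.nan
                rows.append(
                    {
                        "R": R,
                        "S": int(S),
                        "K": int(K),
                        "total_surveys": int(S) * int(K),
                        "mean_power": mean_p,
                    }
                )
    return rows


def min_effort_for_target(
    species_params,
    R,
    target_power,
    station_counts,
    replicate_counts,
    alpha=0.05,
):
    """Smallest total-survey design meeting the target mean power.

    Enumerates the (S, K) ranges, keeps cells whose mean power reaches
    ``target_power`` and returns a dict with the feasible cells and the
    minimal S*K cell (ties broken towards smaller K). If nothing is
    feasible, returns the best cell found with ``feasible=[]``.
    """
    if not 0 <= target_power < 1:
        raise ValueError("target_power must be in [0, 1)")
    grid = effort_grid(
        species_params, [R], station_counts, replicate_counts, alpha
    )
    feasible = [
        g for g in grid if np.isfinite(g["mean_power"]) and g["mean_power"] >= target_power
    ]
    best_any = max(
        (g for g in grid if np.isfinite(g["mean_power"])),
        key=lambda g: g["mean_power"],
        default=None,
    )
    if not feasible:
        return {
            "target_power": target_power,
            "R": R,
            "feasible": [],
            "recommended": None,
            "best_infeasible": best_any,
        }
    recommended = min(feasible, key=lambda g: (g["total_surveys"], g["K"]))
    return {
        "target_power": target_power,
        "R": R,
        "feasible": feasible,
        "recommended": recommended,
        "best_infeasible": None,
    }
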