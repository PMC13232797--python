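"""Detection-conditioned community validation.

The evaluation mirrors a centre-stratified holdout: a fixed number of
well-replicated stations per field centre are withheld, the model predicts
each posterior sample's occupied community at those stations, detection is
layered on through the cumulative per-station detection probability
p* = 1 - (1 - p)^n (n = replicates actually performed), and the predicted
detected communities are compared with the observed ones by per-species
AUC, species-accumulation curves and presence/absence Bray-Curtis
dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .model import PosteriorSamples, V_COMBO, predict_psi
from .simulate import DetectionHistory

__all__ = [
    "HoldoutSplit",
    "CommunityPrediction",
    "make_split",
    "cumulative_detection",
    "predict_detected_community",
    "species_auc",
    "accumulation_curves",
    "bray_curtis",
    "richness_dissimilarity_regression",
    "station_bray_curtis",
]


@dataclass
class HoldoutSplit:
    train_station_ids: np.ndarray
    test_station_ids: np.ndarray
    per_centre: int
    min_replicates: int


@dataclass
class CommunityPrediction:
    """Per posterior sample simulated detected communities at test stations.

    ``score`` is the continuous ranking score mean_s(psi * z * p_total);
    ``detected`` are the per-sample binomial detection events (S, n_sp,
    n_test); ``p_total`` the cumulative detection probability per species
    and station under the posterior-mean detection coefficients.
    """

    station_ids: np.ndarray
    score: np.ndarray  # (n_sp, n_test)
    detected: np.ndarray  # (S, n_sp, n_test) int8
    p_total: np.ndarray  # (n_sp, n_test)
    psi: np.ndarray  # (S, n_sp, n_test)
    z: np.ndarray  # (S, n_sp, n_test)


def make_split(
    data: DetectionHistory,
    centre_of_station: np.ndarray,
    per_centre: int = 2,
    min_replicates: int = 3,
    seed: int = 0,
) -> HoldoutSplit:
    """Withhold ``per_centre`` stations per centre among those surveyed at
    least ``min_replicates`` times. Centres with too few qualifying stations
    contribute all they have (with a warning)."""
    rng = np.random.default_rng(seed)
    n_rep = data.design.n_replicates
    test = []
    for c in np.unique(centre_of_station):
        eligible = np.nonzero(
            (centre_of_station == c) & (n_rep >= min_replicates)
        )[0]
        if eligible.size < per_centre:
            if per_centre > 0:
                warnings.warn(
                    f"centre {c}: only {eligible.size} stations with "
                    f">= {min_replicates} replicates; taking all",
                    stacklevel=2,
                )
            chosen = eligible
        else:
            chosen = rng.choice(eligible, size=per_centre, replace=False)
        test.extend(chosen.tolist())
    test = np.sort(np.asarray(test, dtype=int))
    train = np.setdiff1d(np.arange(n_rep.size), test)
    return HoldoutSplit(train, test, per_centre, min_replicates)


def cumulative_detection(p, n):
    """Probability of at least one detection in n replicates: 1 - (1-p)^n."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** np.asarray(n)


def predict_detected_community(
    samples: PosteriorSamples,
    split: HoldoutSplit,
    data: DetectionHistory,
    x_all: np.ndarray,
    coords_all: np.ndarray | None = None,
    seed: int = 0,
    per_sample_p: bool = False,
) -> CommunityPrediction:
    """Simulate detected communities at the held-out stations.

    For each posterior sample, psi and z are drawn at the test stations
    (kriged spatial factors for spatial models); the per-survey detection
    probability uses the posterior-mean detection coefficients by default
    (``per_sample_p=True`` switches to per-draw coefficients) combined over
    each station's performed replicates into p_total; a Bernoulli(p_total)
    event then yields the simulated detected indicator z * event. The
    continuous ranking score is mean over samples of psi * z * p_total.
    """
    rng = np.random.default_rng(seed)
    test = np.asarray(split.test_station_ids, dtype=int)
    n_rep = data.design.n_replicates[test]
    if np.any(n_rep == 0):
        keep = n_rep > 0
        warnings.warn(
            f"excluding {int((~keep).sum())} test stations with zero replicates",
            stacklevel=2,
        )
        test = test[keep]
        n_rep = n_rep[keep]

    psi, z = predict_psi(
        samples,
        x_all[test],
        None if coords_all is None else coords_all[test],
        seed=int(rng.integers(2**31)),
    )
    S, n_sp, n_test = psi.shape

    # cumulative detection from each station's actual replicate covariates
    mask = data.design.mask()[test]  # (n_test, k_max)
    v = data.design.detection_design()[test]  # (n_test, k_max, 3)

    def p_total_from(alpha):
        eta = np.einsum("jkq,iq->ijk", v, alpha)
        log1mp = -np.logaddexp(0.0, eta)
        log_nodet = np.where(mask[None, :, :], log1mp, 0.0).sum(axis=2)
        return 1.0 - np.exp(log_nodet)  # (n_sp, n_test)

    if per_sample_p:
        detected = np.empty((S, n_sp, n_test), dtype=np.int8)
        score_acc = np.zeros((n_sp, n_test))
        for s in range(S):
            pt = p_total_from(samples.alpha[s])
            event = (rng.random(pt.shape) < pt).astype(np.int8)
            detected[s] = z[s] * event
            score_acc += psi[s] * z[s] * pt
        p_total = p_total_from(samples.alpha.mean(axis=0))
        score = score_acc / S
    else:
        p_total = p_total_from(samples.alpha.mean(axis=0))
        event = (rng.random((S, n_sp, n_test)) < p_total[None]).astype(np.int8)
        detected = (z * event).astype(np.int8)
        score = (psi * z).mean(axis=0) * p_total
    return CommunityPrediction(
        station_ids=test,
        score=score,
        detected=detected,
        p_total=p_total,
        psi=psi,
        z=z,
    )


def species_auc(scores: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Rank-based (Mann-Whitney) AUC per species, ties at half credit.

    ``scores``: (n_sp, n_stations) continuous; ``observed``: same-shape 0/1.
    Species without both a positive and a negative station get NaN.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed)
    n_sp = scores.shape[0]
    out = np.full(n_sp, np.nan)
    for i in range(n_sp):
        pos = observed[i] == 1
        n1, n0 = int(pos.sum()), int((~pos).sum())
        if n1 == 0 or n0 == 0:
            continue
        r = rankdata(scores[i])
        u = r[pos].sum() - n1 * (n1 + 1) / 2
        out[i] = u / (n1 * n0)
    return out


def bray_curtis(observed_list, predicted_list) -> float:
    """Presence/absence Bray-Curtis: 1 - 2|A∩B| / (|A| + |B|)."""
    a, b = set(observed_list), set(predicted_list)
    if not a and not b:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def station_bray_curtis(
    prediction: CommunityPrediction, observed: np.ndarray
) -> np.ndarray:
    """Mean over posterior samples of per-station Bray-Curtis dissimilarity
    between the observed and simulated detected species lists.

    Stations where both lists are empty in a sample contribute NaN to the
    mean for that sample.
    """
    S = prediction.detected.shape[0]
    n_test = prediction.detected.shape[2]
    obs = np.asarray(observed, dtype=bool)
    out = np.zeros(n_test)
    counts = np.zeros(n_test)
    for s in range(S):
        pred = prediction.detected[s].astype(bool)
        shared = (obs & pred).sum(axis=0)
        sizes = obs.sum(axis=0) + pred.sum(axis=0)
        ok = sizes > 0
        out[ok] += 1.0 - 2.0 * shared[ok] / sizes[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, out / np.maximum(counts, 1), np.nan)


def accumulation_curves(
    observed: np.ndarray,
    predicted: np.ndarray | None = None,
    n_permutations: int = 100,
    seed: int = 0,
):
    """Species-accumulation curves with ±2SD envelopes.

    ``observed``: (n_sp, n_stations) 0/1 detected indicators; stations are
    accumulated in ``n_permutations`` random orders and distinct species
    counted. ``predicted``: (S, n_sp, n_stations) simulated detected
    indicators, accumulated per posterior sample (station order permuted per
    sample). Returns a dict with mean and sd arrays of length n_stations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    obs = np.asarray(observed, dtype=bool)
    n_sp, n_st = obs.shape

    def accumulate(mat, order):
        seen = np.zeros(n_sp, dtype=bool)
        out = np.empty(n_st)
        for t, j in enumerate(order):
            seen |= mat[:, j]
            out[t] = seen.sum()
        return out

    obs_curves = np.array(
        [accumulate(obs, rng.permutation(n_st)) for _ in range(n_permutations)]
    )
    result = {
        "observed_mean": obs_curves.mean(axis=0),
        "observed_sd": obs_curves.std(axis=0),
    }
    if predicted is not None:
        pred = np.asarray(predicted, dtype=bool)
        pred_curves = np.array(
            [
                accumulate(pred[s], rng.permutation(n_st))
                for s in range(pred.shape[0])
            ]
        )
        result["predicted_mean"] = pred_curves.mean(axis=0)
        result["predicted_sd"] = pred_curves.std(axis=0)
    return result


def within_station_accumulation(y_station: np.ndarray) -> np.ndarray:
    """Observed accumulation over replicates at one station.

    ``y_station``: (n_sp, n_replicates) 0/1; needs >= 2 replicates.
    """
    y = np.asarray(y_station)
    if y.shape[1] < 2:
        raise ValueError("within-station accumulation needs >= 2 replicates")
    return np.maximum.accumulate(y == 1, axis=1).sum(axis=0).astype(float)


def richness_dissimilarity_regression(richness, dissimilarity):
    """OLS of per-station dissimilarity on observed richness.

    Returns dict with slope, intercept, r2 and the slope's t-test p-value.
    """
    richness = np.asarray(richness, dtype=float)
    dissimilarity = np.asarray(dissimilarity, dtype=float)
    ok = np.isfinite(richness) & np.isfinite(dissimilarity)
    richness, dissimilarity = richness[ok], dissimilarity[ok]
    if richness.size < 3:
        raise ValueError("regression needs >= 3 stations")
    if np.var(richness) == 0:
        raise ValueError("richness has zero variance; slope undefined")
    xmat = sm.add_constant(richness)
    with warnings.catch_warnings():
        # statsmodels divides by a zero total sum of squares when the
        # response is constant; report R^2 = 0 for that case
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(dissimilarity, xmat).fit()
        r2 = float(res.rsquared)
        out = {
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "r2": r2 if np.isfinite(r2) else 0.0,
            "p_value": float(res.pvalues[1]),
        }
    return out
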