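"""Pólya-Gamma random variates for logistic data augmentation.

A random variable ``w ~ PG(b, c)`` has Laplace transform
``E[exp(-w t)] = cosh^b(c/2) / cosh^b(sqrt(c^2/2 + t) / sqrt(2))`` and turns
Bernoulli-logit likelihoods into conditionally Gaussian ones: for a logistic
regression with linear predictor ``eta``, augmenting each observation with
``w ~ PG(1, eta)`` makes the conditional posterior of the coefficients
multivariate normal.

``PG(1, c)`` is drawn exactly with Devroye's alternating-series rejection
sampler (the same construction used by the BayesLogit family of samplers).
``PG(n, c)`` for integer ``n`` is the sum of ``n`` independent ``PG(1, c)``
draws; above a size threshold the sum is drawn from a moment-matched normal
(central-limit regime), below it the draws are summed exactly.

Identities used for moments (and tested against simulation):
    E[PG(b, c)]   = b / (2c) * tanh(c / 2)                  (b/4 at c = 0)
    Var[PG(b, c)] = b / (4 c^3) * (sinh(c) - c) * sech^2(c/2)   (b/24 at c = 0)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "pg_sum_draw", "pg_mean", "pg_var"]

_TRUNC = 0.64
_PI2_8 = math.pi * math.pi / 8.0

# Group size above which the summed PG(n, c) draw switches to a
# moment-matched normal; below it n exact PG(1, c) draws are summed.
NORMAL_APPROX_THRESHOLD = 30


def pg_mean(b: float, c: float) -> float:
    """Mean of PG(b, c)."""
    c = abs(c)
    if c < 1e-8:
        return b / 4.0
    return b / (2.0 * c) * math.tanh(c / 2.0)


def pg_var(b: float, c: float) -> float:
    """Variance of PG(b, c)."""
    c = abs(c)
    if c < 1e-4:
        return b / 24.0
    sech2 = 1.0 / math.cosh(c / 2.0) ** 2
    return b / (4.0 * c**3) * (math.sinh(c) - c) * sech2


@njit(cache=True)
def _norm_logcdf(x):
    # log Phi(x) via erfc; accurate enough in the far tail for the mixing mass
    if x > -37.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    # asymptotic tail expansion
    return -0.5 * x * x - math.log(-x) - 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _mass_texpon(z):
    """Probability that the proposal X comes from the truncated-exponential
    tail (x > TRUNC) rather than the truncated inverse-Gaussian body."""
    t = _TRUNC
    fz = _PI2_8 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _norm_logcdf(b)
    xa = x0 + z + _norm_logcdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _a_coef(n, x):
    k = n + 0.5
    if x > _TRUNC:
        return math.pi * k * math.exp(-k * k * math.pi * math.pi * x / 2.0)
    return (
        math.pi
        * k
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * k * k / x)
    )


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, TRUNC]."""
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from truncated chi-like proposal
        alpha = 0.0
        while np.random.random() > alpha:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal(0.0, 1.0)
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _pg1(c):
    """One exact PG(1, c) draw (Devroye alternating-series sampler)."""
    z = abs(c) * 0.5
    fz = _PI2_8 + z * z / 2.0
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@njit(cache=True)
def _pg_draw_arr(c, seed):
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = _pg1(c[i])
    return out


@njit(cache=True)
def _pg_sum_arr(n, c, threshold, seed):
    np.random.seed(seed)
    out = np.zeros(n.shape[0])
    for i in range(n.shape[0]):
        ni = n[i]
        if ni == 0:
            continue
        ci = abs(c[i])
        if ni <= threshold:
            tot = 0.0
            for _ in range(ni):
                tot += _pg1(ci)
            out[i] = tot
        else:
            if ci < 1e-8:
                m1 = 0.25
            else:
                m1 = math.tanh(ci / 2.0) / (2.0 * ci)
            if ci < 1e-4:
                v1 = 1.0 / 24.0
            else:
                sech2 = 1.0 / (math.cosh(ci / 2.0) * math.cosh(ci / 2.0))
                v1 = (math.sinh(ci) - ci) * sech2 / (4.0 * ci**3)
            val = ni * m1 + math.sqrt(ni * v1) * np.random.normal(0.0, 1.0)
            if val <= 0.0:
                val = ni * m1
            out[i] = val
    return out


def pg_draw(c: np.ndarray, seed: int) -> np.ndarray:
    """Exact PG(1, c_i) draw for each element of ``c`` (any shape)."""
    c = np.ascontiguousarray(c, dtype=np.float64)
    flat = _pg_draw_arr(c.ravel(), int(seed) & 0x7FFFFFFF)
    return flat.reshape(c.shape)


def pg_sum_draw(
    n: np.ndarray,
    c: np.ndarray,
    seed: int,
    threshold: int = NORMAL_APPROX_THRESHOLD,
) -> np.ndarray:
    """Draw ``sum of n_i iid PG(1, c_i)`` = PG(n_i, c_i) per element.

    Small groups are summed exactly; groups above ``threshold`` use a
    moment-matched normal approximation.
    """
    n = np.ascontiguousarray(n, dtype=np.int64)
    c = np.ascontiguousarray(c, dtype=np.float64)
    flat = _pg_sum_arr(
        n.ravel(), c.ravel(), int(threshold), int(seed) & 0x7FFFFFFF
    )
    return flat.reshape(n.shape)
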