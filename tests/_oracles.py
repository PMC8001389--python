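"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic from its textbook definition with plain
loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def empirical_survival(death_ages: list[int], age: float) -> float:
    """Fraction of subjects still alive just after ``age`` (no censoring)."""
    return sum(1 for t in death_ages if t > age) / len(death_ages)


def brute_logrank_2group(
    times_a: list[int],
    died_a: list[bool],
    times_b: list[int],
    died_b: list[bool],
) -> float:
    """Two-group log-rank chi-square via explicit hypergeometric sums."""
    death_ages = sorted(
        {t for t, d in zip(times_a, died_a) if d}
        | {t for t, d in zip(times_b, died_b) if d}
    )
    u = 0.0
    v = 0.0
    for t in death_ages:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, d in zip(times_a, died_a) if d and x == t)
        d_b = sum(1 for x, d in zip(times_b, died_b) if d and x == t)
        n = n_a + n_b
        d = d_a + d_b
        u += d_a - d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if v <= 0.0:
        return 0.0
    return u * u / v


def poisson_two_factor_deviance(
    y: np.ndarray, a_levels: np.ndarray, b_levels: np.ndarray
) -> float:
    """Deviance of the additive Poisson log-link model y ~ a + b.

    Maximises the Poisson log-likelihood directly over the coefficient
    vector (treatment coding built by hand) with a quasi-Newton optimiser.
    """
    a_names = sorted(set(a_levels))
    b_names = sorted(set(b_levels))
    n = len(y)
    p = 1 + (len(a_names) - 1) + (len(b_names) - 1)
    x = np.zeros((n, p))
    x[:, 0] = 1.0
    for i in range(n):
        col = 1
        for lvl in a_names[1:]:
            if a_levels[i] == lvl:
                x[i, col] = 1.0
            col += 1
        for lvl in b_names[1:]:
            if b_levels[i] == lvl:
                x[i, col] = 1.0
            col += 1

    def negloglik(beta):
        eta = x @ beta
        mu = np.exp(eta)
        return float(np.sum(mu - y * eta))

    def grad(beta):
        mu = np.exp(x @ beta)
        return x.T @ (mu - y)

    res = optimize.minimize(
        negloglik,
        np.zeros(p),
        jac=grad,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    eta = x @ res.x
    mu = np.exp(eta)
    dev = 0.0
    for yi, mi in zip(y, mu):
        term = yi * math.log(yi / mi) if yi > 0 else 0.0
        dev += 2.0 * (term - (yi - mi))
    return dev
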