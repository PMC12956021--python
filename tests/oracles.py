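"""Independent oracles for the test suite.

These deliberately avoid the package's simulation code paths: the clone
composition distribution is computed by exact dynamic programming over the
per-generation binomial switching convolution, plating by the
hypergeometric law, and the suspension assay by the closed-form moments of
the Yule process (a single resistant founder leaves a geometric family of
mean e^(gamma*T), so the clone total is shifted negative binomial).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def lineage_resistant_prob(k_on: float, k_off: float, G: int, m0: float) -> float:
    """Single-lineage Markov recursion m_{g+1} = m_g(1-k_off) + (1-m_g)k_on."""
    m = m0
    for _ in range(G):
        m = m * (1.0 - k_off) + (1.0 - m) * k_on
    return m


def resistant_count_pmf(k_on: float, k_off: float, G: int, founder_resistant: bool) -> np.ndarray:
    """Exact pmf of the resistant-cell count among the 2^G cells of a clone.

    Each generation, a clone with r resistant of n cells produces
    Binom(2r, 1-k_off) + Binom(2(n-r), k_on) resistant daughters; the pmf is
    propagated by convolving the two binomial pmfs for every reachable r.
    """
    pmf = np.zeros(2)
    pmf[1 if founder_resistant else 0] = 1.0
    n = 1
    for _ in range(G):
        new = np.zeros(2 * n + 1)
        for r, p_r in enumerate(pmf):
            if p_r == 0.0:
                continue
            from_r = stats.binom.pmf(np.arange(2 * r + 1), 2 * r, 1.0 - k_off)
            from_s = stats.binom.pmf(np.arange(2 * (n - r) + 1), 2 * (n - r), k_on)
            new[: 2 * n + 1] += p_r * np.convolve(from_r, from_s)
        pmf = new
        n *= 2
    return pmf


def plated_resistant_pmf(clone_pmf: np.ndarray, N: int, n0: int) -> np.ndarray:
    """pmf of resistant cells among n0 plated, sampled without replacement."""
    out = np.zeros(n0 + 1)
    ks = np.arange(n0 + 1)
    for r, p_r in enumerate(clone_pmf):
        if p_r == 0.0:
            continue
        out += p_r * stats.hypergeom.pmf(ks, N, r, n0)
    return out


def survival_cv_exact(
    k_on: float,
    k_off: float,
    G: int,
    n0: int,
    T: float,
    T_d: float,
    f_eq: float | None = None,
) -> tuple[float, float]:
    """Exact (mean, CV) of the per-clone survival fraction.

    Founder state is Bernoulli(f_eq) (default: switching equilibrium).
    Survival = (k + NegBin(k, e^(-gamma*T))) / n0 given k plated resistant
    cells; sensitive cells are dead at T.  Moments by total expectation /
    total variance over the exact composition and plating distributions.
    """
    if f_eq is None:
        f_eq = k_on / (k_on + k_off)
    N = 2**G
    if n0 > N:
        raise ValueError("cannot plate more cells than the clone contains")
    clone_pmf = f_eq * resistant_count_pmf(k_on, k_off, G, True) + (
        1.0 - f_eq
    ) * resistant_count_pmf(k_on, k_off, G, False)
    k_pmf = plated_resistant_pmf(clone_pmf, N, n0)
    gamma = math.log(2.0) / T_d
    m = math.exp(gamma * T)  # per-founder mean family size
    v = m * m - m  # per-founder family-size variance (geometric)
    ks = np.arange(k_pmf.size)
    cond_mean = ks * m / n0
    cond_var = ks * v / (n0 * n0)
    mean = float(np.sum(k_pmf * cond_mean))
    second = float(np.sum(k_pmf * (cond_var + cond_mean**2)))
    var = second - mean * mean
    return mean, math.sqrt(max(var, 0.0)) / mean


def survival_cv_moments_large(
    k_on: float,
    k_off: float,
    G: int,
    N0: int,
    T: float,
    T_d: float,
    f_eq: float,
) -> tuple[float, float]:
    """Exact (mean, CV) of per-clone survival for protocol-scale instances.

    Same probability model as :func:`survival_cv_exact` but via moment
    recursions instead of full pmfs, so G = 20 and N0 = 250,000 are exact
    and instant: the resistant-count mean/variance follow the branching
    recursion m' = 2*lam*m + 2*N*k_on,
    v' = 2*k_off*(1-k_off)*m + 2*k_on*(1-k_on)*(N-m) + 4*lam^2*v
    (lam = 1-k_on-k_off), plating is hypergeometric, and the assay adds the
    Yule family-size variance.
    """
    lam = 1.0 - k_on - k_off
    m = f_eq
    v = f_eq * (1.0 - f_eq)
    N = 1
    for _ in range(G):
        e_var = 2 * k_off * (1 - k_off) * m + 2 * k_on * (1 - k_on) * (N - m)
        v = e_var + 4 * lam * lam * v
        m = 2 * lam * m + 2 * N * k_on
        N *= 2
    n0 = min(N0, N)
    e_r2 = v + m * m
    e_k = n0 * m / N
    e_var_k = n0 * (N - n0) / (N - 1) * (m / N - e_r2 / (N * N))
    var_k = e_var_k + (n0 / N) ** 2 * v
    ma = 2.0 ** (T / T_d)
    va = ma * ma - ma
    mean_s = ma * e_k / n0
    var_s = (ma / n0) ** 2 * var_k + va * e_k / (n0 * n0)
    return mean_s, math.sqrt(var_s) / mean_s
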