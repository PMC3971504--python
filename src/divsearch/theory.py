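"""Closed-form analysis of the minimum L1 distance to the optimum.

Model: with both the test point V and the optimum V_max placed uniformly
on the lattice {0..T}^n, the per-drug signed offset Z = V(i) - V_max(i)
has a triangular PMF, its absolute value W folds that PMF about zero, the
L1 distance R1 = sum_i |Z_i| is the n-fold self-convolution of W, and the
nearest of m independently placed points has distance R2 whose CDF is
1 - (1 - CDF_R1)^m.  A subsequent focused refinement multiplies the
distance by independent Uniform(0,1) factors, so rho1 refinements shrink
the expected distance by 2**rho1.

All PMFs here are exact (rational arithmetic up to float rounding); no
simulation is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, lgamma

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DistanceDistribution:
    """Exact PMF of an L1 grid distance on support 0..n*T.

    ``provenance`` records which random variable it represents ("R1" for a
    single uniform point, "R2" for the minimum over m points) together with
    the (n, T, m) that produced it.
    """

    support: np.ndarray
    pmf: np.ndarray
    provenance: str

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    @property
    def mean(self) -> float:
        return float((self.support * self.pmf).sum())

    @property
    def variance(self) -> float:
        mu = self.mean
        return float(((self.support - mu) ** 2 * self.pmf).sum())


def _check_T(T: int) -> None:
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")


def pmf_Z(T: int) -> np.ndarray:
    """Triangular PMF of the signed per-drug offset on support -T..T.

    f_Z(z) = (T + 1 - |z|) / (T + 1)^2, the difference of two independent
    discrete uniforms on 0..T.
    """
    _check_T(T)
    z = np.arange(-T, T + 1)
    return (T + 1 - np.abs(z)) / (T + 1) ** 2


def pmf_W(T: int) -> np.ndarray:
    """PMF of the absolute per-drug offset |Z| on support 0..T.

    f_W(0) = 1/(T+1) and f_W(w) = 2(T + 1 - w)/(T + 1)^2 for w = 1..T
    (the fold of the triangular PMF about zero).
    """
    _check_T(T)
    p = np.empty(T + 1)
    p[0] = 1.0 / (T + 1)
    w = np.arange(1, T + 1)
    p[1:] = 2.0 * (T + 1 - w) / (T + 1) ** 2
    return p


def pmf_R1(n: int, T: int) -> DistanceDistribution:
    """PMF of the L1 distance of one uniform point from a uniform optimum.

    Exact n-fold self-convolution of f_W; support 0..n*T.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    base = pmf_W(T)
    pmf = base.copy()
    for _ in range(n - 1):
        pmf = np.convolve(pmf, base)
    return DistanceDistribution(
        support=np.arange(n * T + 1), pmf=pmf,
        provenance=f"R1(n={n}, T={T})",
    )


def pmf_R2(n: int, T: int, m: int) -> DistanceDistribution:
    """PMF of the minimum L1 distance over m independently placed points.

    CDF_R2(x) = 1 - (1 - CDF_R1(x))^m; the PMF follows by first
    differences with PMF(0) = CDF(0).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    r1 = pmf_R1(n, T)
    cdf2 = 1.0 - (1.0 - r1.cdf) ** m
    pmf = np.diff(cdf2, prepend=0.0)
    return DistanceDistribution(
        support=r1.support, pmf=pmf, provenance=f"R2(n={n}, T={T}, m={m})",
    )


def min_distance_moments(n: int, T: int, m: int) -> tuple[float, float]:
    """Exact (mean, variance) of the minimum L1 distance over m points."""
    dist = pmf_R2(n, T, m)
    return dist.mean, dist.variance


def multi_optimum_moments(
    n: int, T: int, m: int, k: int
) -> tuple[float, float]:
    """Moments of the minimum distance to any of k well-separated optima.

    With k optima the minimum runs over k*m point-to-optimum distances, so
    the moments equal those of the single-optimum case at budget k*m.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return min_distance_moments(n, T, k * m)


def product_uniform_pdf(x, r: int):
    """Density of a product of r independent Uniform(0,1) variables.

    f(x) = (ln(1/x))**(r-1) / (r-1)! on (0, 1]; models the multiplicative
    shrinkage of the distance under successive focused refinements.
    """
    if r < 1:
        raise ValueError(f"factor count r must be >= 1, got {r}")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("x must lie in (0, 1]")
    if r <= 20:
        out = np.log(1.0 / x) ** (r - 1) / factorial(r - 1)
    else:  # log-space for large factorials
        out = np.exp((r - 1) * np.log(np.log(1.0 / x) + 0.0) - lgamma(r))
    return out if out.shape else float(out)


def expected_distance_after_focus(D: float, rho1: int) -> float:
    """Expected distance after rho1 focused refinements: D / 2**rho1.

    Each refinement multiplies the remaining distance by an independent
    Uniform(0,1) factor with mean 1/2.
    """
    if D < 0:
        raise ValueError("initial expected distance must be >= 0")
    if rho1 < 0:
        raise ValueError("rho1 must be >= 0")
    return D / 2.0**rho1


def expected_focused_steps(iterations: int, p_focus: float) -> float:
    """Expected number of focused (path a) steps among sequential iterations."""
    if iterations < 0 or not 0 <= p_focus <= 1:
        raise ValueError("need iterations >= 0 and p_focus in [0, 1]")
    return iterations * p_focus


def theoretical_trajectory(
    n: int, T: int, m: int, p_focus: float, iters: int
) -> np.ndarray:
    """Expected minimum L1 distance to the optimum after each experiment.

    Experiments 1..m follow the order-statistic mean E[R2] with the running
    point count; beyond m the curve decays geometrically as
    E[R2(m)] / 2**((t - m) * p_focus), the expected focused-refinement
    count at probability p_focus per iteration.
    """
    if iters < m:
        raise ValueError("iters must be >= m")
    out = np.empty(iters)
    for t in range(1, m + 1):
        out[t - 1] = min_distance_moments(n, T, t)[0]
    D = out[m - 1]
    extra = np.arange(1, iters - m + 1)
    out[m:] = D / 2.0 ** (extra * p_focus)
    return out


def theory_table(
    ns: list[int], Ts: list[int], ms: list[int]
) -> pd.DataFrame:
    """Grid of exact (mean, variance) over all (n, T, m) combinations."""
    rows = []
    for T in Ts:
        for n in ns:
            for m in ms:
                mean, var = min_distance_moments(n, T, m)
                rows.append({"n": n, "T": T, "m": m, "mean": mean,
                             "variance": var})
    return pd.DataFrame(rows)
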