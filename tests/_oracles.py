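"""Independent oracles used across the test suite.

Each function recomputes a quantity by a deliberately different route from
the package implementation (enumeration, numeric integration, or brute force)
so the two can be compared without sharing code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats


def binomial_two_sided_p(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p by full enumeration: sum the probabilities
    of all outcomes no more likely than the observed one."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-12)))


def thresholded_bivariate_dosage_r2(p1: float, p2: float, latent_r: float) -> float:
    """Dosage r^2 implied by thresholding a latent bivariate normal, by direct
    2-D numeric integration of the density over the joint-carrier quadrant."""
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)

    def density(y, x):
        det = 1 - latent_r**2
        q = (x * x - 2 * latent_r * x * y + y * y) / det
        return np.exp(-q / 2) / (2 * np.pi * np.sqrt(det))

    p11, _ = integrate.dblquad(density, -8.0, t1, -8.0, t2)
    r = (p11 - p1 * p2) / math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return r * r


def greedy_clump(
    pvals: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    variant_ids: np.ndarray,
    dosages: np.ndarray,
    r2_threshold: float,
    window_bp: float,
) -> list[str]:
    """Brute-force greedy clumping with a precomputed all-pairs r^2 matrix."""
    n = len(pvals)
    C = np.corrcoef(dosages.T)
    R2 = np.nan_to_num(C, nan=0.0) ** 2
    order = sorted(range(n), key=lambda i: (pvals[i], chrom[i], pos[i], variant_ids[i]))
    alive = [True] * n
    kept = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        for j in range(n):
            if (
                alive[j]
                and chrom[j] == chrom[i]
                and abs(pos[j] - pos[i]) <= window_bp
                and R2[i, j] > r2_threshold
            ):
                alive[j] = False
    kept.sort(key=lambda i: (chrom[i], pos[i]))
    return [variant_ids[i] for i in kept]


def double_loop_prs(
    dosages: np.ndarray, weights: np.ndarray, pvals: np.ndarray, threshold: float
) -> np.ndarray:
    """Per-subject score by explicit double loop over subjects and variants."""
    n, m = dosages.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            if pvals[j] <= threshold:
                out[i] += dosages[i, j] * weights[j]
    return out


def liability_decile_curve(r2: float, prevalence: float) -> np.ndarray:
    """Expected per-decile prevalence under the liability-threshold model via
    adaptive 1-D quadrature (independent of the package's trapezoid helper)."""
    r = math.sqrt(r2)
    T = stats.norm.ppf(1.0 - prevalence)
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, 11))
    out = np.empty(10)
    for d in range(10):
        lo = -9.0 if d == 0 else edges[d]
        hi = 9.0 if d == 9 else edges[d + 1]

        def f(z):
            return stats.norm.cdf((r * z - T) / math.sqrt(1 - r2)) * stats.norm.pdf(z)

        num, _ = integrate.quad(f, lo, hi)
        den, _ = integrate.quad(stats.norm.pdf, lo, hi)
        out[d] = num / den
    return out


def gls_normal_equations(beta: np.ndarray, V: np.ndarray, lam: np.ndarray):
    """GLS projection onto one factor via whitened least squares (Cholesky +
    lstsq), independent of the closed-form implementation."""
    L = np.linalg.cholesky(V)
    X = np.linalg.solve(L, lam.reshape(-1, 1))
    y = np.linalg.solve(L, beta.reshape(-1, 1))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0, 0])
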