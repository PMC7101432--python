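"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized implementation paths: pair counting
is O(N^2) over all voxel pairs, zone labeling is a hand-written flood fill,
the BH oracle follows the step-up definition directly, and the Bayesian
leaf score is 2D numerical quadrature over (mean, precision).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_cooc(disc: np.ndarray, mask: np.ndarray, offsets) -> np.ndarray:
    """Count all ordered voxel pairs at the given offsets, symmetrized."""
    n_bins = int(disc[mask].max())
    counts = np.zeros((n_bins, n_bins))
    voxels = [tuple(v) for v in np.argwhere(mask)]
    vset = set(voxels)
    for v in voxels:
        for d in offsets:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if w in vset:
                a, b = disc[v] - 1, disc[w] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts / counts.sum() if counts.sum() else counts


def brute_force_szm(disc: np.ndarray, mask: np.ndarray) -> dict[tuple[int, int], int]:
    """Flood-fill zones of equal-bin 26-connected voxels; returns {(bin, size): count}."""
    seen = np.zeros(disc.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    neigh = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        b = disc[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for d in neigh:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < disc.shape[i] for i in range(3)):
                    if mask[w] and not seen[w] and disc[w] == b:
                        seen[w] = True
                        stack.append(w)
        zones[(int(b), size)] = zones.get((int(b), size), 0) + 1
    return zones


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Adjusted p by the step-up definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


def ng_marginal_quadrature(x: np.ndarray, mu0: float, lam0: float, a0: float, b0: float) -> float:
    """Direct 2D quadrature of the normal-gamma marginal likelihood p(x).

    Integrates the joint density over (mean, precision) on a composite
    Gauss-Legendre grid, with the precision on a log scale (tau = e^u) and
    the mean re-centered and scaled by the local precision
    (mu = c + s / sqrt(tau)) so every integrand peak is resolved by the
    grid. Independent of the closed-form implementation path.
    """

    def composite_gl(lo: float, hi: float, h: float, order: int):
        nodes, weights = np.polynomial.legendre.leggauss(order)
        edges = np.linspace(lo, hi, max(2, int(np.ceil((hi - lo) / h)) + 1))
        mids = (edges[:-1] + edges[1:]) / 2
        half = np.diff(edges) / 2
        pts = (mids[:, None] + half[:, None] * nodes[None, :]).ravel()
        wts = (half[:, None] * weights[None, :]).ravel()
        return pts, wts

    from scipy.special import gammaln

    x = np.asarray(x, dtype=float)
    n = x.size
    c = (lam0 * mu0 + x.sum()) / (lam0 + n)  # posterior mean location
    u_hi = float(np.log((a0 + n / 2 + 40.0) / b0) + 2.0)
    u, wu = composite_gl(-18.0, u_hi, 0.5, 16)
    s, ws = composite_gl(-14.0, 14.0, 0.8, 16)
    tau = np.exp(u)[:, None]
    mu = c + s[None, :] / np.sqrt(tau)
    half_log_tau = 0.5 * u[:, None]
    log2pi = np.log(2 * np.pi)
    # sum_i log N(x_i | mu, 1/tau)
    ss = ((x[:, None, None] - mu[None, :, :]) ** 2).sum(axis=0)
    lik = n * (half_log_tau - 0.5 * log2pi) - 0.5 * tau * ss
    # log N(mu | mu0, 1/(lam0 tau)) + log Gamma(tau | a0, b0) + jacobians
    prior = (
        0.5 * np.log(lam0) + half_log_tau - 0.5 * log2pi
        - 0.5 * lam0 * tau * (mu - mu0) ** 2
        + a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * u[:, None] - b0 * tau
        + u[:, None]          # d tau = tau du
        - half_log_tau        # d mu = ds / sqrt(tau)
    )
    logint = lik + prior
    m = logint.max()
    val = float((wu[:, None] * ws[None, :] * np.exp(logint - m)).sum())
    return float(m + np.log(val))


def hypergeom_enumeration(N: int, K: int, n: int, k_obs: int) -> float:
    """P(overlap >= k_obs) by exhaustive enumeration of all C(N, n) draws."""
    from itertools import combinations

    universe = list(range(N))
    pathway = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(pathway & set(draw)) >= k_obs:
            hits += 1
    return hits / total
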