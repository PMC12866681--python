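"""Independent oracles used by the tests.

These deliberately avoid the package's optimization path: the grid search
locates the maximum-likelihood point by exhaustive lattice evaluation with
successive refinement, and the likelihood here is written from the binomial
definition using ``scipy.stats.norm`` rather than the package's internals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

# Search box in (alpha_ild, alpha_itd, beta, gamma, delta/(gamma/2)) space.
ORACLE_BOX = ((-1.0, 1.0), (-0.1, 0.1), (-2.0, 2.0), (0.0, 0.6), (-1.0, 1.0))


def oracle_nll(x, itd, ild, k, n, eps=1e-12):
    """Binomial negative log-likelihood, written independently."""
    a_ild, a_itd, beta, gamma, dfrac = x
    delta = gamma / 2.0 * dfrac
    p = norm.cdf(a_ild * ild + a_itd * itd + beta) * (1 - gamma) + gamma / 2 + delta
    p = np.clip(p, eps, 1 - eps)
    return float(-(k * np.log(p) + (n - k) * np.log(1 - p)).sum())


def grid_search_fit(
    table,
    n_points: int = 9,
    delta0: float = 50.0,
    shrink: float = 0.4,
    delta_min: float = 1e-6,
    extra_stages: int = 3,
    box=ORACLE_BOX,
):
    """Exhaustive 5-D grid search with sublevel-set refinement.

    Each stage evaluates the likelihood on a full ``n_points**5`` lattice and
    re-grids onto the bounding box (padded by one step) of every lattice point
    whose negative log-likelihood lies within ``delta`` of the best seen, with
    ``delta`` shrinking geometrically from ``delta0`` to ``delta_min``.
    Tracking a likelihood region rather than a single winner keeps narrow,
    correlated valleys inside the box until the lattice resolves them.

    Returns ``(best_x, best_nll, final_steps)`` with ``best_x`` in
    (alpha_ild, alpha_itd, beta, gamma, delta-fraction) coordinates and
    ``final_steps`` the per-parameter spacing of the last lattice.
    """
    itd, ild, k, n = table.arrays()
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    blo, bhi = lo.copy(), hi.copy()
    best_nll = np.inf
    best_x = (lo + hi) / 2.0
    steps = (hi - lo) / (n_points - 1)
    delta = delta0
    extra_done = 0
    while True:
        grids = [np.linspace(l, h, n_points) for l, h in zip(blo, bhi)]
        steps = np.array([g[1] - g[0] for g in grids])
        A = grids[0][:, None, None, None, None, None]
        T = grids[1][None, :, None, None, None, None]
        B = grids[2][None, None, :, None, None, None]
        G = grids[3][None, None, None, :, None, None]
        D = grids[4][None, None, None, None, :, None]
        p = norm.cdf(A * ild + T * itd + B) * (1 - G) + G / 2 + G / 2 * D
        p = np.clip(p, 1e-12, 1 - 1e-12)
        nll = -(k * np.log(p) + (n - k) * np.log(1 - p)).sum(axis=-1)
        idx = np.unravel_index(np.argmin(nll), nll.shape)
        if nll[idx] < best_nll:
            best_nll = float(nll[idx])
            best_x = np.array([grids[d][idx[d]] for d in range(5)])
        coords = np.nonzero(nll <= best_nll + delta)
        for d in range(5):
            g = grids[d]
            blo[d] = max(lo[d], g[coords[d].min()] - steps[d])
            bhi[d] = min(hi[d], g[coords[d].max()] + steps[d])
        if delta <= delta_min:
            extra_done += 1
            if extra_done > extra_stages:
                break
        delta = max(delta_min, delta * shrink)
    return best_x, best_nll, steps


def recount_table(trials):
    """Independent per-cell tally of right responses from a raw trial list."""
    counts = {}
    for t in trials:
        cell = (t.condition.itd_us, t.condition.ild_db)
        k, n = counts.get(cell, (0, 0))
        counts[cell] = (k + (t.response.value == "right"), n + 1)
    return counts
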