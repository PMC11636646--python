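"""Independent reference implementations used as test oracles.

Deliberately naive and written against the formulas only — none of this
shares code with the package.
"""

from __future__ import annotations

import mpmath as mp
import numpy as np


def stouffer_oracle(pvals, dps: int = 60) -> float:
    """High-precision Gaussian P-value combination via mpmath error functions.

    Phi_bar(x) = erfc(x / sqrt(2)) / 2 and Phi_bar^{-1}(p) = sqrt(2) *
    erfinv(1 - 2 p).
    """
    with mp.workdps(dps):
        zs = [mp.sqrt(2) * mp.erfinv(1 - 2 * mp.mpf(repr(float(p)))) for p in pvals]
        s = mp.fsum(zs) / mp.sqrt(len(zs))
        return float(mp.erfc(s / mp.sqrt(2)) / 2)


def bh_oracle(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct definition; boolean mask."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k = 0
    for i in range(m):
        if ps[i] <= alpha * (i + 1) / m:
            k = i + 1
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def bh_threshold_oracle(p: np.ndarray, alpha: float) -> float:
    """The BH rejection threshold (largest rejected P-value; 0 if none)."""
    mask = bh_oracle(p, alpha)
    return float(np.max(np.asarray(p)[mask])) if mask.any() else 0.0


def eq3_criterion(t, carry, r_prev, sizes, pvals, alpha):
    """Left-hand side of the layer step-up criterion at threshold t."""
    den = max(r_prev + sizes[pvals <= t].sum(), 1.0)
    return (carry + sizes.sum() * t) / den <= alpha + 1e-12


def eq3_scan_oracle(carry, r_prev, sizes, pvals, alpha, alpha_m, n_grid=4001):
    """Exhaustive scan of the layer criterion over a dense threshold grid.

    The grid contains every observed node P-value inside the search interval
    (the jump points of the denominator) plus a dense linear fill, so the
    largest feasible grid point rejects the same node set as the true
    supremum.
    """
    sizes = np.asarray(sizes, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    ts = np.unique(
        np.concatenate(
            [
                np.linspace(alpha_m, alpha, n_grid),
                pvals[(pvals >= alpha_m) & (pvals <= alpha)],
            ]
        )
    )
    feasible = np.array(
        [eq3_criterion(t, carry, r_prev, sizes, pvals, alpha) for t in ts]
    )
    if not feasible.any():
        return None
    return float(ts[feasible].max())


def greedy_pair_oracle(D: np.ndarray, g: float):
    """Independent greedy closest-pair matcher for singletons with M = 2.

    Sorts all feasible pairs by (distance, i, j) and matches greedily;
    returns the sorted list of merged pairs.
    """
    n = D.shape[0]
    pairs = sorted(
        (float(D[i, j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if D[i, j] <= g
    )
    used = set()
    merged = []
    for _, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        merged.append((i, j))
    return sorted(merged)
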