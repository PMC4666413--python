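"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: order-statistic saturation by full
sort, connected components by explicit flood fill, and OLS inference by
the closed-form normal equations.  They share no code with the package
paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def saturate_rescale_oracle(values, fraction, out_max):
    """Sort, take the k-th order statistics, clip, map affinely."""
    flat = np.sort(np.asarray(values, dtype=float), axis=None)
    n = flat.size
    k = int(np.floor(fraction * n))
    low, high = flat[k], flat[n - 1 - k]
    clipped = np.clip(np.asarray(values, dtype=float), low, high)
    return (clipped - low) / (high - low) * out_max


def flood_fill_components(mask, connectivity):
    """Connected components by explicit stack-based flood fill.

    Returns a list of sets of (row, col) tuples.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        neighbours = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neighbours = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    nrows, ncols = mask.shape
    for r in range(nrows):
        for c in range(ncols):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in neighbours:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < nrows and 0 <= nc < ncols and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                components.append(comp)
    return components


def ols_oracle(x, y):
    """Simple-regression slope/intercept/SE/CI/p from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(0.975, n - 2)
    tstat = slope / se
    p = 2 * stats.t.sf(abs(tstat), n - 2)
    return {
        "slope": slope,
        "intercept": intercept,
        "se": se,
        "ci": (slope - tcrit * se, slope + tcrit * se),
        "p": p,
    }
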