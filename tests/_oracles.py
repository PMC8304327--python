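"""Independent numerical oracles used to cross-check closed forms.

The grid-search inversion below recovers occupancies from an (x, y, z)
ratio triplet by brute-force least squares on the forward two-state model,
without using the closed-form algebra it is meant to verify.
"""

import numpy as np


def forward_ratios(p_light: float, p_heavy: float, rho: float):
    """The forward two-state mixing model: expected (x, y, z) ratios."""
    x = rho * p_heavy / p_light
    y = rho * (1.0 - p_heavy) / (1.0 - p_light)
    return x, y, rho


def _profiled_residual(p_light, x, y, z):
    """Squared ratio residual at p_light with p_heavy profiled out.

    For fixed p_light the residual
    (x - z*p_heavy/p_light)^2 + (y - z*(1-p_heavy)/(1-p_light))^2
    is quadratic in p_heavy; its minimizer (clipped to [0, 1]) is plugged
    back in.
    """
    c1 = z / p_light
    c2 = z / (1.0 - p_light)
    p_heavy = (c1 * x - c2 * y + c2 ** 2) / (c1 ** 2 + c2 ** 2)
    p_heavy = np.clip(p_heavy, 0.0, 1.0)
    return ((x - c1 * p_heavy) ** 2
            + (y - c2 * (1.0 - p_heavy)) ** 2), p_heavy


def grid_search_occupancy(x: float, y: float, z: float,
                          grid_step: float = 1e-4):
    """Brute-force inversion: coarse grid over p_light, staged zooming,
    then a parabolic fit of the residual minimum.

    Returns ``(p_light, p_heavy)``.
    """
    eps = 1e-7
    grid = np.arange(eps, 1.0, grid_step)
    resid, _ = _profiled_residual(grid, x, y, z)
    best = grid[int(np.argmin(resid))]
    step = grid_step
    for step in (grid_step, 1e-6, 1e-8, 1e-10):
        grid = np.clip(np.linspace(best - 2 * step, best + 2 * step, 201),
                       eps, 1.0 - eps)
        resid, _ = _profiled_residual(grid, x, y, z)
        i = int(np.argmin(resid))
        best = grid[i]
    # parabolic vertex through the three innermost points
    if 0 < i < len(grid) - 1:
        h = grid[i + 1] - grid[i]
        denom = resid[i - 1] - 2 * resid[i] + resid[i + 1]
        if denom > 0:
            best = grid[i] + 0.5 * h * (resid[i - 1] - resid[i + 1]) / denom
    _, p_heavy = _profiled_residual(best, x, y, z)
    return float(best), float(p_heavy)
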