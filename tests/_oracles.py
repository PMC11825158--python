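"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive: direction sweeps, exhaustive pair searches,
winding numbers and explicit-sum statistics, kept free of any code path
they are used to check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist


def feret_sweep(vertices: np.ndarray, n_dirs: int = 36_000) -> tuple[float, float]:
    """Min/max width of a point set over a dense sweep of directions."""
    ang = np.pi * np.arange(n_dirs) / n_dirs
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    proj = vertices @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


def max_feret_pairs(vertices: np.ndarray) -> float:
    """Exhaustive max pairwise vertex distance."""
    return float(pdist(vertices).max())


def winding_number_inside(x: float, y: float, vertices: np.ndarray) -> bool:
    """Strict-interior test via the winding number (Sunday's algorithm)."""
    wn = 0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        cross = (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0)
        if y0 <= y:
            if y1 > y and cross > 0:
                wn += 1
        elif y1 <= y and cross < 0:
            wn -= 1
    return wn != 0


def pearson_explicit(x, y) -> float:
    """Pearson's r from explicit sums, no library call."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return float(num / den)


def block_anova_condition_p(values, conditions, subjects) -> tuple[float, float]:
    """Two-factor additive (randomized block) ANOVA, explicit sums of
    squares; returns (F, p) for the condition factor.  Balanced designs
    only."""
    values = np.asarray(values, float)
    conditions = np.asarray(conditions)
    subjects = np.asarray(subjects)
    grand = values.mean()
    clevels = sorted(set(conditions.tolist()))
    slevels = sorted(set(subjects.tolist()))
    a, b = len(clevels), len(slevels)
    ss_cond = sum(
        (values[conditions == c].mean() - grand) ** 2 * (conditions == c).sum()
        for c in clevels
    )
    ss_subj = sum(
        (values[subjects == s].mean() - grand) ** 2 * (subjects == s).sum()
        for s in slevels
    )
    ss_total = ((values - grand) ** 2).sum()
    ss_resid = ss_total - ss_cond - ss_subj
    df_cond = a - 1
    df_resid = (a - 1) * (b - 1)
    ms_cond = ss_cond / df_cond
    ms_resid = ss_resid / df_resid
    if ms_resid == 0:
        return float("inf"), 0.0 if ss_cond > 0 else 1.0
    F = ms_cond / ms_resid
    return float(F), float(sps.f.sf(F, df_cond, df_resid))


def random_convex_polygon(rng: np.random.Generator, n_points: int = 20) -> np.ndarray:
    """Convex hull of random points (vertices in hull order).

    Axis scaling is kept moderate (aspect <= ~2): a 36,000-direction
    width sweep resolves the minimum width of such shapes well below
    1e-4 relative, so sweep-based comparisons test the implementation,
    not the oracle's angular resolution.
    """
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 2)) * rng.uniform(0.7, 1.5, size=2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 24) -> np.ndarray:
    """Star-convex (possibly non-convex) polygon: sorted angles, random radii."""
    # jittered regular angle grid: every angular gap stays below pi, which
    # guarantees the star polygon is simple
    ang = 2 * np.pi * (np.arange(n_vertices) + rng.uniform(0.05, 0.95, n_vertices)) / n_vertices
    rad = rng.uniform(0.5, 1.5, n_vertices)
    return np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)


def ellipse_polygon(a: float, b: float, theta: float = 0.0, n: int = 64,
                    cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    phi = 2 * np.pi * np.arange(n) / n
    x, y = a * np.cos(phi), b * np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    return np.stack([cx + ct * x - st * y, cy + st * x + ct * y], axis=1)
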