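"""Independent oracles and small builders shared across tests.

The brute-force decorrelation oracle re-implements the all-shifts Pearson
correlation as a literal double loop over shift vectors with explicit
overlap masks and ``np.corrcoef`` — deliberately independent of the FFT
path it checks.
"""

from __future__ import annotations

import numpy as np

from nucleomorph.features import MIN_OVERLAP_PX, CircularCrop


def make_disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def make_random_circular_crop(n: int, radius: float, rng) -> CircularCrop:
    """Random-intensity circular crop, min-max scaled and mean-subtracted."""
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    support = (rr - c) ** 2 + (cc - c) ** 2 <= (radius - 0.5) ** 2
    vals = rng.random((n, n))
    inside = vals[support]
    scaled = (inside - inside.min()) / np.ptp(inside)
    out = np.zeros((n, n))
    out[support] = scaled - scaled.mean()
    return CircularCrop(out, support, (c, c), radius, pixel_size_um=0.2)


def brute_force_decorrelation(circ: CircularCrop):
    """All-shifts Pearson correlation by explicit double loop.

    Returns ``(coeff_by_shift, distances, mean_curve)`` with the same
    exclusion rules as the production path: overlap >= 16 px, shift
    magnitude below the circle diameter, and unit-width annular bins.
    """
    A, M = circ.values, circ.support
    H, W = A.shape
    diameter = 2 * circ.radius_px
    coeff = {}
    for dr in range(-(H - 1), H):
        for dc in range(-(W - 1), W):
            if np.hypot(dr, dc) >= diameter:
                continue
            r0, r1 = max(0, -dr), min(H, H - dr)
            c0, c1 = max(0, -dc), min(W, W - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            ref = (slice(r0, r1), slice(c0, c1))
            sh = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
            overlap = M[ref] & M[sh]
            if (dr, dc) == (0, 0):
                coeff[(dr, dc)] = 1.0
                continue
            if overlap.sum() < MIN_OVERLAP_PX:
                continue
            a = A[sh][overlap]
            b = A[ref][overlap]
            if a.std() == 0 or b.std() == 0:
                continue
            coeff[(dr, dc)] = float(np.corrcoef(a, b)[0, 1])
    bins = {}
    for (dr, dc), v in coeff.items():
        k = int(round(np.hypot(dr, dc)))
        bins.setdefault(k, []).append(v)
    distances = np.array(sorted(bins))
    curve = np.array([np.mean(bins[k]) for k in distances])
    return coeff, distances.astype(float), curve


def hull_fill_concavity(mask: np.ndarray) -> float:
    """Convex-deficit oracle: ConvexHull of pixel centers + polygon fill."""
    from matplotlib.path import Path as MPath
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask).astype(float)
    hull = ConvexHull(pts)
    poly = MPath(pts[hull.vertices])
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    grid = np.stack([yy.ravel(), xx.ravel()], axis=1)
    inside = poly.contains_points(grid, radius=0.5).reshape(mask.shape)
    hull_area = inside.sum()
    return (hull_area - mask.sum()) / hull_area
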