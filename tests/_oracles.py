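"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def points_in_polygon_bruteforce(vertices, points):
    """Even-odd (ray crossing) point-in-polygon test, one edge at a time."""
    vertices = np.asarray(vertices, dtype=float)
    px = np.asarray(points, dtype=float)[:, 0]
    py = np.asarray(points, dtype=float)[:, 1]
    inside = np.zeros(len(px), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_bruteforce(vertices, image_shape):
    h, w = image_shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5])
    return points_in_polygon_bruteforce(vertices, pts).reshape(h, w)


def _shift_offsets(radius):
    out = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            d2 = radius**2 - dx**2 - dy**2
            if d2 >= 0:
                out.append((dy, dx, np.sqrt(d2)))
    return out


def ball_opening_background(image, radius):
    """Rolling-ball background by explicit shift-and-compare min/max
    passes over every ball offset (independent of scipy morphology)."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    offsets = _shift_offsets(radius)
    pad_e = np.full((h + 2 * radius, w + 2 * radius), np.inf)
    pad_e[radius:radius + h, radius:radius + w] = img
    eroded = np.full((h, w), np.inf)
    for dy, dx, hb in offsets:
        np.minimum(eroded,
                   pad_e[radius + dy:radius + dy + h,
                         radius + dx:radius + dx + w] - hb,
                   out=eroded)
    pad_d = np.full((h + 2 * radius, w + 2 * radius), -np.inf)
    pad_d[radius:radius + h, radius:radius + w] = eroded
    opened = np.full((h, w), -np.inf)
    for dy, dx, hb in offsets:
        np.maximum(opened,
                   pad_d[radius - dy:radius - dy + h,
                         radius - dx:radius - dx + w] + hb,
                   out=opened)
    return opened


def subtract_background_oracle(image, radius):
    bg = np.clip(ball_opening_background(image, radius), 0, None)
    return np.clip(np.asarray(image, float) - bg, 0, None)


def average_ranks_bruteforce(values):
    """Average ranks (1-based) computed by explicit tie-group scanning."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    """rho from the Pearson formula on average ranks; S = sum d_i^2."""
    rx = average_ranks_bruteforce(x)
    ry = average_ranks_bruteforce(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    rho = np.sum(rx_c * ry_c) / np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    return float(rho), float(np.sum((rx - ry) ** 2))


def random_star_polygon(rng, centre, r_min, r_max, n_vertices=8):
    """Random star-shaped (hence non-self-intersecting) polygon.

    One vertex per angular sector with bounded jitter keeps every
    angular gap below pi, so the centre lies in the polygon's kernel
    and simplicity is guaranteed.
    """
    base = 2 * np.pi * np.arange(n_vertices) / n_vertices
    angles = base + (2 * np.pi / n_vertices) * rng.uniform(0.2, 0.8,
                                                           n_vertices)
    radii = rng.uniform(r_min, r_max, n_vertices)
    cx, cy = centre
    return np.column_stack([cx + radii * np.cos(angles),
                            cy + radii * np.sin(angles)])
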