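"""Deterministic triangle rasterization on the integer pixel lattice.

Pixels are 0-based with centers at integer coordinates; the image domain is
the half-open rectangle [0, W) x [0, H).  A pixel belongs to a triangle when
its center lies strictly inside, or on an edge that the top-left fill rule
assigns to this triangle — so triangles sharing an edge never both claim a
boundary pixel, and coverage is independent of vertex orientation.
"""

from __future__ import annotations

import numpy as np

_EMPTY = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), np.empty((0, 3)))


def triangle_pixels(tri: np.ndarray, shape: tuple[int, int]):
    """Pixels covered by one triangle, with barycentric weights.

    Parameters
    ----------
    tri : (3, 2) array of (x, y) vertex coordinates.
    shape : (H, W) image shape; pixels outside are clipped.

    Returns
    -------
    (rows, cols, weights) — covered pixel indices and the (k, 3) barycentric
    weights of each pixel center with respect to the input vertex order.
    """
    tri = np.asarray(tri, dtype=float)
    h, w = shape
    order = np.array([0, 1, 2])
    x, y = tri[:, 0], tri[:, 1]
    area = (x[1] - x[0]) * (y[2] - y[0]) - (y[1] - y[0]) * (x[2] - x[0])
    if area == 0:
        return _EMPTY
    if area < 0:
        order = np.array([0, 2, 1])
        tri = tri[order]
        x, y = tri[:, 0], tri[:, 1]
        area = -area
    xmin = max(int(np.ceil(x.min())), 0)
    xmax = min(int(np.floor(x.max())), w - 1)
    ymin = max(int(np.ceil(y.min())), 0)
    ymax = min(int(np.floor(y.max())), h - 1)
    if xmin > xmax or ymin > ymax:
        return _EMPTY
    gx, gy = np.meshgrid(np.arange(xmin, xmax + 1), np.arange(ymin, ymax + 1))
    edges = []
    inside = None
    for a, b in ((0, 1), (1, 2), (2, 0)):
        dx, dy = x[b] - x[a], y[b] - y[a]
        e = dx * (gy - y[a]) - dy * (gx - x[a])
        top_left = (dy < 0) or (dy == 0 and dx < 0)
        acc = (e > 0) | ((e == 0) & top_left)
        inside = acc if inside is None else (inside & acc)
        edges.append(e)
    if not inside.any():
        return _EMPTY
    rows = gy[inside]
    cols = gx[inside]
    # barycentric weight of vertex i is the opposite edge function / area
    wts = np.stack([edges[1][inside], edges[2][inside], edges[0][inside]], axis=1) / area
    # undo any orientation swap so weights follow the caller's vertex order
    out = np.empty_like(wts)
    out[:, order] = wts
    return rows, cols, out


def rasterize_values(
    proj: np.ndarray,
    triangles: np.ndarray,
    vertex_values: np.ndarray,
    shape: tuple[int, int],
    background: float = 0.0,
) -> np.ndarray:
    """Rasterize per-vertex scalars with barycentric interpolation.

    Later triangles overwrite earlier ones on shared pixels (irrelevant for
    the near-frontal meshes used here, where coverage is essentially
    exclusive by the fill rule).
    """
    img = np.full(shape, float(background))
    for tri_idx in triangles:
        rows, cols, wts = triangle_pixels(proj[tri_idx], shape)
        if rows.size:
            img[rows, cols] = wts @ vertex_values[tri_idx]
    return img
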