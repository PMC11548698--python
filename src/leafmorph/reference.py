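"""Brute-force reference implementations of the shape descriptors.

These are deliberately naive, independent re-derivations used to validate
the production code in :mod:`leafmorph.morphometrics`: an O(n^3)
all-pairs convex hull, a per-pixel exposed-edge count, and an explicit
scan over candidate rectangle orientations. They share no code with the
implementation they check. Too slow for real images; intended for
exhaustive validation on small pixel sets.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "brute_hull",
    "brute_hull_area",
    "brute_hull_perimeter",
    "brute_perimeter",
    "brute_min_area_rect",
    "brute_descriptors",
    "enumerate_connected_pixel_sets",
]


def _corner_points(pixels: list[tuple[int, int]]) -> np.ndarray:
    pts = set()
    for r, c in pixels:
        for dr in (0, 1):
            for dc in (0, 1):
                pts.add((c + dc, r + dr))  # (x, y)
    return np.array(sorted(pts), dtype=float)


def brute_hull(pixels: list[tuple[int, int]]) -> np.ndarray:
    """Convex hull of pixel-square corners by the O(n^3) edge test.

    A directed pair (p, q) is a hull edge iff every other point lies
    strictly left of or on the line p->q. Vertices are returned in
    counter-clockwise order.
    """
    pts = _corner_points(pixels)
    n = len(pts)
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p, q = pts[i], pts[j]
            d = q - p
            cross = d[0] * (pts[:, 1] - p[1]) - d[1] * (pts[:, 0] - p[0])
            if np.all(cross >= -1e-12):
                # keep only the farthest q per direction to skip collinear
                # interior subdivisions of a hull edge
                key = i
                if key not in edges or np.dot(d, d) > edges[key][1]:
                    edges[key] = (j, float(np.dot(d, d)))
    # walk the edge cycle, starting from an extreme point (guaranteed hull
    # vertex; interior points of collinear edge runs are then skipped by the
    # farthest-endpoint rule)
    start = int(np.lexsort((pts[:, 0], pts[:, 1]))[0])
    order = [start]
    nxt = edges[start][0]
    while nxt != start:
        order.append(nxt)
        nxt = edges[nxt][0]
    verts = pts[order]
    # drop collinear runs so the vertex list is minimal
    keep = []
    m = len(verts)
    for k in range(m):
        a, b, c = verts[k - 1], verts[k], verts[(k + 1) % m]
        if abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])) > 1e-12:
            keep.append(k)
    return verts[keep]


def brute_hull_area(pixels: list[tuple[int, int]]) -> float:
    v = brute_hull(pixels)
    s = 0.0
    for k in range(len(v)):
        x0, y0 = v[k - 1]
        x1, y1 = v[k]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def brute_hull_perimeter(pixels: list[tuple[int, int]]) -> float:
    v = brute_hull(pixels)
    return float(sum(math.dist(v[k - 1], v[k]) for k in range(len(v))))


def brute_perimeter(pixels: list[tuple[int, int]]) -> int:
    """Exposed unit edges counted one pixel at a time."""
    pset = set(map(tuple, pixels))
    exposed = 0
    for r, c in pset:
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb not in pset:
                exposed += 1
    return exposed


def brute_min_area_rect(pixels: list[tuple[int, int]]) -> tuple[float, float]:
    """Minimum-area rectangle by explicit rotation at every hull-edge angle.

    Independent route: rotate all corner points with explicit trigonometry
    at each candidate angle and take the axis-aligned extent.
    """
    hull = brute_hull(pixels)
    pts = _corner_points(pixels)
    cands = []
    m = len(hull)
    for k in range(m):
        dx = hull[(k + 1) % m][0] - hull[k][0]
        dy = hull[(k + 1) % m][1] - hull[k][1]
        theta = math.atan2(dy, dx) % (math.pi / 2)
        xs = pts[:, 0] * math.cos(-theta) - pts[:, 1] * math.sin(-theta)
        ys = pts[:, 0] * math.sin(-theta) + pts[:, 1] * math.cos(-theta)
        w = xs.max() - xs.min()
        h = ys.max() - ys.min()
        ang = theta if w >= h else theta + math.pi / 2
        cands.append((w * h, max(w, h), min(w, h), ang))
    min_area = min(c[0] for c in cands)
    # same tie-break convention as the production code: most elongated
    # rectangle first, then smallest angle
    tied = [c for c in cands if c[0] <= min_area * (1 + 1e-9)]
    best = max(tied, key=lambda c: (c[1], -c[3]))
    return float(best[1]), float(best[2])


def brute_descriptors(pixels: list[tuple[int, int]], scale: float = 1.0) -> dict[str, float]:
    """All ten descriptors from the brute-force primitives."""
    A = len(pixels) * scale * scale
    CA = brute_hull_area(pixels) * scale * scale
    CP = brute_hull_perimeter(pixels) * scale
    P = brute_perimeter(pixels) * scale
    L, W = brute_min_area_rect(pixels)
    L, W = L * scale, W * scale
    return {
        "A": A,
        "CA": CA,
        "P": P,
        "CP": CP,
        "L": L,
        "W": W,
        "C": 4.0 * math.pi * A / (P * P),
        "R": A / (L * W),
        "CC": A / CA,
        "E": 1.0 - W / L,
    }


def enumerate_connected_pixel_sets(
    grid: int = 4, max_size: int = 8, dedupe_translates: bool = True
) -> list[tuple[tuple[int, int], ...]]:
    """All 4-connected pixel sets of <= max_size pixels in a grid x grid field.

    Filters every subset of the grid for 4-connectivity (breadth-first
    search). With ``dedupe_translates`` sets identical up to translation are
    reported once (descriptors are translation invariant).
    """
    from itertools import combinations

    cells = [(r, c) for r in range(grid) for c in range(grid)]
    seen = set()
    out = []
    for k in range(1, max_size + 1):
        for combo in combinations(cells, k):
            pset = set(combo)
            stack = [combo[0]]
            visited = {combo[0]}
            while stack:
                r, c = stack.pop()
                for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if nb in pset and nb not in visited:
                        visited.add(nb)
                        stack.append(nb)
            if len(visited) != k:
                continue
            if dedupe_translates:
                r0 = min(r for r, _ in combo)
                c0 = min(c for _, c in combo)
                canon = tuple(sorted((r - r0, c - c0) for r, c in combo))
                if canon in seen:
                    continue
                seen.add(canon)
                out.append(canon)
            else:
                out.append(combo)
    return out
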