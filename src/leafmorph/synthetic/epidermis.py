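"""Synthetic segmented-epidermis generator with exact ground truth.

The tissue is modelled as a Voronoi tessellation of Poisson-disc-sampled
sites (yielding a realistic, sliver-free cell-size distribution). Wall
waviness — the lobed, jigsaw-puzzle outline of pavement cells — is emulated
by displacing every interior Voronoi edge with a sinusoid applied
identically to both adjacent cells, so the tessellation remains an exact
partition of the field at any amplitude. Stomata are inserted at a
prescribed areal density by inscribing a guard-cell-pair ellipse (two
mirrored half-ellipses) inside host polygons.

All geometry is carried in micrometre coordinates as shapely polygons;
rasterization to a segmented-style RGB image happens in
:func:`render_segmented_image`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.affinity import rotate, translate
from shapely.geometry import Polygon

from ..raster import PALETTE, RasterImage

__all__ = [
    "EpidermisParams",
    "EpidermisTruth",
    "generate_tessellation",
    "render_segmented_image",
    "RenderScaleError",
]


class RenderScaleError(ValueError):
    """Raised when the raster scale is too coarse to keep cells separated."""


@dataclass
class EpidermisParams:
    """Generator settings for one epidermis field.

    Physical defaults follow typical potato leaf epidermis: pavement cells
    of ~1500 µm² with wall undulations of a few µm on a 20-50 µm
    wavelength, and guard-cell pairs of ~30 x 22 µm.
    """

    field_width_um: float = 800.0
    field_height_um: float = 800.0
    scale_um_per_px: float = 1.0
    mean_cell_area_um2: float = 1500.0
    waviness_amplitude_um: float = 2.0
    waviness_wavelength_um: float = 30.0
    stomatal_density_per_mm2: float = 150.0
    stoma_length_um: float = 30.0
    stoma_width_um: float = 22.0
    paired_guard_cells: bool = True  # annotate two mirrored cells per stoma
    stoma_margin_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "field_width_um",
            "field_height_um",
            "scale_um_per_px",
            "mean_cell_area_um2",
            "waviness_wavelength_um",
            "stoma_length_um",
            "stoma_width_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.waviness_amplitude_um < 0:
            raise ValueError("waviness_amplitude_um must be >= 0")
        if self.stomatal_density_per_mm2 < 0:
            raise ValueError("stomatal_density_per_mm2 must be >= 0")

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class EpidermisTruth:
    """Ground truth of a generated field: polygons, classes, densities."""

    params: EpidermisParams
    cell_polygons: list[Polygon]
    cell_classes: list[str]  # "pavement" | "stoma", parallel to polygons
    n_stomata: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_polygons)

    @property
    def stomatal_density_per_mm2(self) -> float:
        return self.n_stomata / self.params.field_area_mm2

    def descriptor_table(self) -> pd.DataFrame:
        """True shape descriptors computed directly from the polygons.

        Uses the same formulas as the pixel pipeline but exact polygon
        geometry; the perimeter is the true (smooth) boundary length, so
        circularity is not comparable to the exposed-edge estimate.
        """
        rows = []
        for i, (poly, cls) in enumerate(zip(self.cell_polygons, self.cell_classes)):
            A = poly.area
            hull = poly.convex_hull
            CA, CP = hull.area, hull.length
            P = poly.length
            rect = shapely.minimum_rotated_rectangle(hull)
            xs, ys = rect.exterior.coords.xy
            sides = sorted(
                float(np.hypot(xs[k + 1] - xs[k], ys[k + 1] - ys[k])) for k in range(2)
            )
            W, L = sides
            rows.append(
                {
                    "cell": i,
                    "cell_class": cls,
                    "A": A,
                    "CA": CA,
                    "P": P,
                    "CP": CP,
                    "L": L,
                    "W": W,
                    "C": 4 * np.pi * A / P**2,
                    "R": A / (L * W) if L * W else np.nan,
                    "CC": A / CA,
                    "E": 1 - W / L if L else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _poisson_disc(
    rng: np.random.Generator, n: int, width: float, height: float, radius: float
) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of n sites with min spacing radius.

    The radius is relaxed geometrically if the target count cannot be
    placed, so the call always terminates deterministically.
    """
    pts: list[np.ndarray] = []
    r = radius
    while len(pts) < n:
        placed_any = False
        attempts = 0
        limit = 400 * (n - len(pts)) + 400
        arr = np.empty((0, 2))
        while len(pts) < n and attempts < limit:
            cand = rng.uniform((0, 0), (width, height))
            attempts += 1
            if len(pts) == 0 or np.min(np.hypot(*(arr - cand).T)) >= r:
                pts.append(cand)
                arr = np.asarray(pts)
                placed_any = True
        if len(pts) < n and not placed_any:
            r *= 0.8  # field saturated at this spacing; relax
        elif len(pts) < n:
            r *= 0.9
    return np.asarray(pts)


def _clipped_voronoi(
    sites: np.ndarray, width: float, height: float
) -> tuple[list[Polygon], dict[tuple, float]]:
    """Voronoi cells clipped exactly to the field rectangle.

    Sites are mirrored across all four field edges, so every original
    site's region is finite and its boundary coincides with the rectangle
    at the field border. Also returns, per shared edge (keyed by its
    rounded endpoints), the edge's clearance: half the distance between
    the two generating sites, i.e. how far the wall can bulge before
    reaching a cell centre.
    """
    mirrors = [
        sites * (-1, 1),
        sites * (1, -1),
        np.column_stack([2 * width - sites[:, 0], sites[:, 1]]),
        np.column_stack([sites[:, 0], 2 * height - sites[:, 1]]),
    ]
    all_sites = np.vstack([sites] + mirrors)
    vor = Voronoi(all_sites)
    clearance: dict[tuple, float] = {}
    for (i, j), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in rv or len(rv) != 2:
            continue
        key = _edge_key(vor.vertices[rv[0]], vor.vertices[rv[1]])
        clearance[key] = 0.5 * float(np.hypot(*(all_sites[i] - all_sites[j])))
    polys = []
    for i in range(len(sites)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # regions are convex: angular sort about the centroid gives the
        # boundary order regardless of how qhull listed the vertices
        center = verts.mean(axis=0)
        ang = np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0])
        polys.append(Polygon(verts[np.argsort(ang)]))
    return polys, clearance


def _edge_key(a: np.ndarray, b: np.ndarray) -> tuple:
    ka = (round(a[0], 6), round(a[1], 6))
    kb = (round(b[0], 6), round(b[1], 6))
    return (ka, kb) if ka <= kb else (kb, ka)


def _wavy_polyline(
    v0: np.ndarray,
    v1: np.ndarray,
    amplitude: float,
    wavelength: float,
    phase: float,
    clearance: float = np.inf,
) -> np.ndarray:
    """Sinusoidal perturbation of segment v0->v1, pinned at both endpoints.

    The same polyline (up to reversal) is used by both cells sharing the
    edge, which keeps the tessellation gap- and overlap-free. The
    amplitude is clamped by the edge length and by the edge's clearance
    (half the generating-site distance) so lobes from opposite walls
    cannot pinch a cell interior shut.
    """
    d = v1 - v0
    length = float(np.hypot(*d))
    if length == 0 or amplitude == 0:
        return np.array([v0, v1])
    amp = min(amplitude, 0.3 * length, 0.35 * clearance)
    normal = np.array([-d[1], d[0]]) / length
    n_pts = max(8, int(np.ceil(length / (wavelength / 12.0))))
    t = np.linspace(0.0, 1.0, n_pts + 2)
    s = t * length
    offset = amp * np.sin(2 * np.pi * s / wavelength + phase) * np.sin(np.pi * t)
    pts = v0[None, :] + t[:, None] * d[None, :] + offset[:, None] * normal[None, :]
    pts[0], pts[-1] = v0, v1
    return pts


def _apply_waviness(
    polys: list[Polygon],
    params: EpidermisParams,
    rng: np.random.Generator,
    clearance: dict[tuple, float] | None = None,
) -> list[Polygon]:
    clearance = clearance or {}
    if params.waviness_amplitude_um == 0:
        return polys
    w, h = params.field_width_um, params.field_height_um

    def on_border(a, b) -> bool:
        for coord, lim in ((0, w), (1, h)):
            for val in (0.0, lim):
                if abs(a[coord] - val) < 1e-6 and abs(b[coord] - val) < 1e-6:
                    return True
        return False

    # one deterministic phase per shared edge, independent of traversal order
    phases: dict[tuple, float] = {}

    def phase_for(key: tuple) -> float:
        if key not in phases:
            h64 = abs(hash(key)) % (2**31)
            phases[key] = float(
                np.random.default_rng([params.seed, h64]).uniform(0, 2 * np.pi)
            )
        return phases[key]

    out = []
    for poly in polys:
        coords = np.asarray(poly.exterior.coords)[:-1]
        new_pts: list[np.ndarray] = []
        m = len(coords)
        for k in range(m):
            a, b = coords[k], coords[(k + 1) % m]
            if on_border(a, b):
                seg = np.array([a, b])
            else:
                # build the polyline in the edge's canonical direction so
                # both adjacent cells get the identical geometry, then
                # orient it along this cell's traversal
                key = _edge_key(a, b)
                phase = phase_for(key)
                forward = (round(a[0], 6), round(a[1], 6)) == key[0]
                p0, p1 = (a, b) if forward else (b, a)
                seg = _wavy_polyline(p0, p1, params.waviness_amplitude_um,
                                     params.waviness_wavelength_um, phase,
                                     clearance=clearance.get(key, np.inf))
                if not forward:
                    seg = seg[::-1]
            new_pts.extend(seg[:-1])
        out.append(Polygon(np.asarray(new_pts)))
    return out


def _make_stoma(
    center: tuple[float, float], length: float, width: float, angle_deg: float
) -> tuple[Polygon, Polygon, Polygon]:
    """Ellipse of the guard-cell pair plus its two mirrored halves."""
    n = 64
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ellipse = Polygon(np.column_stack([length / 2 * np.cos(t), width / 2 * np.sin(t)]))
    tt = np.linspace(0, np.pi, n // 2)
    upper = Polygon(
        np.column_stack([length / 2 * np.cos(tt), width / 2 * np.sin(tt)])
    )
    lower = Polygon(
        np.column_stack([length / 2 * np.cos(tt), -width / 2 * np.sin(tt)])
    )
    out = []
    for g in (ellipse, upper, lower):
        g = rotate(g, angle_deg, origin=(0, 0))
        out.append(translate(g, xoff=center[0], yoff=center[1]))
    return tuple(out)


def generate_tessellation(params: EpidermisParams) -> EpidermisTruth:
    """Generate a ground-truth epidermis field.

    Returns polygons in µm coordinates, tagged "pavement" or "stoma"
    (guard cells). Host cells that received a stoma keep their outer wall
    and acquire an interior ring (the guard-cell-pair ellipse).
    """
    area = params.field_width_um * params.field_height_um
    n_cells = int(round(area / params.mean_cell_area_um2))
    if n_cells < 1:
        raise ValueError(
            "field too small for one cell: field area "
            f"{area:.0f} µm² < mean cell area {params.mean_cell_area_um2:.0f} µm²"
        )
    n_stomata = int(round(params.stomatal_density_per_mm2 * params.field_area_mm2))
    if n_stomata > n_cells:
        raise ValueError(
            f"expected stoma count {n_stomata} exceeds cell count {n_cells}; "
            "lower stomatal_density_per_mm2 or mean_cell_area_um2"
        )
    rng = np.random.default_rng(params.seed)
    spacing = 0.7 * np.sqrt(params.mean_cell_area_um2)
    sites = _poisson_disc(rng, n_cells, params.field_width_um, params.field_height_um, spacing)
    polys, clearance = _clipped_voronoi(sites, params.field_width_um, params.field_height_um)
    polys = _apply_waviness(polys, params, rng, clearance)

    classes = ["pavement"] * len(polys)
    cell_polys: list[Polygon] = list(polys)
    placed = 0
    host_order = list(rng.permutation(len(polys)))

    def try_host(host: Polygon, margin: float):
        """Fit the guard-cell ellipse inside a host at the given wall margin."""
        inner = host.buffer(-margin)
        if inner.is_empty:
            return None
        if inner.geom_type == "MultiPolygon":
            inner = max(inner.geoms, key=lambda g: g.area)
        try:
            from shapely.ops import polylabel

            center = polylabel(inner, tolerance=1.0)
        except Exception:  # degenerate slivers
            center = inner.representative_point()
        # prefer the host's own long axis, then random orientations
        rect = shapely.minimum_rotated_rectangle(inner)
        xs, ys = rect.exterior.coords.xy
        sides = [
            (np.hypot(xs[k + 1] - xs[k], ys[k + 1] - ys[k]),
             np.degrees(np.arctan2(ys[k + 1] - ys[k], xs[k + 1] - xs[k])))
            for k in range(2)
        ]
        axis_angle = max(sides)[1]
        angles = [axis_angle] + list(rng.uniform(0, 180, size=11))
        for angle in angles:
            ellipse, upper, lower = _make_stoma(
                (center.x, center.y), params.stoma_length_um, params.stoma_width_um,
                float(angle),
            )
            if inner.contains(ellipse):
                return ellipse, upper, lower
        return None

    for margin in (params.stoma_margin_um, 0.7 * params.stoma_margin_um):
        for host_idx in host_order:
            if placed == n_stomata:
                break
            host = cell_polys[host_idx]
            if classes[host_idx] != "pavement" or host.interiors:
                continue
            fitted = try_host(host, margin)
            if fitted is None:
                continue
            ellipse, upper, lower = fitted
            cell_polys[host_idx] = host.difference(ellipse)
            if params.paired_guard_cells:
                cell_polys.extend([upper, lower])
                classes.extend(["stoma", "stoma"])
            else:
                cell_polys.append(ellipse)
                classes.append("stoma")
            placed += 1
        if placed == n_stomata:
            break
    if placed < n_stomata:
        raise ValueError(
            "stoma dimensions exceed host polygons: placed "
            f"{placed}/{n_stomata} stomata of {params.stoma_length_um}x"
            f"{params.stoma_width_um} µm; enlarge cells or shrink stomata"
        )
    return EpidermisTruth(
        params=params, cell_polygons=cell_polys, cell_classes=classes, n_stomata=placed
    )


def render_segmented_image(
    truth: EpidermisTruth,
    scale_um_per_px: float | None = None,
    margin_px: int = 4,
) -> tuple[RasterImage, np.ndarray]:
    """Rasterize ground truth as a segmented-style RGB micrograph.

    Every pixel centre is assigned to its containing polygon; 1-px outline
    strokes (pure green) are placed on the tissue side of every owner
    change, cell interiors are filled with the class palette colors, and a
    background margin surrounds the tissue. Returns the image plus the
    owner map (polygon index per pixel, -1 outside tissue) used as
    round-trip truth.

    Raises :class:`RenderScaleError` if at this scale some cell has no
    interior pixels or falls apart (two cells would merge or vanish).
    """
    params = truth.params
    s = scale_um_per_px if scale_um_per_px is not None else params.scale_um_per_px
    w_px = int(round(params.field_width_um / s))
    h_px = int(round(params.field_height_um / s))
    H, W = h_px + 2 * margin_px, w_px + 2 * margin_px
    owner = np.full((H, W), -1, dtype=np.int32)

    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    xs = (cols - margin_px + 0.5) * s
    ys = (rows - margin_px + 0.5) * s

    for idx, poly in enumerate(truth.cell_polygons):
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor(minx / s)) + margin_px - 1)
        c1 = min(W, int(np.ceil(maxx / s)) + margin_px + 1)
        r0 = max(0, int(np.floor(miny / s)) + margin_px - 1)
        r1 = min(H, int(np.ceil(maxy / s)) + margin_px + 1)
        if c1 <= c0 or r1 <= r0:
            continue
        sub_x = xs[r0:r1, c0:c1].ravel()
        sub_y = ys[r0:r1, c0:c1].ravel()
        shapely.prepare(poly)
        inside = shapely.contains_xy(poly, sub_x, sub_y).reshape(r1 - r0, c1 - c0)
        block = owner[r0:r1, c0:c1]
        block[inside] = idx
        owner[r0:r1, c0:c1] = block

    # pixel centres exactly on shared walls belong to no polygon; assign to
    # the nearest cell so the tissue footprint stays gap-free
    in_field = (
        (xs > 0) & (xs < params.field_width_um) & (ys > 0) & (ys < params.field_height_um)
    )
    unassigned = in_field & (owner < 0)
    if np.any(unassigned):
        tree = shapely.STRtree(truth.cell_polygons)
        pts = shapely.points(xs[unassigned], ys[unassigned])
        nearest = tree.nearest(pts)
        owner[unassigned] = nearest

    # strokes: for every 4-adjacent pair with different owners mark the
    # tissue-side (or top/left) pixel, so interiors are 4-separated
    stroke = np.zeros((H, W), dtype=bool)
    diff = owner[:, :-1] != owner[:, 1:]
    left_is_tissue = owner[:, :-1] >= 0
    stroke[:, :-1] |= diff & left_is_tissue
    stroke[:, 1:] |= diff & ~left_is_tissue & (owner[:, 1:] >= 0)
    diffv = owner[:-1, :] != owner[1:, :]
    top_is_tissue = owner[:-1, :] >= 0
    stroke[:-1, :] |= diffv & top_is_tissue
    stroke[1:, :] |= diffv & ~top_is_tissue & (owner[1:, :] >= 0)

    # verify the render stays faithful: every cell keeps exactly one
    # 4-connected interior component. Slivers of a few pixels (lobe tips
    # severed by a stroke) are absorbed into the stroke set; anything
    # larger means the scale is genuinely too coarse.
    from scipy import ndimage

    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    sliver_limit = 5
    for idx in range(truth.n_cells):
        cell_interior = (owner == idx) & ~stroke
        n_px = int(cell_interior.sum())
        if n_px == 0:
            raise RenderScaleError(
                f"scale {s} µm/px too coarse: cell {idx} has no interior pixels"
            )
        frag_lab, n_frag = ndimage.label(cell_interior, structure=four)
        if n_frag == 1:
            continue
        sizes = ndimage.sum_labels(cell_interior, frag_lab, np.arange(1, n_frag + 1))
        main = int(np.argmax(sizes)) + 1
        if np.any(np.delete(sizes, main - 1) > sliver_limit):
            raise RenderScaleError(
                f"scale {s} µm/px too coarse: cell {idx} splits into "
                f"fragments of sizes {sizes.astype(int).tolist()}"
            )
        stroke |= cell_interior & (frag_lab != main)

    interior = (owner >= 0) & ~stroke
    _, n_lab = ndimage.label(interior, structure=four)
    if n_lab != truth.n_cells:
        raise RenderScaleError(
            f"scale {s} µm/px too coarse: {n_lab} interior components for "
            f"{truth.n_cells} cells (cells merged, split, or vanished)"
        )

    img = np.zeros((H, W, 3), dtype=np.uint8)
    class_colors = np.array(
        [PALETTE[c] for c in truth.cell_classes] or [(0, 0, 0)], dtype=np.uint8
    )
    tissue = owner >= 0
    img[tissue] = class_colors[owner[tissue]]
    img[stroke] = PALETTE["outline"]
    return RasterImage(img, s), owner


def sidecar_json(truth: EpidermisTruth, scale_um_per_px: float | None = None) -> str:
    """JSON sidecar documenting params, palette and seed for a render."""
    params = truth.params
    return json.dumps(
        {
            "params": dataclasses.asdict(params),
            "palette": {k: list(v) for k, v in PALETTE.items()},
            "seed": params.seed,
            "scale_um_per_px": scale_um_per_px or params.scale_um_per_px,
            "n_cells": truth.n_cells,
            "n_stomata": truth.n_stomata,
        },
        indent=2,
    )
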