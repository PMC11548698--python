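"""Trichome length and density from fold-line micrographs.

The leaf edge is imaged in profile, so trichomes appear as thin dark
protrusions from a dark leaf-body band. The pipeline is:

1. :func:`segment_profile` — foreground by Otsu threshold on luminance.
2. :func:`detect_trichomes` — the leaf body is the morphological opening
   of the foreground with a disc wider than any stalk; protrusions are
   the components of (foreground - body) that touch the body.
3. :func:`measure_trichome` — each protrusion is skeletonized and its
   length taken as the longest geodesic path from the body contact to a
   skeleton endpoint, measured as a subsampled polyline (which removes
   the staircase bias of raw 8-connected step counting), plus the tip
   radius from the distance transform. A terminal blob much wider than
   the stalk marks a glandular head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .raster import BinaryMask, RasterImage

__all__ = [
    "TrichomeRecord",
    "ProfileResult",
    "Protrusion",
    "segment_profile",
    "detect_trichomes",
    "measure_trichome",
    "profile_summary",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class TrichomeRecord:
    """One measured trichome."""

    length_um: float
    glandular: bool
    head_area_um2: float
    base_pos_um: float
    multi_base: bool = False


@dataclass
class Protrusion:
    """A candidate trichome: pixels of one (foreground - body) component."""

    pixels: np.ndarray  # (n, 2) (row, col) in full-image coordinates
    base_pixels: np.ndarray  # contact pixels with the leaf body
    scale_um_per_px: float
    multi_base: bool = False


@dataclass
class ProfileResult:
    """Per-image summary of trichome records."""

    records: list[TrichomeRecord]
    edge_length_mm: float
    density_per_mm: float = field(init=False)
    glandular_density_per_mm: float = field(init=False)
    nonglandular_density_per_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.edge_length_mm > 0:
            raise ValueError("edge length must be > 0")
        n = len(self.records)
        ng = sum(r.glandular for r in self.records)
        self.density_per_mm = n / self.edge_length_mm
        self.glandular_density_per_mm = ng / self.edge_length_mm
        self.nonglandular_density_per_mm = (n - ng) / self.edge_length_mm

    def length_summary(self) -> pd.DataFrame:
        """Median and quartiles of length per class (µm)."""
        frame = self.as_frame()
        if frame.empty:
            return pd.DataFrame(
                columns=["cell_class", "n", "length_q1", "length_median", "length_q3"]
            )
        frame["cell_class"] = np.where(frame["glandular"], "glandular", "non-glandular")
        rows = []
        for cls, grp in frame.groupby("cell_class"):
            q1, med, q3 = np.percentile(grp["length_um"], [25, 50, 75])
            rows.append(
                {
                    "cell_class": cls,
                    "n": len(grp),
                    "length_q1": q1,
                    "length_median": med,
                    "length_q3": q3,
                }
            )
        return pd.DataFrame(rows)

    def as_frame(self) -> pd.DataFrame:
        cols = ["length_um", "glandular", "head_area_um2", "base_pos_um", "multi_base"]
        if not self.records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([vars(r) for r in self.records])[cols]


def segment_profile(
    img: RasterImage, threshold: float | str = "otsu", dark_objects: bool = True
) -> BinaryMask:
    """Foreground (leaf + trichomes) mask of a fold-line micrograph.

    Luminance is thresholded by Otsu's method (or a fixed value); by
    default dark objects on a light background are foreground, which the
    ``dark_objects`` polarity flag inverts. Only the largest connected
    component — the leaf body with its attached protrusions — is kept.
    """
    if img.n_channels >= 3:
        px = img.pixels[:, :, :3].astype(float)
        lum = 0.2126 * px[:, :, 0] + 0.7152 * px[:, :, 1] + 0.0722 * px[:, :, 2]
    else:
        lum = img.channel(0).astype(float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.all(lum == lum.flat[0]):
            raise ValueError("no foreground: image is uniform")
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(lum)
    else:
        thr = threshold
    fg = lum < thr if dark_objects else lum > thr
    if not fg.any():
        raise ValueError("no foreground after thresholding")
    labels, n = ndimage.label(fg, structure=EIGHT_CONNECTED)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    return BinaryMask(labels == largest, img.scale_um_per_px)


def detect_trichomes(mask: BinaryMask, opening_radius_um: float) -> list[Protrusion]:
    """Separate trichome protrusions from the leaf body.

    The body is the morphological opening of the mask with a disc of
    ``opening_radius_um`` (choose it above the widest stalk but below the
    shortest trichome of interest). Components of (mask - body) that touch
    the body are protrusions; their contact pixels define the base. A
    component whose contact splits into several separated runs is flagged
    multi-base (two trichomes may have merged).
    """
    from skimage.morphology import disk, opening

    radius_px = max(1, int(round(opening_radius_um / mask.scale_um_per_px)))
    if 2 * radius_px + 1 > min(mask.shape):
        raise ValueError(
            f"opening radius {opening_radius_um} µm exceeds the leaf body width"
        )
    body = opening(mask.pixels, disk(radius_px))
    if not body.any():
        raise ValueError(
            f"opening radius {opening_radius_um} µm exceeds the leaf body width"
        )
    labels, n = ndimage.label(body, structure=EIGHT_CONNECTED)
    if n > 1:  # keep the largest body fragment
        largest = np.argmax(
            ndimage.sum_labels(body, labels, index=np.arange(1, n + 1))
        ) + 1
        body = labels == largest
    body_halo = ndimage.binary_dilation(body, structure=EIGHT_CONNECTED)

    rest = mask.pixels & ~body
    labels, n = ndimage.label(rest, structure=EIGHT_CONNECTED)
    out: list[Protrusion] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        local = labels[sl] == lab
        rows, cols = np.nonzero(local)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        contact = local & body_halo[sl]
        if not contact.any():
            continue  # floating debris, not attached to the body
        crows, ccols = np.nonzero(contact)
        base = np.column_stack([crows + sl[0].start, ccols + sl[1].start])
        _, n_base = ndimage.label(contact, structure=EIGHT_CONNECTED)
        out.append(
            Protrusion(
                pixels=np.column_stack([rows, cols]),
                base_pixels=base,
                scale_um_per_px=mask.scale_um_per_px,
                multi_base=n_base > 1,
            )
        )
    # stable order along the leaf edge
    out.sort(key=lambda p: p.base_pixels[:, 1].mean())
    return out


def _skeleton_graph(skel: np.ndarray) -> tuple[np.ndarray, coo_matrix]:
    """Skeleton pixels and their 8-neighbour graph (unit / sqrt2 weights)."""
    coords = np.column_stack(np.nonzero(skel))
    index = -np.ones(skel.shape, dtype=int)
    index[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    rows, cols, data = [], [], []
    H, W = skel.shape
    for dr, dc, w in (
        (0, 1, 1.0),
        (1, 0, 1.0),
        (1, 1, np.sqrt(2)),
        (1, -1, np.sqrt(2)),
    ):
        r, c = coords[:, 0], coords[:, 1]
        r2, c2 = r + dr, c + dc
        ok = (r2 >= 0) & (r2 < H) & (c2 >= 0) & (c2 < W)
        ok[ok] &= skel[r2[ok], c2[ok]]
        a = index[r[ok], c[ok]]
        b = index[r2[ok], c2[ok]]
        rows.extend([*a, *b])
        cols.extend([*b, *a])
        data.extend([w] * (2 * len(a)))
    n = len(coords)
    return coords, coo_matrix((data, (rows, cols)), shape=(n, n))


def _polyline_length(path: np.ndarray, step: int = 5) -> float:
    """Euclidean length of a pixel path subsampled every ``step`` pixels."""
    if len(path) < 2:
        return 0.0
    idx = list(range(0, len(path) - 1, step)) + [len(path) - 1]
    pts = path[idx].astype(float)
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def measure_trichome(
    protrusion: Protrusion,
    gland_width_factor: float = 2.0,
) -> TrichomeRecord | None:
    """Measure one protrusion; returns None (with a warning) if too small.

    Length: longest geodesic path over the skeleton from the base contact
    to any endpoint, measured as a subsampled polyline, plus the tip
    radius (distance-transform value at the far endpoint). Glandular: a
    terminal blob survives an opening that removes the stalk and is wider
    than ``gland_width_factor`` times the median stalk width.
    """
    from skimage.morphology import disk, opening, skeletonize

    scale = protrusion.scale_um_per_px
    r0, c0 = protrusion.pixels.min(axis=0)
    r1, c1 = protrusion.pixels.max(axis=0)
    pad = 1
    mask = np.zeros((r1 - r0 + 1 + 2 * pad, c1 - c0 + 1 + 2 * pad), dtype=bool)
    mask[protrusion.pixels[:, 0] - r0 + pad, protrusion.pixels[:, 1] - c0 + pad] = True
    base = np.column_stack(
        [protrusion.base_pixels[:, 0] - r0 + pad, protrusion.base_pixels[:, 1] - c0 + pad]
    )

    skel = skeletonize(mask)
    if skel.sum() < 2:
        warnings.warn("protrusion too small to skeletonize; record dropped")
        return None
    coords, graph = _skeleton_graph(skel)
    dt = ndimage.distance_transform_edt(mask)

    # sources: skeleton pixels nearest to the base contact
    d2base = np.min(
        ((coords[:, None, :] - base[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    src = np.nonzero(d2base <= max(4.0, d2base.min()))[0]
    dist, predecessors, _sources = dijkstra(
        graph.tocsr(), indices=src, min_only=True, return_predecessors=True
    )

    # endpoints: skeleton pixels with at most one skeleton neighbour
    deg = np.asarray((graph.tocsr() > 0).sum(axis=1)).ravel()
    endpoints = np.nonzero(deg <= 1)[0]
    reachable = endpoints[np.isfinite(dist[endpoints])]
    if reachable.size == 0:
        reachable = np.nonzero(np.isfinite(dist))[0]
    tip = int(reachable[np.argmax(dist[reachable])])

    # reconstruct the geodesic path and measure it as a polyline
    path_idx = [tip]
    while predecessors[path_idx[-1]] >= 0:
        path_idx.append(int(predecessors[path_idx[-1]]))
    path = coords[path_idx[::-1]]
    length_px = _polyline_length(path) + float(dt[tuple(coords[tip])])

    # stalk width from the distance transform along the proximal skeleton
    on_path = np.zeros(len(coords), dtype=bool)
    on_path[path_idx] = True
    widths = 2.0 * dt[coords[path_idx, 0], coords[path_idx, 1]]
    n_prox = max(3, int(0.6 * len(widths)))
    stalk_w = float(np.median(widths[-n_prox:]))  # path stored tip -> base

    # glandular head: open away the stalk, look for a blob at the tip
    open_r = max(1, int(np.ceil(0.75 * stalk_w / 2.0)))
    blobs = opening(mask, disk(open_r))
    head_area_um2 = 0.0
    glandular = False
    if blobs.any():
        blab, nb = ndimage.label(blobs, structure=EIGHT_CONNECTED)
        tip_rc = coords[tip]
        lab_at_tip = blab[tip_rc[0], tip_rc[1]]
        if lab_at_tip == 0:
            near = np.column_stack(np.nonzero(blab))
            if len(near):
                d = ((near - tip_rc) ** 2).sum(axis=1)
                if d.min() <= (2 * stalk_w) ** 2:
                    lab_at_tip = blab[tuple(near[np.argmin(d)])]
        if lab_at_tip > 0:
            blob_mask = blab == lab_at_tip
            blob_width = 2.0 * float(dt[blob_mask].max())
            if blob_width > gland_width_factor * stalk_w:
                glandular = True
                head_area_um2 = float(blob_mask.sum()) * scale * scale

    base_pos_um = float(protrusion.base_pixels[:, 1].mean()) * scale
    return TrichomeRecord(
        length_um=length_px * scale,
        glandular=glandular,
        head_area_um2=head_area_um2,
        base_pos_um=base_pos_um,
        multi_base=protrusion.multi_base,
    )


def profile_summary(
    records: list[TrichomeRecord], edge_length_mm: float
) -> ProfileResult:
    """Densities per class and length summaries for one profile image."""
    return ProfileResult(records=[r for r in records if r is not None],
                         edge_length_mm=edge_length_mm)
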