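"""Segmented-micrograph processing: channel arithmetic to labeled cells.

The input convention is a manually segmented RGB micrograph in which cell
outlines are drawn in the green channel over tissue rendered in red.
Subtracting the red from the green channel isolates the outlines; after
binarization and background removal, the inverted image decomposes into
one connected component per cell.

Connectivity convention: outlines are treated as 8-connected barriers and
cell interiors as 4-connected regions, which prevents diagonal leakage
between neighbouring cells.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .raster import BinaryMask, LabeledComponents, RasterImage

__all__ = ["extract_outline_mask", "mask_non_tissue", "label_cells"]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def extract_outline_mask(
    img: RasterImage, threshold: float | str = "otsu"
) -> BinaryMask:
    """Outline mask from the clamped green-minus-red difference.

    The mask is true where ``max(green - red, 0)`` strictly exceeds the
    threshold. ``threshold`` is either a fixed number or ``"otsu"``, in
    which case Otsu's method is applied to the histogram of nonzero
    differences (deterministic; an image with green <= red everywhere
    yields an empty mask). Invariant to adding a constant to both
    channels.
    """
    if img.n_channels < 2:
        raise ValueError(
            "outline extraction needs an RGB image (green minus red); for "
            "grayscale fold-line profiles use the trichome pathway"
        )
    green = img.channel(1).astype(np.int32)
    red = img.channel(0).astype(np.int32)
    diff = np.clip(green - red, 0, None)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        nonzero = diff[diff > 0]
        if nonzero.size == 0:
            return BinaryMask(np.zeros(img.shape, dtype=bool), img.scale_um_per_px)
        if np.all(nonzero == nonzero.flat[0]):
            thr = nonzero.flat[0] - 1  # single level: keep it all
        else:
            from skimage.filters import threshold_otsu

            thr = threshold_otsu(nonzero)
    else:
        thr = threshold
    return BinaryMask(diff > thr, img.scale_um_per_px)


def mask_non_tissue(
    mask: BinaryMask,
    tissue_region: Polygon | np.ndarray | list[tuple[int, int]] | None,
) -> BinaryMask:
    """Remove non-tissue surroundings from an outline mask.

    Pixels outside the tissue region are set to background (mask value
    True, i.e. they act as barriers exactly like outlines, so they never
    become cell components); pixels inside are unchanged. The region is
    either a shapely polygon in pixel coordinates (x=col, y=row), or a
    sequence of ``(row, col)`` flood-fill seeds marking background, whose
    reachable non-outline area is filled. ``None`` or an empty region
    yields an all-background mask. Idempotent for a fixed region.
    """
    out = mask.pixels.copy()
    if tissue_region is None:
        return BinaryMask(np.ones_like(out), mask.scale_um_per_px)
    if isinstance(tissue_region, Polygon):
        if tissue_region.is_empty:
            return BinaryMask(np.ones_like(out), mask.scale_um_per_px)
        minx, miny, maxx, maxy = tissue_region.bounds
        H, W = out.shape
        if minx < -0.5 or miny < -0.5 or maxx > W + 0.5 or maxy > H + 0.5:
            raise ValueError("tissue region lies outside the image bounds")
        import shapely

        cols, rows = np.meshgrid(np.arange(W) + 0.5, np.arange(H) + 0.5)
        shapely.prepare(tissue_region)
        inside = shapely.contains_xy(tissue_region, cols.ravel(), rows.ravel())
        out[~inside.reshape(H, W)] = True
        return BinaryMask(out, mask.scale_um_per_px)
    seeds = np.atleast_2d(np.asarray(tissue_region, dtype=int))
    if seeds.size == 0:
        return BinaryMask(np.ones_like(out), mask.scale_um_per_px)
    H, W = out.shape
    if np.any(seeds < 0) or np.any(seeds[:, 0] >= H) or np.any(seeds[:, 1] >= W):
        raise ValueError("flood-fill seed outside the image bounds")
    free, _ = ndimage.label(~out, structure=FOUR_CONNECTED)
    bg_labels = {free[r, c] for r, c in seeds if free[r, c] > 0}
    if bg_labels:
        out[np.isin(free, sorted(bg_labels))] = True
    return BinaryMask(out, mask.scale_um_per_px)


def _majority_color(img_pixels: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> tuple:
    colors = img_pixels[rows, cols].reshape(len(rows), -1)
    vals, counts = np.unique(colors, axis=0, return_counts=True)
    return tuple(int(v) for v in vals[np.argmax(counts)])


def label_cells(
    mask: BinaryMask,
    img: RasterImage | None = None,
    palette: dict[str, tuple[int, int, int]] | None = None,
    color_tolerance: float = 40.0,
) -> LabeledComponents:
    """Label cell interiors of an outline mask.

    Connected components of the inverted mask are labeled with
    4-connectivity. When an image and a fill palette are given, each
    component is classed by its majority fill color (nearest palette
    entry within ``color_tolerance``, else "unknown"); components whose
    majority color is the palette's background entry are dropped.
    Components touching the image border are flagged border-touching.
    """
    labels, n = ndimage.label(~mask.pixels, structure=FOUR_CONNECTED)
    if n == 0:
        raise ValueError("no cells found: the mask has no interior components")

    pal_names: list[str] = []
    pal_colors: np.ndarray | None = None
    if palette is not None and img is not None:
        pal_names = list(palette)
        pal_colors = np.array([palette[k] for k in pal_names], dtype=float)

    classes: dict[int, str] = {}
    keep: dict[int, int] = {}
    border: set[int] = set()
    remapped = np.zeros_like(labels)
    objects = ndimage.find_objects(labels)
    nxt = 1
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        rows, cols = np.nonzero(labels[sl] == lab)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        cls = "unknown"
        if pal_colors is not None:
            color = _majority_color(img.pixels, rows, cols)
            dist = np.linalg.norm(pal_colors - np.asarray(color, dtype=float), axis=1)
            j = int(np.argmin(dist))
            if dist[j] <= color_tolerance:
                cls = pal_names[j]
        if cls in ("background", "outline"):
            continue
        keep[lab] = nxt
        classes[nxt] = cls
        remapped[rows, cols] = nxt
        H, W = mask.shape
        if rows.min() == 0 or cols.min() == 0 or rows.max() == H - 1 or cols.max() == W - 1:
            border.add(nxt)
        nxt += 1
    if not keep:
        raise ValueError("no cells found: all components were background")
    return LabeledComponents(
        labels=remapped,
        classes=classes,
        border_touching=border,
        scale_um_per_px=mask.scale_um_per_px,
    )
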