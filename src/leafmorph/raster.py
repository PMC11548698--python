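"""Raster containers shared by both imaging pipelines.

Coordinates are 0-based ``(row, col)``; a pixel is the unit square
``[col, col+1) x [row, row+1)`` in pixel units, so physical extent is
``shape * scale_um_per_px``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RasterImage",
    "BinaryMask",
    "LabeledComponents",
    "PALETTE",
    "palette_to_json",
]

#: Reserved palette of the synthetic renderer: colors are chosen so that
#: green - red > 0 exactly on outline strokes and fill colors carry the
#: cell class (red >= green).
PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (0, 0, 0),
    "outline": (0, 255, 0),
    "pavement": (180, 0, 0),
    "stoma": (180, 0, 120),
}


def palette_to_json(palette: dict[str, tuple[int, int, int]] | None = None) -> str:
    """Serialize a fill palette to JSON (emitted as an image sidecar)."""
    pal = palette if palette is not None else PALETTE
    return json.dumps({k: list(v) for k, v in pal.items()}, indent=2)


@dataclass
class RasterImage:
    """A multi-channel pixel grid with a physical scale.

    Parameters
    ----------
    pixels
        ``H x W`` (grayscale) or ``H x W x 3`` (RGB, channel order red,
        green, blue) array of 8- or 16-bit intensities.
    scale_um_per_px
        Physical pixel pitch in micrometres per pixel; must be positive.
    """

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be HxW or HxWxC")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have H, W >= 1")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def channel(self, index: int) -> np.ndarray:
        if self.pixels.ndim == 2:
            if index != 0:
                raise IndexError("grayscale image has a single channel")
            return self.pixels
        return self.pixels[:, :, index]

    def save(self, path: str | Path) -> None:
        """Write as PNG or TIFF depending on the file suffix."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, self.pixels)
        else:
            import imageio.v3 as iio

            iio.imwrite(path, self.pixels)

    @classmethod
    def load(cls, path: str | Path, scale_um_per_px: float) -> "RasterImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            pixels = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            pixels = iio.imread(path)
        if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
            pixels = pixels[:, :, :3]
        return cls(pixels=pixels, scale_um_per_px=scale_um_per_px)


@dataclass
class BinaryMask:
    """A boolean grid at the same scale as its source image."""

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabeledComponents:
    """Cell map: integer labels 1..N over a background/outline of 0.

    ``classes[label]`` is the cell class ("pavement" | "stoma" | "unknown");
    ``border_touching`` flags labels whose pixels touch the image border.
    """

    labels: np.ndarray
    classes: dict[int, str]
    border_touching: set[int] = field(default_factory=set)
    scale_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        present = set(np.unique(self.labels)) - {0}
        if present != set(range(1, len(present) + 1)):
            raise ValueError("labels must be contiguous 1..N")
        if present - set(self.classes):
            raise ValueError("every label needs a class entry")

    @property
    def n_components(self) -> int:
        return len(self.classes)

    def save(self, path: str | Path) -> None:
        """Write the label map as 16-bit PNG/TIFF plus a CSV of classes."""
        import pandas as pd

        RasterImage(self.labels.astype(np.uint16), self.scale_um_per_px).save(path)
        table = pd.DataFrame(
            {
                "label": sorted(self.classes),
                "cell_class": [self.classes[k] for k in sorted(self.classes)],
                "border_touching": [k in self.border_touching for k in sorted(self.classes)],
            }
        )
        table.to_csv(Path(path).with_suffix(".classes.csv"), index=False)
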