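"""Synthetic fold-line micrographs: a leaf-edge band with protruding trichomes.

Emulates transmitted-light images of a leaf folded so that its marginal
trichomes lie in profile: a dark leaf-body band along the bottom image
edge, with trichomes as thin dark curvilinear protrusions of known arc
length. Glandular trichomes carry a terminal disc (the secretory head).
Trichome lengths are log-normal (strictly positive and right-skewed, as
hair-length data typically are).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..raster import RasterImage

__all__ = ["ProfileParams", "ProfileTruth", "TrichomeTruthRecord", "generate_fold_profile"]

BACKGROUND_LEVEL = 230  # transmitted light
TISSUE_LEVEL = 30


@dataclass
class ProfileParams:
    """Generator settings for one fold-line profile image."""

    edge_length_mm: float = 4.0
    trichome_density_per_mm: float = 5.0
    length_median_um: float = 300.0
    length_sigma: float = 0.4  # log-normal shape parameter
    glandular_fraction: float = 0.3
    head_diameter_um: float = 35.0
    stalk_width_um: float = 10.0
    max_bend_rad: float = 0.8  # total turning angle of the arc-shaped stalk
    body_height_um: float = 150.0
    scale_um_per_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "edge_length_mm",
            "length_median_um",
            "head_diameter_um",
            "stalk_width_um",
            "body_height_um",
            "scale_um_per_px",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.trichome_density_per_mm < 0:
            raise ValueError("trichome_density_per_mm must be >= 0")
        if not 0 <= self.glandular_fraction <= 1:
            raise ValueError("glandular_fraction must be in [0, 1]")
        if self.length_sigma < 0:
            raise ValueError("length_sigma must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class TrichomeTruthRecord:
    """One generated trichome.

    ``length_um`` is measured from the base to the apex: the stalk arc
    length, plus the head radius for glandular trichomes.
    """

    length_um: float
    glandular: bool
    base_pos_um: float
    bend_rad: float


@dataclass
class ProfileTruth:
    """Ground truth for one generated profile."""

    params: ProfileParams
    records: list[TrichomeTruthRecord] = field(default_factory=list)

    @property
    def n_trichomes(self) -> int:
        return len(self.records)

    @property
    def density_per_mm(self) -> float:
        return self.n_trichomes / self.params.edge_length_mm

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def _arc_path(length: float, bend: float, tilt: float, step: float) -> np.ndarray:
    """Points along a circular arc of given arc length and total turn.

    Starts at the origin heading straight up (plus a small tilt); returns
    (x, y) offsets in µm with y growing away from the leaf body.
    """
    n = max(2, int(np.ceil(length / step)) + 1)
    s = np.linspace(0.0, length, n)
    if abs(bend) < 1e-9:
        theta = np.full(n, np.pi / 2 + tilt)
        x = np.cos(theta[0]) * s
        y = np.sin(theta[0]) * s
        return np.column_stack([x, y])
    # heading rotates linearly with arc length (constant curvature)
    theta = np.pi / 2 + tilt + bend * s / length
    k = bend / length
    x = (np.sin(theta) - np.sin(np.pi / 2 + tilt)) / k
    y = -(np.cos(theta) - np.cos(np.pi / 2 + tilt)) / k
    return np.column_stack([x, y])


def _draw_disc(img: np.ndarray, row: float, col: float, radius_px: float, value: int) -> None:
    from skimage.draw import disk

    rr, cc = disk((row, col), max(radius_px, 1.0), shape=img.shape)
    img[rr, cc] = value


def generate_fold_profile(
    params: ProfileParams, max_retries: int = 200
) -> tuple[RasterImage, ProfileTruth]:
    """Render one grayscale fold-line profile plus its ground truth.

    The trichome count is deterministic: ``round(density * edge_length)``.
    Trichomes never overlap: bases keep a minimum separation (resampled up
    to ``max_retries``, else an error), all stalks bend the same way — as
    hairs do in a fold preparation, combed flat against the slide — and
    each stalk's bend is reduced (ultimately to straight) until its path
    keeps clear of every previously placed trichome.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(params.seed)
    s = params.scale_um_per_px
    edge_um = params.edge_length_mm * 1000.0
    count = int(round(params.trichome_density_per_mm * params.edge_length_mm))

    clear_um = params.stalk_width_um + params.head_diameter_um / 2.0 + 2.0 * s
    min_sep = max(3.0 * params.stalk_width_um, 1.2 * clear_um)
    if count > 0 and (count - 1) * min_sep > edge_um:
        raise ValueError(
            f"cannot place {count} trichomes with {min_sep:.0f} µm separation "
            f"on a {edge_um:.0f} µm edge; lower the density"
        )
    bases = np.array([])
    if count > 0:
        bases = None
        for _ in range(max_retries):
            cand = np.sort(rng.uniform(0.0, edge_um, size=count))
            if count < 2 or np.all(np.diff(cand) >= min_sep):
                bases = cand
                break
        if bases is None:
            # deterministic fallback: jittered regular spacing
            slots = np.linspace(min_sep / 2, edge_um - min_sep / 2, count)
            bases = np.sort(slots + rng.uniform(-0.1, 0.1, size=count) * min_sep)
            if count >= 2 and not np.all(np.diff(bases) >= min_sep):
                raise ValueError("trichome spacing below stalk width after retries")

    arc_lengths = params.length_median_um * np.exp(
        params.length_sigma * rng.standard_normal(count)
    )
    glandular = rng.uniform(size=count) < params.glandular_fraction

    # place non-crossing combed arcs; whole-image retries with progressively
    # gentler bends, ending in all-straight hairs which (given the base
    # separation) always fit
    paths_um: list[np.ndarray] = []
    final_bends = np.zeros(count)
    n_attempts = 12
    for attempt in range(n_attempts):
        damp = 0.0 if attempt == n_attempts - 1 else 0.8**attempt
        bend_sign = 1.0 if rng.uniform() < 0.5 else -1.0
        bends = bend_sign * rng.uniform(0.1, 1.0, size=count) * params.max_bend_rad * damp
        tilts = rng.normal(0.0, 0.05 * damp, size=count)
        paths_um, final_bends = [], np.zeros(count)
        placed_pts: list[np.ndarray] = []
        ok = True
        for i in range(count):
            chosen = None
            tree = cKDTree(np.vstack(placed_pts)) if placed_pts else None
            for factor in (1.0, 0.5, 0.25, 0.0):
                bend = bends[i] * factor
                tilt = tilts[i] if factor > 0 else 0.0
                pts = _arc_path(arc_lengths[i], bend, tilt, step=s) + (bases[i], 0.0)
                if tree is None or tree.query(pts)[0].min() >= clear_um:
                    chosen = (bend, pts)
                    break
            if chosen is None:
                ok = False
                break
            final_bends[i] = chosen[0]
            paths_um.append(chosen[1])
            placed_pts.append(chosen[1])
        if ok:
            break
    if count and len(paths_um) != count:
        raise ValueError("could not place non-overlapping trichomes; lower the density")

    max_reach = max((p[:, 1].max() for p in paths_um), default=0.0)
    max_excur = max(
        (float(np.abs(p[:, 0] - b).max()) for p, b in zip(paths_um, bases)), default=0.0
    )
    height_um = params.body_height_um + max_reach + params.head_diameter_um + 30.0
    side_margin_um = max_excur + params.head_diameter_um + 20.0
    W = int(round((edge_um + 2 * side_margin_um) / s))
    H = int(round(height_um / s))
    img = np.full((H, W), BACKGROUND_LEVEL, dtype=np.uint8)

    # leaf body band along the bottom edge
    body_rows = int(round(params.body_height_um / s))
    img[H - body_rows :, :] = TISSUE_LEVEL
    body_top_row = H - body_rows

    records = []
    stalk_r_px = max(params.stalk_width_um / 2.0 / s, 1.0)
    for i in range(count):
        pts = paths_um[i]
        x_px = (pts[:, 0] + side_margin_um) / s
        y_px = body_top_row - pts[:, 1] / s
        for xp, yp in zip(x_px, y_px):
            _draw_disc(img, yp, xp, stalk_r_px, TISSUE_LEVEL)
        length = float(arc_lengths[i])
        if glandular[i]:
            _draw_disc(img, y_px[-1], x_px[-1], params.head_diameter_um / 2.0 / s, TISSUE_LEVEL)
            length += params.head_diameter_um / 2.0  # apex of the head
        records.append(
            TrichomeTruthRecord(
                length_um=length,
                glandular=bool(glandular[i]),
                base_pos_um=float(bases[i]),
                bend_rad=float(final_bends[i]),
            )
        )
    return RasterImage(img, s), ProfileTruth(params=params, records=records)
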