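"""End-to-end pipeline: extract -> measure -> trichomes -> stats.

Every run writes all intermediate tables, a JSON log of the effective
parameters (so defaults are auditable), and a summary; reruns with the
same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .morphometrics import build_sample_table, components_from_labels, stomatal_density
from .outline import extract_outline_mask, label_cells
from .raster import PALETTE, RasterImage
from .stats import build_species_profiles, cluster_species, kendall_matrix, run_pca
from .trichomes import detect_trichomes, measure_trichome, profile_summary, segment_profile

log = logging.getLogger("leafmorph")

__all__ = ["run_pipeline", "measure_segmented_image", "measure_profile_image"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, path: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage
        self.path = path


def _load_palette(config: PipelineConfig) -> dict[str, tuple[int, int, int]]:
    if config.palette_file is None:
        return PALETTE
    raw = json.loads(Path(config.palette_file).read_text())
    return {k: tuple(v) for k, v in raw.items()}


def measure_segmented_image(
    img: RasterImage,
    metadata: dict[str, str],
    palette: dict[str, tuple[int, int, int]] | None = None,
    threshold: float | str = "otsu",
    include_border: bool = False,
    guard_cell_pairing: int = 2,
    perimeter_method: str = "edges",
) -> tuple[pd.DataFrame, dict]:
    """Cells table plus density summary for one segmented micrograph."""
    palette = palette or PALETTE
    mask = extract_outline_mask(img, threshold=threshold)
    labeled = label_cells(mask, img=img, palette=palette)
    table = build_sample_table(
        labeled, metadata, include_border=include_border, perimeter_method=perimeter_method
    )
    comps = components_from_labels(labeled)
    tissue_px = int(np.count_nonzero(img.pixels.reshape(img.shape[0], img.shape[1], -1).any(axis=2)))
    tissue_area_mm2 = tissue_px * (img.scale_um_per_px**2) / 1e6
    dens = stomatal_density(comps, tissue_area_mm2, guard_cell_pairing=guard_cell_pairing)
    table["st_density_per_mm2"] = dens.stomatal_density_per_mm2
    table["pave_density_per_mm2"] = dens.pavement_density_per_mm2
    return table, vars(dens)


def measure_profile_image(
    img: RasterImage,
    edge_length_mm: float,
    opening_radius_um: float = 15.0,
    threshold: float | str = "otsu",
):
    """ProfileResult for one fold-line micrograph."""
    mask = segment_profile(img, threshold=threshold)
    protrusions = detect_trichomes(mask, opening_radius_um)
    records = [measure_trichome(p) for p in protrusions]
    return profile_summary([r for r in records if r is not None], edge_length_mm)


def _trichome_species_summary(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-species tr_L / tr_D / gtr_L / gtr_D from per-image trichome rows."""
    if not frames:
        return pd.DataFrame()
    all_rows = pd.concat(frames, ignore_index=True)
    out = {}
    for species, grp in all_rows.groupby("species"):
        edge = grp.groupby("image_id")["edge_length_mm"].first().sum()
        ngl = grp[~grp["glandular"]]
        gl = grp[grp["glandular"]]
        out[species] = {
            "tr_L": ngl["length_um"].median() if len(ngl) else np.nan,
            "tr_D": len(ngl) / edge,
            "gtr_L": gl["length_um"].median() if len(gl) else np.nan,
            "gtr_D": len(gl) / edge,
        }
    return pd.DataFrame(out).T.rename_axis("species")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages of a configured analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    palette = _load_palette(config)

    cell_tables, density_rows = [], []
    for entry in config.segmented_images:
        image_id = entry.image_id or Path(entry.path).stem
        try:
            img = RasterImage.load(entry.path, entry.scale_um_per_px)
            table, dens = measure_segmented_image(
                img,
                {"species": entry.species, "side": entry.side, "image_id": image_id},
                palette=palette,
                threshold=config.outline_threshold,
                include_border=config.include_border_cells,
                guard_cell_pairing=config.guard_cell_pairing,
                perimeter_method=config.perimeter_method,
            )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("extract/measure", entry.path, exc) from exc
        cell_tables.append(table)
        density_rows.append({"image_id": image_id, "species": entry.species,
                             "side": entry.side, **dens})
    cells = pd.concat(cell_tables, ignore_index=True) if cell_tables else pd.DataFrame()
    cells.to_csv(out / "cells.csv", index=False)
    pd.DataFrame(density_rows).to_csv(out / "densities.csv", index=False)

    trich_frames = []
    for entry in config.profile_images:
        image_id = entry.image_id or Path(entry.path).stem
        try:
            img = RasterImage.load(entry.path, entry.scale_um_per_px)
            result = measure_profile_image(
                img, entry.edge_length_mm, opening_radius_um=entry.opening_radius_um
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("trichomes", entry.path, exc) from exc
        frame = result.as_frame()
        frame["species"] = entry.species
        frame["image_id"] = image_id
        frame["edge_length_mm"] = entry.edge_length_mm
        trich_frames.append(frame)
    trich = pd.concat(trich_frames, ignore_index=True) if trich_frames else pd.DataFrame()
    trich.to_csv(out / "trichomes.csv", index=False)

    summary: dict = {"n_cells": int(len(cells)), "n_trichomes": int(len(trich))}
    if len(cells):
        try:
            trich_summary = _trichome_species_summary(trich_frames)
            profile = build_species_profiles(cells, trich_summary)
            profile.to_csv(out / "species_profiles.csv")
            level = config.stats.correlation_level
            if level == "image" and cells["image_id"].nunique() < 3:
                log.info("fewer than 3 images; correlating per-cell rows instead")
                level = "cell"
            corr = kendall_matrix(
                cells,
                features=[c for c in cells.columns
                          if pd.api.types.is_numeric_dtype(cells[c]) and c != "label"],
                level=level,
            )
            corr.to_csv(out / "kendall_correlation.csv")
            if len(profile) >= 2:
                numeric = profile.dropna(axis=1)
                constant = [c for c in numeric.columns if numeric[c].nunique() == 1]
                if constant and config.stats.standardize:
                    log.info("dropping constant feature(s): %s", ", ".join(constant))
                    profile = profile.drop(columns=constant)
                pca = run_pca(profile, standardize=config.stats.standardize)
                pca.loadings.to_csv(out / "pca_loadings.csv")
                pca.scores.to_csv(out / "pca_scores.csv")
                pd.Series(pca.variance_fractions, name="variance_fraction").to_csv(
                    out / "pca_variance.csv", index_label="component"
                )
                clust = cluster_species(
                    profile,
                    metric=config.stats.cluster_metric,
                    method=config.stats.cluster_linkage,
                    standardize=config.stats.standardize,
                )
                pd.DataFrame(
                    clust.linkage, columns=["child_a", "child_b", "height", "n_leaves"]
                ).to_csv(out / "linkage.csv", index=False)
                (out / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
                summary["pca_variance_fractions"] = [
                    float(v) for v in pca.variance_fractions[:3]
                ]
                summary["cluster_labels"] = clust.flat_labels(config.stats.n_cluster_groups)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("stats", str(out), exc) from exc

    (out / "run_log.json").write_text(
        json.dumps(
            {"version": __version__, "config": config.model_dump(), "summary": summary},
            indent=2,
            default=str,
        )
    )
    log.info("pipeline finished: %s", summary)
    return out
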