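"""Self-contained validation experiments on synthetic ground truth.

Each function generates synthetic data with the package's own generator,
runs the measurement pipeline on it, and compares the result with the
generator's truth. They are used by the acceptance script and the test
suite; problem sizes are chosen to finish on a single CPU in seconds to
a few minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .morphometrics import components_from_labels, stomatal_density
from .outline import extract_outline_mask, label_cells
from .pipeline import measure_profile_image, measure_segmented_image
from .raster import PALETTE
from .synthetic import (
    EpidermisParams,
    ProfileParams,
    generate_fold_profile,
    generate_tessellation,
    render_segmented_image,
)

__all__ = [
    "roundtrip_validation",
    "stomatal_density_recovery",
    "trichome_recovery",
    "waviness_curve",
    "two_regime_experiment",
]


def roundtrip_validation(seed: int = 0, n_images: int = 10) -> dict:
    """Segmentation round trip on fields of ~50-200 cells.

    Renders ``n_images`` wavy fields with stomata, re-extracts the cells
    and checks label count and per-cell class assignment against truth.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.choice([300, 330, 360, 400, 430, 460, 500], size=n_images)
    count_ok = 0
    cells_total = 0
    cells_class_ok = 0
    for i in range(n_images):
        side = float(sizes[i])
        params = EpidermisParams(
            field_width_um=side,
            field_height_um=side,
            waviness_amplitude_um=3.0,
            stomatal_density_per_mm2=60.0,
            seed=int(seed * 1000 + i),
        )
        truth = generate_tessellation(params)
        assert 50 <= truth.n_cells <= 205
        img, owner = render_segmented_image(truth)
        labeled = label_cells(extract_outline_mask(img), img=img, palette=PALETTE)
        if labeled.n_components == truth.n_cells:
            count_ok += 1
        for label in range(1, labeled.n_components + 1):
            r, c = np.argwhere(labeled.labels == label)[0]
            cells_total += 1
            if labeled.classes[label] == truth.cell_classes[owner[r, c]]:
                cells_class_ok += 1
    return {
        "n_images": n_images,
        "count_ok": count_ok,
        "n_cells": cells_total,
        "class_accuracy": cells_class_ok / cells_total,
    }


def stomatal_density_recovery(
    seed: int = 0, densities: tuple[float, ...] = (10.0, 30.0, 60.0)
) -> dict:
    """True vs. pipeline-recovered stomatal density on 1 mm² fields."""
    errors = {}
    for density in densities:
        params = EpidermisParams(
            field_width_um=1000.0,
            field_height_um=1000.0,
            waviness_amplitude_um=2.0,
            stomatal_density_per_mm2=density,
            seed=int(seed * 100 + density),
        )
        truth = generate_tessellation(params)
        img, _ = render_segmented_image(truth)
        labeled = label_cells(extract_outline_mask(img), img=img, palette=PALETTE)
        comps = components_from_labels(labeled)
        tissue_mm2 = float(np.count_nonzero(img.pixels.any(axis=2))) * 1e-6
        est = stomatal_density(comps, tissue_mm2).stomatal_density_per_mm2
        errors[density] = abs(est - density) / density
    return {"relative_errors": errors, "max_relative_error": max(errors.values())}


def trichome_recovery(seed: int = 0, n_target: int = 200) -> dict:
    """Length-distribution and density recovery on a long synthetic edge."""
    density = 10.0
    edge_mm = n_target / density
    params = ProfileParams(
        edge_length_mm=edge_mm, trichome_density_per_mm=density, seed=seed
    )
    img, truth = generate_fold_profile(params)
    result = measure_profile_image(img, edge_mm, opening_radius_um=15.0)
    measured = np.array([r.length_um for r in result.records])
    true_lengths = np.array([r.length_um for r in truth.records])
    ks = ks_2samp(measured, true_lengths).statistic
    return {
        "n": truth.n_trichomes,
        "true_density_per_mm": truth.density_per_mm,
        "est_density_per_mm": result.density_per_mm,
        "density_rel_error": abs(result.density_per_mm - truth.density_per_mm)
        / truth.density_per_mm,
        "true_median_um": float(np.median(true_lengths)),
        "est_median_um": float(np.median(measured)),
        "median_rel_error": abs(np.median(measured) - np.median(true_lengths))
        / np.median(true_lengths),
        "ks_distance": float(ks),
    }


def waviness_curve(
    seed: int = 0, amplitudes: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
) -> dict:
    """Mean true waviness index across a wall-amplitude grid."""
    means = {}
    for amplitude in amplitudes:
        params = EpidermisParams(
            field_width_um=400.0,
            field_height_um=400.0,
            waviness_amplitude_um=amplitude,
            stomatal_density_per_mm2=0.0,
            seed=seed,
        )
        truth = generate_tessellation(params)
        means[amplitude] = float(truth.descriptor_table()["CC"].mean())
    vals = list(means.values())
    return {
        "mean_cc": means,
        "strictly_decreasing": all(a > b for a, b in zip(vals, vals[1:])),
    }


REGIME_LARGE_WAVY = dict(
    mean_cell_area_um2=2000.0,
    waviness_amplitude_um=5.0,
    stomatal_density_per_mm2=100.0,
    stoma_length_um=30.0,
    stoma_width_um=22.0,
)
REGIME_SMALL_SMOOTH = dict(
    mean_cell_area_um2=800.0,
    waviness_amplitude_um=1.0,
    stomatal_density_per_mm2=250.0,
    stoma_length_um=20.0,
    stoma_width_um=14.0,
)


def two_regime_experiment(seed: int = 0, species_per_regime: int = 4) -> dict:
    """Two synthetic 'clades' of species with contrasting epidermis types.

    One regime has large wavy-walled cells at low stomatal density, the
    other small smooth cells at high density. Each pseudo-species is one
    generated field run through the full measurement pipeline; species
    median profiles then go into PCA and hierarchical clustering.
    """
    from sklearn.metrics import adjusted_rand_score

    from .stats import build_species_profiles, cluster_species, run_pca

    tables = []
    truth_labels = {}
    for regime_idx, regime in enumerate((REGIME_LARGE_WAVY, REGIME_SMALL_SMOOTH)):
        for k in range(species_per_regime):
            name = f"regime{regime_idx}_sp{k}"
            params = EpidermisParams(
                field_width_um=400.0,
                field_height_um=400.0,
                seed=int(seed * 100 + 10 * regime_idx + k),
                **regime,
            )
            truth = generate_tessellation(params)
            img, _ = render_segmented_image(truth)
            table, _ = measure_segmented_image(
                img, {"species": name, "side": "ab", "image_id": name}
            )
            tables.append(table)
            truth_labels[name] = regime_idx
    cells = pd.concat(tables, ignore_index=True)
    profile = build_species_profiles(cells)
    pca = run_pca(profile)
    labels = cluster_species(profile).flat_labels(2)
    names = sorted(truth_labels)
    ari = adjusted_rand_score(
        [truth_labels[n] for n in names], [labels[n] for n in names]
    )
    pc1 = pca.scores["PC1"]
    groups = [pc1[[n for n in names if truth_labels[n] == g]] for g in (0, 1)]
    separated = max(groups[0]) < min(groups[1]) or max(groups[1]) < min(groups[0])
    return {
        "n_species": len(names),
        "n_cells": int(len(cells)),
        "variance_fractions": pca.variance_fractions,
        "ari": float(ari),
        "pc1_separates_regimes": bool(separated),
    }
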