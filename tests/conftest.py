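import numpy as np
import pytest

from leafmorph import (
    EpidermisParams,
    ProfileParams,
    generate_fold_profile,
    generate_tessellation,
    render_segmented_image,
)


@pytest.fixture(scope="session")
def epidermis_truth():
    """Medium wavy field with stomata: 500x500 µm, ~197 cells."""
    params = EpidermisParams(
        field_width_um=500,
        field_height_um=500,
        waviness_amplitude_um=3.0,
        stomatal_density_per_mm2=60.0,
        seed=0,
    )
    return generate_tessellation(params)


@pytest.fixture(scope="session")
def epidermis_render(epidermis_truth):
    """Rendered segmented image plus the owner (polygon index) map."""
    return render_segmented_image(epidermis_truth)


@pytest.fixture(scope="session")
def fold_profile():
    """4 mm edge at 5 trichomes/mm (20 hairs), default length distribution."""
    params = ProfileParams(edge_length_mm=4.0, trichome_density_per_mm=5.0, seed=1)
    img, truth = generate_fold_profile(params)
    return params, img, truth


def random_blob(rng: np.random.Generator, n_pixels: int) -> list[tuple[int, int]]:
    """A random 4-connected pixel set grown by a lattice random walk."""
    pixels = {(0, 0)}
    frontier = [(0, 0)]
    while len(pixels) < n_pixels:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(4)]
        nb = (r + dr, c + dc)
        if nb not in pixels:
            pixels.add(nb)
            frontier.append(nb)
    return sorted(pixels)
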