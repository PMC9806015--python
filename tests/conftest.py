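import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import spatialtme as st
from spatialtme.synthetic import ProcessSpec, assign_markers, render_scene, simulate_point_pattern

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel1():
    return st.default_panel(1)


@pytest.fixture(scope="session")
def panel2():
    return st.default_panel(2)


def make_separated_scene(panel, seed=3, shape=(400, 400), n_expect=120,
                         marker_probs=None, noise_level=0.0):
    """A rendered scene with well-separated nuclei (hard-core placement)."""
    mask = np.ones(shape, bool)
    spec = ProcessSpec("inhibited", n_expect / mask.sum(), inhibition_radius=25)
    pts = simulate_point_pattern(mask, spec, seed=seed)
    if marker_probs is None:
        marker_probs = {panel.markers[0]: 0.4, panel.markers[1]: 0.3,
                        panel.markers[2]: 0.3}
    cells = assign_markers(pts, panel, marker_probs, seed=seed + 1)
    return render_scene(cells, panel, image_shape=shape, seed=seed + 2,
                        noise_level=noise_level)


@pytest.fixture(scope="session")
def separated_scene(panel1):
    return make_separated_scene(panel1)


def random_cells(n, panel, rng, size=500.0):
    """Random cell table with random (possibly multi-positive) marker sets."""
    sets = []
    for _ in range(n):
        k = rng.choice([1, 1, 1, 2])
        sets.append(frozenset(rng.choice(panel.markers, size=k, replace=False)))
    return pd.DataFrame(
        {
            "x": rng.uniform(0, size, n),
            "y": rng.uniform(0, size, n),
            "panel": panel.panel_id,
            "markers": sets,
        }
    )
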