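"""Marker assignment and scene rendering for synthetic mIF images.

A scene emulates one field of view of a multiplex-immunofluorescence scan:
a DAPI-like nuclear stain in the blue channel plus up to five markers of
one panel, each rendered into its assigned red or green channel at an
amplitude determined by its intensity level ('+', '++', '+++' map to the
X / 2X / 3X positivity bands). Because several markers of a panel share a
channel in the composite RGB image, the renderer also returns one
*component map* per marker — the analogue of a spectrally unmixed
single-antigen image — and downstream marker detection operates on those.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk

from ..detection import MarkerThresholds
from ..panels import PanelSpec

LEVELS = ("+", "++", "+++")
#: rendered amplitude per level, as a multiple of the positivity threshold X;
#: chosen to sit inside the [X,2X), [2X,3X), [3X,inf) bands after mild blur
LEVEL_AMPLITUDE = {"+": 1.4, "++": 2.5, "+++": 3.5}


def assign_markers(
    positions: np.ndarray,
    panel: PanelSpec,
    marker_probs: dict,
    coexpression_rules: tuple = (),
    seed: int = 0,
    level_probs: tuple[float, float, float] = (0.3, 0.4, 0.3),
) -> "pd.DataFrame":
    """Assign marker phenotypes and intensity levels to cell positions.

    ``marker_probs`` is a mixture over single-marker phenotypes: each cell is
    positive for marker ``m`` with probability ``marker_probs[m]`` and
    marker-negative with the remaining probability (the probabilities must
    sum to <= 1). ``coexpression_rules`` is a sequence of
    ``(marker_a, marker_b, p)`` triples: a cell positive for ``marker_a``
    additionally gains ``marker_b`` with probability ``p``, producing
    multi-positive phenotypes such as CD8+CD133+ cells.

    Returns a DataFrame with columns ``cell_id, x, y, panel, markers,
    levels`` where ``markers`` is a frozenset and ``levels`` a dict
    marker -> level for the positive markers.
    """
    import pandas as pd

    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    for m in marker_probs:
        if m not in panel.markers:
            raise ValueError(f"marker {m!r} is not in panel {panel.panel_id}")
    for a, b, p in coexpression_rules:
        if a not in panel.markers or b not in panel.markers:
            raise ValueError(f"coexpression rule ({a}, {b}) outside panel")
        if not 0 <= p <= 1:
            raise ValueError("coexpression probability must be in [0, 1]")
    names = [m for m in panel.markers if m in marker_probs]
    probs = np.array([marker_probs[m] for m in names], dtype=float)
    if np.any(probs < 0) or probs.sum() > 1 + 1e-12:
        raise ValueError("marker_probs must be non-negative and sum to <= 1")

    rng = np.random.default_rng(seed)
    n = len(positions)
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    u = rng.random(n)
    marker_sets: list[set] = [set() for _ in range(n)]
    for i, m in enumerate(names):
        hit = (u >= cum[i]) & (u < cum[i + 1])
        for j in np.nonzero(hit)[0]:
            marker_sets[j].add(m)
    for a, b, p in coexpression_rules:
        for j in range(n):
            if a in marker_sets[j] and rng.random() < p:
                marker_sets[j].add(b)

    lv = np.asarray(level_probs, dtype=float)
    lv = lv / lv.sum()
    levels = []
    for j in range(n):
        levels.append(
            {m: LEVELS[rng.choice(3, p=lv)] for m in sorted(marker_sets[j])}
        )
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "panel": panel.panel_id,
            "markers": [frozenset(s) for s in marker_sets],
            "levels": levels,
        }
    )


@dataclass
class SceneGroundTruth:
    """Simulated truth for one rendered scene."""

    shape: tuple[int, int]
    label_mask: np.ndarray  # int32, one positive label per nucleus
    cells: "pd.DataFrame"  # cell table as produced by assign_markers
    tn_mask: np.ndarray | None = None
    ts_mask: np.ndarray | None = None


@dataclass
class Scene:
    """One rendered synthetic mIF field.

    ``rgb`` is the uint8 composite; ``marker_maps`` holds one float
    component image per marker (unmixed single-antigen analogue);
    ``nuclear_map`` is the DAPI-like channel before compositing.
    """

    rgb: np.ndarray
    marker_maps: dict
    nuclear_map: np.ndarray
    ground_truth: SceneGroundTruth
    thresholds: MarkerThresholds = field(default_factory=MarkerThresholds)


def render_scene(
    cells: "pd.DataFrame",
    panel: PanelSpec,
    image_shape: tuple[int, int] = (1024, 1024),
    nucleus_radius: float = 6.0,
    psf_sigma: float = 1.0,
    noise_level: float = 0.0,
    seed: int = 0,
    thresholds: MarkerThresholds | None = None,
    nuclear_amplitude: float = 200.0,
    tn_mask: np.ndarray | None = None,
    ts_mask: np.ndarray | None = None,
) -> Scene:
    """Render a cell table into an RGB scene plus ground truth.

    Nuclei are drawn as discs of ``nucleus_radius`` in the blue channel and
    in the integer label mask; each positive marker is drawn as a disc in
    that marker's component map at an amplitude set by its intensity level.
    ``noise_level`` is the expected number of small speckle objects (1–2 px
    radius, below typical denoising size cuts) added per marker map, for
    denoising tests. A Gaussian PSF of ``psf_sigma`` blurs all stains.
    Deterministic for a fixed seed.
    """
    if thresholds is None:
        thresholds = MarkerThresholds.default(panel.markers)
    h, w = image_shape
    xs = cells["x"].to_numpy(dtype=float)
    ys = cells["y"].to_numpy(dtype=float)
    if len(cells) and (
        xs.min() < -0.5 or xs.max() > w - 0.5 or ys.min() < -0.5 or ys.max() > h - 0.5
    ):
        raise ValueError("cells do not fit inside image_shape")

    rng = np.random.default_rng(seed)
    label_mask = np.zeros((h, w), dtype=np.int32)
    nuclear = np.zeros((h, w), dtype=float)
    overlap_px = 0
    for cid, x, y in zip(cells["cell_id"], xs, ys):
        rr, cc = disk((y, x), nucleus_radius, shape=(h, w))
        overlap_px += int(np.count_nonzero(label_mask[rr, cc]))
        label_mask[rr, cc] = int(cid) + 1
        nuclear[rr, cc] = nuclear_amplitude
    total_px = max(1, len(cells)) * np.pi * nucleus_radius**2
    if overlap_px > 0.2 * total_px:
        warnings.warn(
            f"nuclei overlap heavily ({overlap_px} px); labels overwrite",
            stacklevel=2,
        )

    marker_maps = {}
    for m in panel.markers:
        img = np.zeros((h, w), dtype=float)
        x_level = thresholds.x[m]
        for x, y, mk, lv in zip(xs, ys, cells["markers"], cells["levels"]):
            if m in mk:
                rr, cc = disk((y, x), nucleus_radius, shape=(h, w))
                img[rr, cc] = LEVEL_AMPLITUDE[lv[m]] * x_level
        # speckle noise: small bright non-cell objects
        n_specks = rng.poisson(noise_level)
        for _ in range(n_specks):
            sy, sx = rng.uniform(0, h), rng.uniform(0, w)
            rr, cc = disk((sy, sx), rng.uniform(1.0, 2.0), shape=(h, w))
            img[rr, cc] = rng.uniform(1.1, 3.0) * x_level
        if psf_sigma > 0:
            img = gaussian_filter(img, psf_sigma)
        marker_maps[m] = img

    if psf_sigma > 0:
        nuclear = gaussian_filter(nuclear, psf_sigma)

    rgb = np.zeros((h, w, 3), dtype=float)
    for m, img in marker_maps.items():
        ch = 0 if panel.channel_of_marker[m] == "R" else 1
        rgb[:, :, ch] += img
    rgb[:, :, 2] = nuclear
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    gt = SceneGroundTruth(
        shape=(h, w),
        label_mask=label_mask,
        cells=cells.reset_index(drop=True),
        tn_mask=tn_mask,
        ts_mask=ts_mask,
    )
    return Scene(rgb=rgb, marker_maps=marker_maps, nuclear_map=nuclear,
                 ground_truth=gt, thresholds=thresholds)


def halves_region_masks(image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Simple disjoint tumour-nest / tumour-stroma masks: left and right halves."""
    h, w = image_shape
    tn = np.zeros((h, w), dtype=bool)
    ts = np.zeros((h, w), dtype=bool)
    tn[:, : w // 2] = True
    ts[:, w // 2 :] = True
    return tn, ts
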