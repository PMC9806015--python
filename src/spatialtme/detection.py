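"""Cell detection, typing and quantitative summaries from mIF images.

The pipeline: split the RGB scan into channels, threshold each marker's
component image at its positivity threshold X (removing small noise
objects), detect nuclei on the DAPI-like channel with a classical
smoothing / thresholding / distance-transform-watershed detector, then
intersect nucleus centroids with the marker masks to obtain typed cells.
Intensity is binned at X / 2X / 3X into '+', '++', '+++', which feed the
H-score; region masks (tumour nest TN vs. tumour stroma TS) assign each
cell a compartment, and densities (per mm^2), percentages (%/sight) and
H-scores are summarised per phenotype and region.

Nucleus detection is a pluggable interface: any callable with the
``detect_nuclei`` signature can replace the classical default (e.g. a
learned star-convex detector); the pipeline around it is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .panels import PanelSpec

DEFAULT_THRESHOLD_X = 60.0  # positivity threshold on the 0-255 channel scale
BIN_LOW, BIN_MEDIAN, BIN_HIGH = "+", "++", "+++"


@dataclass(frozen=True)
class MarkerThresholds:
    """Per-marker positivity threshold X.

    Bin boundaries are exactly [X, 2X) -> '+', [2X, 3X) -> '++',
    [3X, inf) -> '+++'; values below X are negative.
    """

    x: dict = field(default_factory=dict)

    def __post_init__(self):
        for m, v in self.x.items():
            if v <= 0:
                raise ValueError(f"threshold X for {m!r} must be > 0")

    @classmethod
    def default(cls, markers, x: float = DEFAULT_THRESHOLD_X) -> "MarkerThresholds":
        return cls({m: float(x) for m in markers})

    def bin(self, marker: str, value: float) -> str | None:
        """Intensity bin of a channel value, or None if below X."""
        if marker not in self.x:
            raise KeyError(f"no threshold configured for marker {marker!r}")
        x = self.x[marker]
        if value < x:
            return None
        if value < 2 * x:
            return BIN_LOW
        if value < 3 * x:
            return BIN_MEDIAN
        return BIN_HIGH


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Losslessly split an RGB image into (R, G, B) channel maps."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    return image[:, :, 0], image[:, :, 1], image[:, :, 2]


def extract_marker_mask(
    channel_map: np.ndarray,
    marker: str,
    thresholds: MarkerThresholds,
    min_object_px: int = 10,
) -> np.ndarray:
    """Binary stained-area mask: pixels >= X, small objects removed."""
    if marker not in thresholds.x:
        raise KeyError(f"no threshold configured for marker {marker!r}")
    mask = np.asarray(channel_map, dtype=float) >= thresholds.x[marker]
    if min_object_px > 0:
        # components strictly smaller than min_object_px are removed
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return mask


@dataclass(frozen=True)
class NucleusDetectorConfig:
    """Classical nucleus detector settings.

    ``threshold``: absolute intensity cut on the smoothed nuclear channel;
    ``None`` uses Otsu. ``min_distance`` separates watershed seed peaks,
    and should be of the order of the nucleus radius.
    """

    smooth_sigma: float = 2.0
    threshold: float | None = None
    min_distance: int = 5
    min_area: int = 9


def detect_nuclei(
    nuclear_map: np.ndarray, config: NucleusDetectorConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect nuclei on a single-channel nuclear image.

    Returns ``(centroids, label_mask)`` where centroids is an ``(n, 2)``
    array of ``(x, y)`` positions and label_mask an int32 image with one
    positive label per nucleus. A blank image yields an empty result.
    Deterministic for fixed input.
    """
    img = np.asarray(nuclear_map, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear map must be a single-channel image")
    if config is None:
        config = NucleusDetectorConfig()

    smoothed = gaussian(img, sigma=config.smooth_sigma, preserve_range=True)
    if config.threshold is not None:
        thr = config.threshold
    else:
        if smoothed.max() <= smoothed.min():
            return np.empty((0, 2)), np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    binary = remove_small_objects(binary, max_size=config.min_area - 1)
    if not binary.any():
        return np.empty((0, 2)), np.zeros(img.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=config.min_distance, labels=binary,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.empty((0, 2)), np.zeros(img.shape, dtype=np.int32)
    seeds = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    labels = watershed(-distance, seeds, mask=binary).astype(np.int32)

    centroids = np.array(
        [[p.centroid[1], p.centroid[0]] for p in regionprops(labels)], dtype=float
    )
    return centroids.reshape(-1, 2), labels


def type_cells(
    centroids: np.ndarray,
    marker_masks: dict,
    marker_maps: dict,
    panel: PanelSpec,
    thresholds: MarkerThresholds,
) -> pd.DataFrame:
    """Intersect nucleus centroids with marker masks to type cells.

    A cell is positive for marker ``m`` iff its centroid pixel lies inside
    ``marker_masks[m]``; the intensity bin is read from ``marker_maps[m]``
    at the centroid pixel via the X / 2X / 3X boundaries. Multi-positive
    cells are allowed. Returns a cell table with ``cell_id, x, y, panel,
    markers, levels``.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(marker_masks) == 0:
        raise ValueError("no marker masks supplied")
    shape = next(iter(marker_masks.values())).shape
    records = []
    for cid, (x, y) in enumerate(centroids):
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"centroid ({x}, {y}) lies outside the image frame")
        markers, levels = set(), {}
        for m, mask in marker_masks.items():
            if mask[r, c]:
                markers.add(m)
                b = thresholds.bin(m, float(marker_maps[m][r, c]))
                # mask positivity implies value >= X up to interpolation;
                # clamp to the low bin if blur pulled it just under X
                levels[m] = b if b is not None else BIN_LOW
        records.append(
            {
                "cell_id": cid,
                "x": x,
                "y": y,
                "panel": panel.panel_id,
                "markers": frozenset(markers),
                "levels": levels,
            }
        )
    return pd.DataFrame(
        records, columns=["cell_id", "x", "y", "panel", "markers", "levels"]
    )


def compute_h_score(low_pct: float, median_pct: float, high_pct: float) -> float:
    """H-score = %low x 1 + %median x 2 + %high x 3, in [0, 300]."""
    for v in (low_pct, median_pct, high_pct):
        if not 0 <= v <= 100:
            raise ValueError("bin percentages must be in [0, 100]")
    if low_pct + median_pct + high_pct > 100 + 1e-9:
        raise ValueError("bin percentages sum to more than 100")
    return low_pct * 1 + median_pct * 2 + high_pct * 3


def assign_region(
    cells: pd.DataFrame, tn_mask: np.ndarray, ts_mask: np.ndarray
) -> pd.DataFrame:
    """Label each cell TN / TS / none by centroid membership in the masks."""
    tn = np.asarray(tn_mask, dtype=bool)
    ts = np.asarray(ts_mask, dtype=bool)
    if tn.shape != ts.shape:
        raise ValueError("TN and TS masks must share dimensions")
    if np.any(tn & ts):
        raise ValueError("TN and TS masks overlap")
    regions = []
    for x, y in zip(cells["x"], cells["y"]):
        r = int(np.clip(round(y), 0, tn.shape[0] - 1))
        c = int(np.clip(round(x), 0, tn.shape[1] - 1))
        regions.append("TN" if tn[r, c] else ("TS" if ts[r, c] else "none"))
    out = cells.copy()
    out["region"] = regions
    return out


def _marker_bin_percentages(
    region_cells: pd.DataFrame, marker: str
) -> tuple[float, float, float]:
    """% of all cells in the region falling in each intensity bin of a marker.

    Marker-negative cells contribute to the denominator only, so the
    H-score spans the full 0-300 range.
    """
    n = len(region_cells)
    if n == 0:
        return 0.0, 0.0, 0.0
    counts = {BIN_LOW: 0, BIN_MEDIAN: 0, BIN_HIGH: 0}
    for mk, lv in zip(region_cells["markers"], region_cells["levels"]):
        if marker in mk:
            counts[lv[marker]] += 1
    return tuple(100.0 * counts[b] / n for b in (BIN_LOW, BIN_MEDIAN, BIN_HIGH))


def summarize_quantities(
    cells: pd.DataFrame,
    region_areas_px: dict,
    microns_per_pixel: float = 0.5,
    phenotypes: dict | None = None,
) -> pd.DataFrame:
    """Per phenotype x region densities, percentages and H-scores.

    ``phenotypes`` maps a phenotype name to the marker set defining it
    (a cell belongs iff that set is a subset of its positive markers);
    the default is the single-marker phenotypes present in the table.
    Density is count / (area_px * mpp^2 * 1e-6) per mm^2; percentage is
    100 * phenotype count / all cells in the region. A zero-area region
    yields a missing density.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    if "region" not in cells.columns:
        raise ValueError("cells must carry a 'region' column (assign_region)")
    if phenotypes is None:
        all_markers = sorted({m for s in cells["markers"] for m in s})
        phenotypes = {m: {m} for m in all_markers}

    rows = []
    for region, area_px in region_areas_px.items():
        sub = cells[cells["region"] == region]
        total = len(sub)
        area_mm2 = float(area_px) * microns_per_pixel**2 * 1e-6
        for name, markers in phenotypes.items():
            members = sub[[set(markers) <= set(m) for m in sub["markers"]]]
            count = len(members)
            density = count / area_mm2 if area_mm2 > 0 else np.nan
            pct = 100.0 * count / total if total > 0 else np.nan
            if len(markers) == 1:
                h = compute_h_score(
                    *_marker_bin_percentages(sub, next(iter(markers)))
                )
            else:
                h = np.nan  # H-score defined per single marker stain
            rows.append(
                {
                    "phenotype": name,
                    "region": region,
                    "count": count,
                    "density_per_mm2": density,
                    "percentage": pct,
                    "h_score": h,
                }
            )
    return pd.DataFrame(rows)
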