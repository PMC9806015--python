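"""Spatial point-process simulators for cell placement.

Three placement regimes are supported inside an arbitrary binary region
mask: homogeneous Poisson (complete spatial randomness), Thomas-style
clustered placement (Poisson parents with Gaussian offspring — cells that
sit closer together and form more graph connections), and simple sequential
inhibition (a hard-core minimum spacing — cells that sit further apart and
form fewer connections).

Coordinates are 0-based real-valued pixel positions, origin top-left,
``x`` = column and ``y`` = row, with the pixel centre at the integer
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class ProcessSpec:
    """Configuration of one spatial point process.

    Parameters
    ----------
    kind : {"poisson", "clustered", "inhibited"}
    intensity : float
        Expected points per unit area (per px**2 of region foreground).
    cluster_parent_rate : float, optional
        Parents per px**2 for ``clustered``; defaults to
        ``intensity / cluster_mean_offspring``.
    cluster_sigma : float
        Gaussian offspring dispersion (px) for ``clustered``.
    cluster_mean_offspring : float
        Mean offspring per parent for ``clustered``.
    inhibition_radius : float
        Hard-core minimum spacing (px) for ``inhibited``.
    """

    kind: str = "poisson"
    intensity: float = 1e-3
    cluster_parent_rate: float | None = None
    cluster_sigma: float = 5.0
    cluster_mean_offspring: float = 10.0
    inhibition_radius: float = 0.0

    def __post_init__(self):
        if self.kind not in ("poisson", "clustered", "inhibited"):
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.kind == "clustered" and self.cluster_sigma <= 0:
            raise ValueError("cluster_sigma must be > 0 for clustered processes")
        if self.inhibition_radius < 0:
            raise ValueError("inhibition_radius must be >= 0")


def _foreground(region_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(region_mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("region mask has no foreground pixels")
    return rows, cols


def _uniform_in_mask(rows, cols, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform over the union of foreground pixels, as (x, y)."""
    if n == 0:
        return np.empty((0, 2))
    idx = rng.integers(0, rows.size, size=n)
    x = cols[idx] + rng.uniform(-0.5, 0.5, size=n)
    y = rows[idx] + rng.uniform(-0.5, 0.5, size=n)
    return np.column_stack([x, y])


def _inside(mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    r = np.clip(np.rint(pts[:, 1]).astype(int), 0, mask.shape[0] - 1)
    c = np.clip(np.rint(pts[:, 0]).astype(int), 0, mask.shape[1] - 1)
    ok = (
        (pts[:, 1] > -0.5)
        & (pts[:, 1] < mask.shape[0] - 0.5)
        & (pts[:, 0] > -0.5)
        & (pts[:, 0] < mask.shape[1] - 0.5)
    )
    return ok & mask[r, c]


def simulate_point_pattern(
    region_mask: np.ndarray, spec: ProcessSpec, seed: int
) -> np.ndarray:
    """Simulate one point pattern inside a binary region mask.

    Returns an ``(n, 2)`` array of ``(x, y)`` pixel positions, all inside
    the mask foreground. For ``kind="poisson"`` the count is
    Poisson(intensity × foreground area).
    """
    mask = np.asarray(region_mask).astype(bool)
    rows, cols = _foreground(mask)
    area = float(rows.size)  # one pixel = one unit of area
    rng = np.random.default_rng(seed)

    if spec.kind == "poisson":
        n = rng.poisson(spec.intensity * area)
        return _uniform_in_mask(rows, cols, n, rng)

    if spec.kind == "clustered":
        parent_rate = spec.cluster_parent_rate
        if parent_rate is None:
            parent_rate = spec.intensity / spec.cluster_mean_offspring
        n_parents = rng.poisson(parent_rate * area)
        parents = _uniform_in_mask(rows, cols, n_parents, rng)
        pts = []
        for px, py in parents:
            k = rng.poisson(spec.cluster_mean_offspring)
            if k == 0:
                continue
            off = rng.normal(0.0, spec.cluster_sigma, size=(k, 2))
            pts.append(np.column_stack([px + off[:, 0], py + off[:, 1]]))
        if not pts:
            return np.empty((0, 2))
        pts = np.vstack(pts)
        return pts[_inside(mask, pts)]

    # inhibited: simple sequential inhibition with a hard-core radius
    target = rng.poisson(spec.intensity * area)
    if target == 0:
        return np.empty((0, 2))
    accepted: list[np.ndarray] = []
    r2 = spec.inhibition_radius**2
    max_proposals = 100 * target
    proposals = _uniform_in_mask(rows, cols, max_proposals, rng)
    for p in proposals:
        if len(accepted) >= target:
            break
        if r2 > 0 and accepted:
            arr = np.asarray(accepted)
            if np.min(np.sum((arr - p) ** 2, axis=1)) < r2:
                continue
        accepted.append(p)
    return np.asarray(accepted) if accepted else np.empty((0, 2))


def mean_nearest_neighbour_distance(points: np.ndarray) -> float:
    """Mean distance to the nearest other point (brute force via KD-tree)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return float("nan")
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(np.mean(d[:, 1]))
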