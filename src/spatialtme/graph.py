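"""Delaunay cell-connection graphs and the 60-slot spatial feature vector.

Cells of one panel on one image are connected by the Delaunay
triangulation of their positions; the resulting edge table (endpoint ids,
Euclidean pixel length, endpoint marker sets) is traversed once, and each
edge increments every unordered marker-pair category formed from its two
endpoints' label sets. With two 5-marker panels there are exactly
C(5,2) + 5 = 15 categories per panel and 30 in total; each category
contributes a connection count and a mean connection length, i.e. 60 raw
features per image pair, plus their two normalized (relative) forms:

    pct_len[A|B] = mean_len[A|B] / (sum_i n_i * len_i / sum_i n_i)
    pct_num[A|B] = n[A|B] / sum_i n_i

with denominators taken over all categories of both panels' graphs within
the same image. Multi-positive cells enter as a single node carrying the
full marker set, so a CD8+CD133+ cell contributes to the CD8-CD8,
CD8-CD133 and CD133-CD133 categories of its edges without creating
zero-length duplicate-point artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .panels import PanelSpec, all_edge_categories, category_name, default_panel

logger = logging.getLogger(__name__)

_JITTER_SEED = 171717  # deterministic degeneracy-breaking jitter stream
_JITTER_SCALE = 1e-6  # px


@dataclass
class EdgeTable:
    """Delaunay edges of one panel's cells on one image.

    ``nodes`` has columns ``x, y, markers`` (markers a frozenset);
    ``edges`` has columns ``i, j, length`` with ``i < j`` node indices and
    Euclidean pixel lengths. No self-loops, no duplicate undirected edges.
    """

    panel_id: int
    nodes: pd.DataFrame
    edges: pd.DataFrame


def _collapse_duplicates(positions: np.ndarray, marker_sets: list) -> tuple:
    """Merge exactly co-located points into single multi-marker nodes."""
    seen: dict = {}
    pos_out: list = []
    mk_out: list = []
    for p, mk in zip(positions, marker_sets):
        key = (float(p[0]), float(p[1]))
        if key in seen:
            mk_out[seen[key]] = mk_out[seen[key]] | frozenset(mk)
        else:
            seen[key] = len(pos_out)
            pos_out.append(p)
            mk_out.append(frozenset(mk))
    return np.asarray(pos_out, dtype=float).reshape(-1, 2), mk_out


def _collinear_chain(points: np.ndarray) -> np.ndarray:
    """Edges of consecutive segments along the principal axis."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    order = np.argsort(centred @ vt[0])
    return np.column_stack([order[:-1], order[1:]])


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected edge index pairs of the Delaunay triangulation."""
    try:
        tri = Delaunay(points)
    except QhullError:
        rank = np.linalg.matrix_rank(points - points.mean(axis=0))
        if rank < 2:
            return _collinear_chain(points)
        rng = np.random.default_rng(_JITTER_SEED)
        jittered = points + rng.uniform(-_JITTER_SCALE, _JITTER_SCALE, points.shape)
        tri = Delaunay(jittered)
    simplices = tri.simplices
    pairs = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def build_delaunay(cells: pd.DataFrame, panel_id: int | None = None) -> EdgeTable:
    """Build the Delaunay edge table for one panel's cells on one image.

    ``cells`` needs ``x``, ``y`` and ``markers`` columns. Exactly
    co-located points are collapsed into one node whose marker set is the
    union. Degenerate inputs return defined results: n <= 1 gives no
    edges, n == 2 the single segment, collinear inputs the chain of
    consecutive segments.
    """
    if panel_id is None:
        panel_id = int(cells["panel"].iloc[0]) if len(cells) else 0
    positions = cells[["x", "y"]].to_numpy(dtype=float)
    marker_sets = list(cells["markers"])
    positions, marker_sets = _collapse_duplicates(positions, marker_sets)
    nodes = pd.DataFrame(
        {"x": positions[:, 0], "y": positions[:, 1], "markers": marker_sets}
    )

    n = len(positions)
    if n <= 1:
        pairs = np.empty((0, 2), dtype=int)
    elif n == 2:
        pairs = np.array([[0, 1]])
    else:
        pairs = _delaunay_edges(positions)

    if len(pairs):
        d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
        lengths = np.hypot(d[:, 0], d[:, 1])
    else:
        lengths = np.empty(0)
    edges = pd.DataFrame(
        {"i": pairs[:, 0].astype(int) if len(pairs) else np.empty(0, dtype=int),
         "j": pairs[:, 1].astype(int) if len(pairs) else np.empty(0, dtype=int),
         "length": lengths}
    )
    return EdgeTable(panel_id=panel_id, nodes=nodes, edges=edges)


@dataclass
class SpatialFeatureSet:
    """Per-image spatial features over the fixed 30-category schema.

    ``table`` is indexed by (panel_id, marker_a, marker_b) with columns
    ``n`` (connection count), ``total_length``, ``mean_length`` (NaN when
    n == 0) and, after :func:`normalize_features`, ``pct_num`` and
    ``pct_len``.
    """

    table: pd.DataFrame
    n_skipped_edges: int = 0

    def to_series(self) -> pd.Series:
        """Flatten to named feature columns (n[..], len[..], pct_*[..])."""
        out = {}
        for (pid, a, b), row in self.table.iterrows():
            out[category_name("n", a, b)] = row["n"]
            out[category_name("len", a, b)] = row["mean_length"]
            if "pct_num" in row.index:
                out[category_name("pct_num", a, b)] = row["pct_num"]
                out[category_name("pct_len", a, b)] = row["pct_len"]
        return pd.Series(out)


def tabulate_edges(
    edge_tables: dict[int, EdgeTable],
    panels: tuple[PanelSpec, ...] | None = None,
) -> SpatialFeatureSet:
    """Traverse the edge tables and fill the 30-category feature schema.

    Each edge contributes one count (and its length once) to every
    unordered marker pair formed from its endpoints' marker sets. Edges
    with a marker-less endpoint are skipped and counted in
    ``n_skipped_edges``.
    """
    if panels is None:
        panels = tuple(default_panel(pid) for pid in sorted(edge_tables))
    panel_by_id = {p.panel_id: p for p in panels}
    cats = all_edge_categories(panels)
    counts = {c: 0 for c in cats}
    totals = {c: 0.0 for c in cats}
    skipped = 0

    for pid, et in edge_tables.items():
        panel = panel_by_id[pid]
        markers = et.nodes["markers"].to_list()
        for i, j, length in et.edges.itertuples(index=False):
            ma, mb = markers[int(i)], markers[int(j)]
            if not ma or not mb:
                skipped += 1
                continue
            pairs = {panel.canonical_pair(a, b) for a in ma for b in mb}
            for a, b in pairs:
                key = (pid, a, b)
                counts[key] += 1
                totals[key] += float(length)
    if skipped:
        logger.info("tabulate_edges: skipped %d edges with unlabelled endpoints",
                    skipped)

    idx = pd.MultiIndex.from_tuples(cats, names=["panel", "marker_a", "marker_b"])
    n = np.array([counts[c] for c in cats], dtype=float)
    tot = np.array([totals[c] for c in cats])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, tot / np.where(n > 0, n, 1), np.nan)
    table = pd.DataFrame(
        {"n": n, "total_length": tot, "mean_length": mean}, index=idx
    )
    return SpatialFeatureSet(table=table, n_skipped_edges=skipped)


def normalize_features(fs: SpatialFeatureSet) -> SpatialFeatureSet:
    """Add the relative forms pct_len and pct_num to a feature set.

    The overall mean connection length (sum_i n_i * len_i / sum_i n_i) and
    the total connection count are computed within the image over all 30
    categories of both panels; a zero-edge image yields all-missing
    normalized values.
    """
    t = fs.table.copy()
    total_n = t["n"].sum()
    if total_n == 0:
        t["pct_num"] = np.nan
        t["pct_len"] = np.nan
        return SpatialFeatureSet(table=t, n_skipped_edges=fs.n_skipped_edges)
    overall_mean = t["total_length"].sum() / total_n
    t["pct_num"] = t["n"] / total_n
    t["pct_len"] = t["mean_length"] / overall_mean
    return SpatialFeatureSet(table=t, n_skipped_edges=fs.n_skipped_edges)


def image_features(
    cells_by_panel: dict[int, pd.DataFrame],
    panels: tuple[PanelSpec, ...] | None = None,
) -> pd.Series:
    """Cells of one image pair -> flattened 120-column feature row."""
    tables = {
        pid: build_delaunay(cells, panel_id=pid)
        for pid, cells in cells_by_panel.items()
    }
    return normalize_features(tabulate_edges(tables, panels)).to_series()


def aggregate_patient(
    slide_features: list[pd.Series] | pd.DataFrame, patient_id
) -> pd.Series:
    """Missing-aware arithmetic mean of per-slide feature rows.

    A category missing on one slide is ignored in that feature's mean; a
    category missing on all slides stays missing for the patient.
    """
    if isinstance(slide_features, list):
        if not slide_features:
            raise ValueError("at least one slide is required")
        slide_features = pd.DataFrame(slide_features)
    out = slide_features.mean(axis=0, skipna=True)
    out.name = patient_id
    return out
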