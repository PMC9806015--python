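"""Simulate one mIF field, detect its cells and summarise the infiltrate.

Places panel-1 cells with a hard-core spacing inside a 512 x 512 px field,
renders DAPI + marker stains, then runs the detection pipeline: nucleus
detection on the blue channel, marker masks at the X threshold, centroid
intersection for typing, region assignment and per-mm^2 summaries.
"""

import numpy as np

import spatialtme as st
from spatialtme.synthetic import (
    ProcessSpec,
    assign_markers,
    halves_region_masks,
    render_scene,
    simulate_point_pattern,
)

shape = (512, 512)
panel = st.default_panel(1)
mask = np.ones(shape, bool)
positions = simulate_point_pattern(
    mask, ProcessSpec("inhibited", 160 / mask.sum(), inhibition_radius=25), seed=1
)
cells = assign_markers(
    positions, panel, {"CD4": 0.3, "CD20": 0.3, "CD38": 0.2, "FOXP3": 0.1}, seed=2
)
tn, ts = halves_region_masks(shape)
scene = render_scene(cells, panel, image_shape=shape, seed=3, tn_mask=tn, ts_mask=ts)

centroids, _ = st.detect_nuclei(
    scene.nuclear_map, st.NucleusDetectorConfig(threshold=50.0, min_distance=6)
)
masks = {m: st.extract_marker_mask(scene.marker_maps[m], m, scene.thresholds)
         for m in panel.markers}
typed = st.type_cells(centroids, masks, scene.marker_maps, panel, scene.thresholds)
typed = st.assign_region(typed, tn, ts)
summary = st.summarize_quantities(
    typed, {"TN": tn.sum(), "TS": ts.sum()}, microns_per_pixel=0.5
)

print(f"simulated cells: {len(cells)}, detected cells: {len(typed)}")
print(summary[summary["count"] > 0].round(1).to_string(index=False))
print(
    "\nEach row gives one phenotype in one tissue compartment: its cell count,\n"
    "density per mm^2, share of all cells in that compartment, and the 0-300\n"
    "H-score weighting the +/++/+++ staining-intensity bins."
)
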