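"""Marker panels and the fixed edge-category schema.

Two five-marker panels are stained on serial sections of the same block:
panel 1 carries CD38, CD20, CD4, FOXP3 and CD66b; panel 2 carries PD-L1,
CD163, CD8, CD68 and CD133, each on top of a DAPI nuclear counterstain.
After spectral separation each marker lives in either the red or the green
channel of the RGB scan.

Spatial edge categories are unordered marker pairs *within* a panel,
self-pairs included: C(5,2) + 5 = 15 per panel, 30 in total. Each category
yields a connection count and a mean connection length, giving the fixed
60-slot spatial feature vector (120 columns once the two normalized forms
are added).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

PANEL1_MARKERS: tuple[str, ...] = ("CD38", "CD20", "CD4", "FOXP3", "CD66b")
PANEL2_MARKERS: tuple[str, ...] = ("PD-L1", "CD163", "CD8", "CD68", "CD133")

#: channel each marker is read from after separating the R and G channels
GREEN_MARKERS = frozenset({"CD4", "CD20", "CD38", "CD66b", "CD133", "CD163"})
RED_MARKERS = frozenset({"CD8", "CD68", "PD-L1", "FOXP3"})


@dataclass(frozen=True)
class PanelSpec:
    """One five-marker staining panel.

    Parameters
    ----------
    panel_id : int
        1 or 2.
    markers : tuple of str
        Exactly five marker names, in canonical order.
    channel_of_marker : dict
        Maps each marker to ``"R"`` or ``"G"``.
    """

    panel_id: int
    markers: tuple[str, ...]
    channel_of_marker: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.markers) != 5:
            raise ValueError(f"a panel has exactly 5 markers, got {len(self.markers)}")
        if len(set(self.markers)) != 5:
            raise ValueError("panel markers must be distinct")
        if not self.channel_of_marker:
            object.__setattr__(
                self,
                "channel_of_marker",
                {m: ("G" if m in GREEN_MARKERS else "R") for m in self.markers},
            )
        missing = set(self.markers) - set(self.channel_of_marker)
        if missing:
            raise ValueError(f"no channel assigned for markers {sorted(missing)}")
        bad = {c for c in self.channel_of_marker.values()} - {"R", "G"}
        if bad:
            raise ValueError(f"marker channels must be 'R' or 'G', got {bad}")

    def categories(self) -> list[tuple[str, str]]:
        """The 15 unordered marker pairs of this panel (self-pairs included)."""
        return list(combinations_with_replacement(self.markers, 2))

    def canonical_pair(self, a: str, b: str) -> tuple[str, str]:
        """Order a marker pair by panel marker order."""
        ia, ib = self.markers.index(a), self.markers.index(b)
        return (a, b) if ia <= ib else (b, a)


def default_panel(panel_id: int) -> PanelSpec:
    if panel_id == 1:
        return PanelSpec(1, PANEL1_MARKERS)
    if panel_id == 2:
        return PanelSpec(2, PANEL2_MARKERS)
    raise ValueError(f"panel_id must be 1 or 2, got {panel_id}")


def default_panels() -> tuple[PanelSpec, PanelSpec]:
    return default_panel(1), default_panel(2)


def all_edge_categories(
    panels: tuple[PanelSpec, ...] | None = None,
) -> list[tuple[int, str, str]]:
    """The fixed 30-slot category schema: (panel_id, marker_a, marker_b)."""
    if panels is None:
        panels = default_panels()
    out: list[tuple[int, str, str]] = []
    for p in panels:
        out.extend((p.panel_id, a, b) for a, b in p.categories())
    return out


def category_name(kind: str, a: str, b: str) -> str:
    """Flat column name for one category feature, e.g. ``n[CD4|CD20]``.

    ``|`` separates the markers because marker names may contain ``-``.
    """
    return f"{kind}[{a}|{b}]"
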