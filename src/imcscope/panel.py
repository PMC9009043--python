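"""Marker panel: the ordered mapping from image channels to markers.

A panel row ties a channel index to a marker name and a role. Roles drive
the analysis: ``immune`` markers define immune identity, the single
``nuclear`` channel (iridium DNA intercalator) drives segmentation, and
``structural`` channels (collagen) are kept for context but excluded from
immune annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

VALID_ROLES = ("immune", "structural", "nuclear")

#: The 10-channel default panel: 8 immune markers, collagen-1, iridium DNA.
DEFAULT_PANEL_ROWS = [
    (0, "CD20", "immune", "Dy161"),
    (1, "CD68", "immune", "Tb159"),
    (2, "CD66a", "immune", "Er167"),
    (3, "CD45", "immune", "Sm152"),
    (4, "CD45RA", "immune", "Gd155"),
    (5, "CD3", "immune", "Er170"),
    (6, "CD8", "immune", "Dy162"),
    (7, "HLA-DR", "immune", "Nd143"),
    (8, "Collagen1", "structural", "Tm169"),
    (9, "DNA-Ir", "nuclear", "Ir191"),
]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered channel → marker mapping with per-marker roles.

    Invariants (checked on construction): contiguous 0-based channel
    indices, unique marker names, exactly one nuclear channel.
    """

    markers: tuple[str, ...]
    roles: tuple[str, ...]
    metal_tags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.roles):
            raise PanelError("markers and roles must have equal length")
        if len(set(self.markers)) != len(self.markers):
            raise PanelError("marker names must be unique")
        for r in self.roles:
            if r not in VALID_ROLES:
                raise PanelError(f"invalid role {r!r}; expected one of {VALID_ROLES}")
        if sum(r == "nuclear" for r in self.roles) != 1:
            raise PanelError("panel must contain exactly one nuclear channel")
        if self.metal_tags and len(self.metal_tags) != len(self.markers):
            raise PanelError("metal_tags length must match markers")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def immune_markers(self) -> tuple[str, ...]:
        return tuple(m for m, r in zip(self.markers, self.roles) if r == "immune")

    @property
    def nuclear_marker(self) -> str:
        return next(m for m, r in zip(self.markers, self.roles) if r == "nuclear")

    @property
    def structural_markers(self) -> tuple[str, ...]:
        return tuple(m for m, r in zip(self.markers, self.roles) if r == "structural")

    def index_of(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise PanelError(f"marker {marker!r} not in panel") from None

    def to_frame(self) -> pd.DataFrame:
        tags = self.metal_tags or ("",) * len(self)
        return pd.DataFrame(
            {
                "channel_index": range(len(self)),
                "marker": self.markers,
                "role": self.roles,
                "metal_tag": tags,
            }
        )


def default_panel() -> MarkerPanel:
    """The bundled 10-channel liver-allograft panel."""
    _, markers, roles, tags = zip(*DEFAULT_PANEL_ROWS)
    return MarkerPanel(markers=markers, roles=roles, metal_tags=tags)


def read_panel(path: str | Path) -> MarkerPanel:
    """Read a panel CSV (columns: channel_index, marker, role[, metal_tag])."""
    df = pd.read_csv(path)
    required = {"channel_index", "marker", "role"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    df = df.sort_values("channel_index")
    if list(df["channel_index"]) != list(range(len(df))):
        raise PanelError("channel indices must be contiguous from 0")
    tags = (
        tuple(str(t) for t in df["metal_tag"].fillna(""))
        if "metal_tag" in df.columns
        else ()
    )
    return MarkerPanel(
        markers=tuple(df["marker"]), roles=tuple(df["role"]), metal_tags=tags
    )


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)
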