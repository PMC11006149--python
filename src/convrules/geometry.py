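"""Axis-aligned pixel boxes shared by the phantom generator and concept assignment.

Boxes use 0-based, half-open pixel coordinates: a box ``(x0, y0, x1, y1)``
covers columns ``x0..x1-1`` and rows ``y0..y1-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["RegionBox", "iou", "read_boxes_csv", "write_boxes_csv"]


@dataclass(frozen=True)
class RegionBox:
    """A named rectangular region in image coordinates (half-open)."""

    name: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"degenerate box {self.name!r}: ({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def overlaps(self, other: "RegionBox") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    def within(self, image_size: int) -> bool:
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= image_size and self.y1 <= image_size


def iou(a: RegionBox, b: RegionBox) -> float:
    """Intersection-over-union of two boxes under half-open semantics.

    Returns 1.0 iff the boxes cover identical pixels and 0.0 iff disjoint.
    """
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def write_boxes_csv(path, boxes_per_image) -> None:
    """Write per-image region boxes as CSV (image_id, region, x0, y0, x1, y1)."""
    rows = []
    for image_id, boxes in enumerate(boxes_per_image):
        for box in boxes.values():
            rows.append((image_id, box.name, box.x0, box.y0, box.x1, box.y1))
    pd.DataFrame(rows, columns=["image_id", "region", "x0", "y0", "x1", "y1"]).to_csv(
        path, index=False
    )


def read_boxes_csv(path) -> list[dict[str, RegionBox]]:
    """Read the box CSV dialect back into a per-image list of name -> RegionBox."""
    df = pd.read_csv(path)
    out: list[dict[str, RegionBox]] = []
    for image_id, grp in df.groupby("image_id", sort=True):
        out.append(
            {
                r.region: RegionBox(r.region, int(r.x0), int(r.y0), int(r.x1), int(r.y1))
                for r in grp.itertuples()
            }
        )
    return out
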