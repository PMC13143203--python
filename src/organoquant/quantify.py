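"""Quantities derived from masks, projections, ROIs, and manual tallies.

The central readout is the EdU+/DAPI+ voxel ratio: because tightly clustered
nuclei cannot all be separated into instances, proliferation is quantified as
the total segmented EdU volume divided by the total segmented DAPI volume per
organoid. The remaining operations cover the morphometry and tally summaries
used alongside it: maximum z-projections, polygon (taste bud profile) areas
in physical units, marker-count categorization, and mouse-level averaging
with the mouse as the experimental unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

if TYPE_CHECKING:  # pragma: no cover
    from .io import PolygonROI, VolumeStack

__all__ = [
    "QuantRecord",
    "edu_dapi_ratio",
    "max_projection",
    "polygon_area",
    "categorize_marker_counts",
    "per_mouse_average",
]


@dataclass(frozen=True)
class QuantRecord:
    """Per-organoid quantification output.

    One stack is one organoid: the ratio is the count of EdU-positive voxels
    over the count of DAPI-positive voxels in that organoid's masks.
    """

    organoid_id: str
    edu_positive_voxels: int
    dapi_positive_voxels: int
    edu_dapi_ratio: float
    params: dict = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if self.edu_positive_voxels < 0 or self.dapi_positive_voxels <= 0:
            raise ValueError(
                "voxel counts must be >= 0 with dapi_positive_voxels > 0"
            )
        expected = self.edu_positive_voxels / self.dapi_positive_voxels
        if not np.isclose(self.edu_dapi_ratio, expected, rtol=0, atol=1e-12):
            raise ValueError("edu_dapi_ratio must equal edu/dapi voxel counts")

    @classmethod
    def from_masks(
        cls,
        organoid_id: str,
        edu_mask: np.ndarray,
        dapi_mask: np.ndarray,
        params: Mapping | None = None,
        source: str = "",
    ) -> "QuantRecord":
        """Build a record directly from the two binary masks."""
        ratio = edu_dapi_ratio(edu_mask, dapi_mask)
        return cls(
            organoid_id=organoid_id,
            edu_positive_voxels=int(np.asarray(edu_mask).sum()),
            dapi_positive_voxels=int(np.asarray(dapi_mask).sum()),
            edu_dapi_ratio=ratio,
            params=dict(params or {}),
            source=source,
        )

    def to_row(self) -> dict:
        return {
            "organoid_id": self.organoid_id,
            "edu_positive_voxels": self.edu_positive_voxels,
            "dapi_positive_voxels": self.dapi_positive_voxels,
            "edu_dapi_ratio": repr(self.edu_dapi_ratio),
            "params": json.dumps(self.params, sort_keys=True),
            "source": self.source,
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "QuantRecord":
        return cls(
            organoid_id=str(row["organoid_id"]),
            edu_positive_voxels=int(row["edu_positive_voxels"]),
            dapi_positive_voxels=int(row["dapi_positive_voxels"]),
            edu_dapi_ratio=float(row["edu_dapi_ratio"]),
            params=json.loads(row["params"]) if pd.notna(row.get("params")) else {},
            source="" if pd.isna(row.get("source")) else str(row["source"]),
        )


def edu_dapi_ratio(edu_mask: np.ndarray, dapi_mask: np.ndarray) -> float:
    """Total EdU-positive voxels divided by total DAPI-positive voxels.

    No containment of EdU+ voxels within DAPI+ voxels is required; the two
    masks are independent channel segmentations. The DAPI mask must contain
    at least one positive voxel for the ratio to be defined.
    """
    edu = np.asarray(edu_mask)
    dapi = np.asarray(dapi_mask)
    if edu.dtype != bool or dapi.dtype != bool:
        raise ValueError("masks must be boolean")
    if edu.shape != dapi.shape:
        raise ValueError(f"shape mismatch: {edu.shape} vs {dapi.shape}")
    dapi_count = int(dapi.sum())
    if dapi_count == 0:
        raise ValueError("DAPI mask is empty; ratio undefined")
    return int(edu.sum()) / dapi_count


def max_projection(stack: "VolumeStack", channel: str) -> np.ndarray:
    """Maximum z-projection of one channel: per-pixel max over z."""
    return stack.get_channel(channel).max(axis=0)


def polygon_area(roi: "PolygonROI") -> float:
    """Area of a polygon outline in µm².

    Shoelace area of the vertex polygon in pixel² divided by the squared
    pixels-per-µm scale. Invariant to vertex-order reversal and cyclic
    rotation of the vertex list.
    """
    area_px2 = _ShapelyPolygon(roi.vertices).area
    return area_px2 / roi.scale_px_per_um**2


def categorize_marker_counts(
    per_organoid_counts: Sequence[int],
) -> dict[str, float]:
    """Fractions of organoids containing 0, 1-9, or >=10 marker-positive cells.

    Returns a dict over the three bins, with fractions that sum to 1 exactly
    (the last fraction is computed as the complement of the other two).
    """
    counts = list(per_organoid_counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0:
        raise ValueError("counts must be non-negative integers")
    total = len(counts)
    f0 = int((arr == 0).sum()) / total
    f1 = int(((arr >= 1) & (arr <= 9)).sum()) / total
    return {"0": f0, "1-9": f1, ">=10": 1.0 - f0 - f1}


def per_mouse_average(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mouse-level means and per-condition mean ± s.e.m. of those means.

    The mouse is the experimental unit: each mouse's units (taste bud
    profiles or organoids) are averaged first, then conditions are summarized
    as the mean of mouse means with the s.e.m. computed over mice (sample
    standard deviation, n-1 denominator, over sqrt of the number of mice).
    A single-mouse condition reports its mean with s.e.m. NaN.

    Parameters
    ----------
    table : DataFrame
        Columns ``mouse_id``, ``condition``, ``unit_id``, ``count`` and
        optionally ``marker``; one row per counting unit.

    Returns
    -------
    (mouse_means, condition_summary) : DataFrames
        ``mouse_means`` has one row per mouse (and marker, if present);
        ``condition_summary`` has columns ``mean``, ``sem``, ``n_mice``.
    """
    required = {"mouse_id", "condition", "unit_id", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("table is empty")
    if (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    keys = ["condition", "mouse_id"] + (["marker"] if "marker" in table else [])
    mouse_means = (
        table.groupby(keys, sort=False)["count"].mean().reset_index(name="mean")
    )
    group = [k for k in keys if k != "mouse_id"]
    summary = (
        mouse_means.groupby(group, sort=False)["mean"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n_mice="size")
        .reset_index()
    )
    return mouse_means, summary
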