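"""Reading and writing the pipeline's inputs and outputs.

Confocal z-stacks come in as plain multi-page TIFF or OME-TIFF; the axis
order is inferred from TIFF metadata when present, with a ``(z, c, y, x)``
fallback and an explicit override. Intensities are kept in their native
integer range on load — no implicit 8-bit conversion; rescaling happens only
at the normalization stage of the pipeline. Boolean masks round-trip through
uint8 TIFF, quantification reports through CSV, polygon ROIs through JSON
vertex lists, and pipeline configuration through YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon

from .segmentation import ChannelParams

__all__ = [
    "VolumeStack",
    "PolygonROI",
    "PipelineConfig",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeStack:
    """A multichannel 3D intensity volume.

    ``data`` is indexed ``(channel, z, y, x)``; intensities are finite and
    non-negative; every channel shares the same spatial dimensions.
    ``voxel_size_um`` is optional ``(z, y, x)`` metadata in micrometres.
    """

    data: np.ndarray
    channel_names: list[str]
    voxel_size_um: tuple[float, float, float] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4D (channel, z, y, x), got ndim={self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape[1:]):
            raise ValueError(f"spatial dimensions must be >= 1, got {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        names = list(self.channel_names)
        if len(names) != self.data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")
        self.channel_names = names

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial (z, y, x) shape."""
        return self.data.shape[1:]

    def get_channel(self, name: str) -> np.ndarray:
        """Return one channel as a 3D (z, y, x) array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


@dataclass(frozen=True)
class PolygonROI:
    """A freehand polygon outline in pixel coordinates with a spatial scale.

    ``vertices`` are ordered ``(x, y)`` pixel coordinates of a simple
    (non-self-intersecting) polygon; ``scale_px_per_um`` converts pixel to
    physical units.
    """

    vertices: tuple[tuple[float, float], ...]
    scale_px_per_um: float
    label: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(verts)}")
        if self.scale_px_per_um <= 0:
            raise ValueError(
                f"scale_px_per_um must be positive, got {self.scale_px_per_um}"
            )
        poly = _ShapelyPolygon(verts)
        if not poly.is_simple or poly.area == 0:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        object.__setattr__(self, "vertices", verts)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "scale_px_per_um": self.scale_px_per_um,
            "vertices": [list(v) for v in self.vertices],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PolygonROI":
        payload = json.loads(Path(path).read_text())
        return cls(
            vertices=tuple(tuple(v) for v in payload["vertices"]),
            scale_px_per_um=payload["scale_px_per_um"],
            label=payload.get("label", ""),
        )


@dataclass
class PipelineConfig:
    """Full parameterization of a quantification run.

    ``channels`` maps channel name to its index in the file and its
    :class:`~organoquant.segmentation.ChannelParams`; ``threshold_source``
    selects the volume the Otsu histogram is computed on.
    """

    channels: dict[str, ChannelParams] = field(default_factory=dict)
    channel_map: dict[str, int] = field(default_factory=dict)
    threshold_source: str = "reconstructed"
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.channel_map:
            if name not in self.channels:
                raise ValueError(f"channel_map names unknown channel {name!r}")
        if self.threshold_source not in ("reconstructed", "filtered"):
            raise ValueError(
                f"invalid threshold_source {self.threshold_source!r}"
            )

    @classmethod
    def default_edu(cls) -> "PipelineConfig":
        """The standard two-channel DAPI/EdU configuration."""
        return cls(
            channels={
                "DAPI": ChannelParams.nuclear(),
                "EdU": ChannelParams.proliferation(),
            },
            channel_map={"DAPI": 0, "EdU": 1},
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "channels": {
                name: {"index": self.channel_map.get(name), **params.to_dict()}
                for name, params in self.channels.items()
            },
            "threshold_source": self.threshold_source,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        channels: dict[str, ChannelParams] = {}
        channel_map: dict[str, int] = {}
        for name, entry in payload.get("channels", {}).items():
            entry = dict(entry)
            idx = entry.pop("index", None)
            if idx is not None:
                channel_map[name] = int(idx)
            channels[name] = ChannelParams(**entry)
        return cls(
            channels=channels,
            channel_map=channel_map,
            threshold_source=payload.get("threshold_source", "reconstructed"),
            output_dir=payload.get("output_dir", "."),
            seed=int(payload.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile array with labelled axes to (C, Z, Y, X)."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if sorted(axes) != sorted(set(axes)) or data.ndim != len(axes):
        raise ValueError(f"cannot interpret TIFF axes {axes!r} for shape {data.shape}")
    for ax in "CZ":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    unknown = set(axes) - set("CZYX")
    if unknown:
        raise ValueError(f"unsupported TIFF axes {sorted(unknown)} in {axes!r}")
    return np.transpose(data, [axes.index(a) for a in "CZYX"])


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int],
    axes: str | None = None,
) -> VolumeStack:
    """Read a multichannel z-stack from a TIFF / OME-TIFF file.

    Parameters
    ----------
    path : path
        TIFF file to read.
    channel_map : mapping of name -> index
        Names and file channel indices of the channels to load, e.g.
        ``{"DAPI": 0, "EdU": 1}``. The resulting stack orders channels by
        their index in this mapping's iteration order.
    axes : str, optional
        Explicit axis order override (e.g. ``"ZCYX"``) for files whose
        metadata is missing or wrong. When omitted, the order is inferred
        from TIFF metadata, falling back to ``(z, c, y, x)`` for unlabelled
        multi-dimensional data.

    Integer data is returned dtype-faithful, without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if not channel_map:
        raise ValueError("channel_map must not be empty")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            inferred = series.axes
    except (tifffile.TiffFileError, IndexError) as exc:
        raise ValueError(f"{path} is not a readable TIFF image: {exc}") from exc

    if axes is None:
        axes = inferred
        if not axes or len(axes) != data.ndim or not set(axes.upper()) <= set(
            "CZYXSQI"
        ):
            # unlabelled payload: assume (z, c, y, x) for 4D, (z, y, x) for 3D
            axes = {2: "YX", 3: "ZYX", 4: "ZCYX"}.get(data.ndim)
            if axes is None:
                raise ValueError(
                    f"cannot infer axis order for {data.ndim}D data in {path}"
                )
    full = _axes_to_czyx(data, axes)

    n_chan = full.shape[0]
    for name, idx in channel_map.items():
        if not 0 <= idx < n_chan:
            raise IndexError(
                f"channel {name!r} maps to index {idx} but file has {n_chan}"
                f" channel(s)"
            )
    names = list(channel_map)
    stacked = np.stack([full[channel_map[n]] for n in names])
    return VolumeStack(data=stacked, channel_names=names, source=str(path))


def write_stack(path: str | Path, stack: VolumeStack, ome: bool = True) -> None:
    """Write a VolumeStack as (OME-)TIFF with CZYX axis order."""
    tifffile.imwrite(
        Path(path),
        stack.data,
        ome=ome,
        photometric="minisblack",
        metadata={"axes": "CZYX"} if ome else None,
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a 3D boolean mask as a uint8 (0/1) TIFF; lossless round trip."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError(f"mask must be boolean, got dtype {mask.dtype}")
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got ndim={mask.ndim}")
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back as boolean."""
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    return data.astype(bool)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(path: str | Path, records: Sequence) -> None:
    """Write per-organoid quantification records to CSV.

    One row per organoid, header row included, numeric fields at full
    precision (round-trip exact through ``repr``).
    """
    from .quantify import QuantRecord  # local import avoids a cycle

    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for rec in records:
        if not isinstance(rec, QuantRecord):
            raise TypeError(f"expected QuantRecord, got {type(rec).__name__}")
        rows.append(rec.to_row())
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format=None)


def read_report(path: str | Path) -> list:
    """Read a CSV report written by :func:`write_report` back into records."""
    from .quantify import QuantRecord

    df = pd.read_csv(Path(path))
    return [QuantRecord.from_row(row) for _, row in df.iterrows()]
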