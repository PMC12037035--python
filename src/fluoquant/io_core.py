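"""Image, mask and table I/O plus the shared container types.

All pipelines consume :class:`ImageScene` (a multi-channel raster with
physical pixel size) and emit pandas DataFrames ("result tables") written
as plain CSV, and optionally :class:`LabelMask` objects written as 16-bit
label TIFFs.
"""

from __future__ import annotations

import hashlib
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("fluoquant")

__all__ = [
    "ImageScene",
    "LabelMask",
    "read_image",
    "write_scene",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "log_operation",
]


@dataclass
class ImageScene:
    """Multi-channel 2D (or 2D+time) intensity raster with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(C, Y, X)`` for still scenes or ``(C, T, Y, X)``
        for time series. Stored in its native dtype; analysis code converts
        to float64 on entry via :meth:`channel`.
    channel_names
        One label per channel, e.g. ``["CD20", "CD70"]``.
    pixel_size_um
        Micrometers per pixel (> 0). Pixel area is ``pixel_size_um ** 2``.
    frame_interval_s
        Seconds per frame for time series; ``None`` for still scenes.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"scene data must be (C, Y, X) or (C, T, Y, X), got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.isfinite(np.asarray(self.data, dtype=np.float64)).all():
            raise ValueError("scene intensities must be finite")
        if np.min(self.data) < 0:
            raise ValueError("scene intensities must be >= 0")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if self.is_timeseries and not (
            self.frame_interval_s is not None and self.frame_interval_s > 0
        ):
            raise ValueError("time series scenes require frame_interval_s > 0")

    @property
    def is_timeseries(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a float64 copy."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in scene (have {self.channel_names})"
            ) from None
        return np.asarray(self.data[idx], dtype=np.float64).copy()

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class LabelMask:
    """Integer label raster; 0 is background, k > 0 marks region k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF
# ---------------------------------------------------------------------------


def write_scene(scene: ImageScene, path: str | Path) -> Path:
    """Write a scene as OME-TIFF with pixel size / frame interval metadata."""
    path = Path(path)
    axes = "CTYX" if scene.is_timeseries else "CYX"
    metadata: dict = {
        "axes": axes,
        "PhysicalSizeX": scene.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": scene.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(scene.channel_names)},
    }
    if scene.frame_interval_s is not None:
        metadata["TimeIncrement"] = scene.frame_interval_s
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, scene.data, ome=True, metadata=metadata)
    return path


def _parse_ome_metadata(xml_text: str) -> dict:
    """Pull pixel size, frame interval and channel names out of OME XML."""
    out: dict = {}
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return out
    names = []
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "Pixels":
            if "PhysicalSizeX" in el.attrib:
                out["pixel_size_um"] = float(el.attrib["PhysicalSizeX"])
            if "TimeIncrement" in el.attrib:
                out["frame_interval_s"] = float(el.attrib["TimeIncrement"])
        elif tag == "Channel" and "Name" in el.attrib:
            names.append(el.attrib["Name"])
    if names:
        out["channel_names"] = names
    return out


def read_image(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageScene:
    """Read a TIFF / OME-TIFF into an :class:`ImageScene`.

    Metadata found in the file (OME pixel size, frame interval, channel
    names) wins over nothing, but explicit arguments win over file
    metadata only when the file carries none. Missing pixel size from both
    sources is an error — never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        meta = _parse_ome_metadata(tif.ome_metadata) if tif.ome_metadata else {}

    # Normalize to (C, Y, X) or (C, T, Y, X).
    axes = axes.replace("S", "C").replace("Q", "T")
    if arr.ndim == 2:
        arr = arr[np.newaxis]
        axes = "CYX"
    elif arr.ndim == 3 and axes.endswith("YX"):
        axes = axes[0] + "YX" if axes[0] in "CT" else "CYX"
        if axes[0] == "T":
            arr = arr[np.newaxis]
            axes = "CTYX"
    elif arr.ndim == 4:
        if axes[:2] == "TC":
            arr = np.moveaxis(arr, 1, 0)
        axes = "CTYX"
    if arr.ndim not in (3, 4):
        raise ValueError(f"cannot interpret TIFF axes {axes!r} with shape {arr.shape}")

    n_channels = arr.shape[0]
    file_names = meta.get("channel_names")
    names = file_names if file_names else channel_names
    if names is None:
        names = [f"ch{i}" for i in range(n_channels)]
    if len(names) != n_channels:
        raise ValueError(
            f"file has {n_channels} channels but {len(names)} names were given"
        )
    if channel_names is not None:
        missing = [c for c in channel_names if c not in names]
        if missing:
            raise ValueError(f"requested channels {missing} absent from {names}")

    px = meta.get("pixel_size_um", pixel_size_um)
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in file metadata and none given; pass pixel_size_um"
        )
    dt = meta.get("frame_interval_s", frame_interval_s)
    if arr.ndim == 4 and dt is None:
        raise ValueError(f"{path}: time series without frame interval")
    return ImageScene(arr, list(names), float(px), dt)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as a 16-bit TIFF."""
    path = Path(path)
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit mask")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    return path


def read_mask(path: str | Path) -> LabelMask:
    arr = tifffile.imread(path)
    return LabelMask(arr.astype(np.int32))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as CSV (header always present, full precision)."""
    path = Path(path)
    if len(set(table.columns)) != len(table.columns):
        raise ValueError("table column names must be unique")
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def log_operation(name: str, **params) -> None:
    """One structured log line per pipeline operation."""
    rendered = " ".join(f"{k}={_render_param(v)}" for k, v in sorted(params.items()))
    logger.info("op=%s %s", name, rendered)


def _render_param(value) -> str:
    if isinstance(value, np.ndarray):
        digest = hashlib.sha1(np.ascontiguousarray(value).tobytes()).hexdigest()[:10]
        return f"array{value.shape}#{digest}"
    return repr(value)
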