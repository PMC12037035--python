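"""Membrane cluster segmentation, PLA dot counting and bead calibration.

The cluster pipeline mirrors the classic Fiji recipe: find local maxima,
segment them by seeded watershed, threshold globally (Otsu with a
percentage offset), AND the two masks, fill holes, and measure connected
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .io_core import ImageScene, LabelMask, log_operation

logger = logging.getLogger("fluoquant")

__all__ = [
    "ClusterParams",
    "CalibrationCurve",
    "detect_clusters",
    "count_pla_spots",
    "fit_calibration",
    "calibrate_molecules",
    "molecules_per_cluster",
]

CLUSTER_COLUMNS = [
    "cluster_id",
    "area_um2",
    "mean_intensity",
    "integrated_intensity",
    "centroid_x_um",
    "centroid_y_um",
    "cell_id",
]


@dataclass
class ClusterParams:
    """Parameters of the maxima/watershed/threshold cluster pipeline.

    ``otsu_offset_percent`` lowers (positive values) or raises (negative)
    the Otsu threshold by that percentage of its height above the image
    minimum, so the threshold shifts exactly with any constant intensity
    offset. 20 is the common default for bright membrane clusters.
    """

    maxima_min_distance_px: int = 5
    threshold_mode: str = "otsu_offset"  # or "auto" (plain Otsu)
    otsu_offset_percent: float = 20.0
    smooth_sigma_px: float = 1.0
    min_cluster_px: int = 4

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu_offset", "auto"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not (-100.0 <= self.otsu_offset_percent <= 100.0):
            raise ValueError("otsu_offset_percent must be in [-100, 100]")


def _offset_otsu(img: np.ndarray, offset_percent: float) -> float:
    """Otsu threshold lowered by offset_percent of its height above min."""
    t = threshold_otsu(img)
    lo = float(img.min())
    return lo + (1.0 - offset_percent / 100.0) * (t - lo)


def _seeded_watershed(smoothed: np.ndarray, min_distance: int) -> np.ndarray:
    peaks = peak_local_max(
        smoothed, min_distance=min_distance, exclude_border=False
    )
    markers = np.zeros(smoothed.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    return watershed(-smoothed, markers, watershed_line=False)


def detect_clusters(
    scene: ImageScene,
    channel: str,
    params: ClusterParams | None = None,
) -> tuple[LabelMask, pd.DataFrame]:
    """Segment bright membrane clusters in one channel.

    Pipeline order is fixed: (1) Gaussian smoothing; (2) local maxima;
    (3) maxima-seeded watershed; (4) global Otsu threshold shifted by
    ``otsu_offset_percent``; (5) AND of watershed regions and threshold
    mask; (6) per-region binary hole filling; (7) 8-connected labeling and
    measurement. Returns the label mask plus one row per cluster.
    """
    params = params or ClusterParams()
    img = scene.channel(channel)
    if not np.isfinite(img).all():
        raise ValueError("channel contains non-finite pixels")
    empty = pd.DataFrame(columns=CLUSTER_COLUMNS)
    blank = LabelMask(np.zeros(img.shape, dtype=np.int32))
    if img.max() == img.min():
        return blank, empty

    smoothed = (
        ndimage.gaussian_filter(img, params.smooth_sigma_px)
        if params.smooth_sigma_px > 0
        else img
    )
    ws = _seeded_watershed(smoothed, params.maxima_min_distance_px)
    if params.threshold_mode == "otsu_offset":
        thr = _offset_otsu(smoothed, params.otsu_offset_percent)
    else:
        thr = float(threshold_otsu(smoothed))
    binary = smoothed >= thr

    # hole filling per watershed region keeps split lines between regions
    combined = np.zeros(img.shape, dtype=bool)
    for region_id in np.unique(ws):
        if region_id == 0:
            continue
        piece = (ws == region_id) & binary
        if piece.any():
            combined |= ndimage.binary_fill_holes(piece)

    # relabel: connected components within each watershed region
    labels = cc_label(combined, connectivity=2) * 0
    next_id = 0
    for region_id in np.unique(ws):
        piece = (ws == region_id) & combined
        if not piece.any():
            continue
        sub = cc_label(piece, connectivity=2)
        sub_ids = np.unique(sub)
        for sid in sub_ids[sub_ids > 0]:
            next_id += 1
            labels[sub == sid] = next_id

    rows = []
    out = np.zeros(img.shape, dtype=np.int32)
    keep_id = 0
    for prop in regionprops(labels, intensity_image=img):
        if prop.area < params.min_cluster_px:
            continue
        keep_id += 1
        out[labels == prop.label] = keep_id
        cy, cx = prop.centroid
        rows.append(
            {
                "cluster_id": keep_id,
                "area_um2": prop.area * scene.pixel_area_um2,
                "mean_intensity": prop.intensity_mean,
                "integrated_intensity": prop.intensity_mean * prop.area,
                "centroid_x_um": cx * scene.pixel_size_um,
                "centroid_y_um": cy * scene.pixel_size_um,
                "cell_id": 1,
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    log_operation("clusters.detect_clusters", channel=channel,
                  n_clusters=len(table), threshold=thr,
                  mode=params.threshold_mode,
                  offset=params.otsu_offset_percent)
    return LabelMask(out), table


# ---------------------------------------------------------------------------
# PLA
# ---------------------------------------------------------------------------


def _segment_cells(dapi: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """Threshold + distance-transform watershed of the DAPI channel."""
    if dapi.max() == dapi.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    smoothed = ndimage.gaussian_filter(dapi, smooth_sigma)
    binary = smoothed >= threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(binary)
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=7, labels=binary, exclude_border=False)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    return watershed(-dist, markers, mask=binary).astype(np.int32)


def count_pla_spots(
    scene: ImageScene,
    pla_channel: str = "PLA",
    dapi_channel: str = "DAPI",
    min_spot_area_px: int = 3,
    max_spot_area_px: int = 400,
    maxima_min_distance_px: int = 2,
    assign_max_dist_px: float = 10.0,
    smooth_sigma_px: float = 1.0,
) -> tuple[pd.DataFrame, LabelMask]:
    """Count PLA dots per cell.

    Cells come from DAPI (threshold + watershed); dots are thresholded,
    split by intensity-seeded watershed, size-filtered, then assigned to
    the containing cell or — within ``assign_max_dist_px`` — the nearest
    cell centroid. Unassignable dots count under ``cell_id`` 0.
    """
    pla = scene.channel(pla_channel)
    dapi = scene.channel(dapi_channel)
    cells = _segment_cells(dapi)
    cell_ids = [int(i) for i in np.unique(cells) if i != 0]
    if not cell_ids:
        logger.warning("count_pla_spots: no cells found in DAPI channel")
        return (
            pd.DataFrame(columns=["cell_id", "dots_per_cell"]),
            LabelMask(np.zeros(pla.shape, dtype=np.int32)),
        )

    counts = {cid: 0 for cid in cell_ids}
    counts[0] = 0
    spot_labels = np.zeros(pla.shape, dtype=np.int32)
    if pla.max() > pla.min():
        smoothed = (
            ndimage.gaussian_filter(pla, smooth_sigma_px)
            if smooth_sigma_px > 0
            else pla
        )
        binary = smoothed >= threshold_otsu(smoothed)
        peaks = peak_local_max(
            smoothed, min_distance=maxima_min_distance_px, labels=binary,
            exclude_border=False,
        )
        markers = np.zeros(pla.shape, dtype=np.int32)
        for i, (y, x) in enumerate(peaks, start=1):
            markers[y, x] = i
        spots = watershed(-smoothed, markers, mask=binary)

        centroids = {
            cid: ndimage.center_of_mass(cells == cid) for cid in cell_ids
        }
        kept = 0
        for prop in regionprops(spots):
            if not (min_spot_area_px <= prop.area <= max_spot_area_px):
                continue
            kept += 1
            spot_labels[spots == prop.label] = kept
            y, x = prop.centroid
            owner = int(cells[int(round(y)), int(round(x))])
            if owner == 0:
                dists = {
                    cid: np.hypot(y - cy, x - cx)
                    for cid, (cy, cx) in centroids.items()
                }
                nearest = min(dists, key=dists.get)
                owner = nearest if dists[nearest] <= assign_max_dist_px else 0
            counts[owner] += 1

    rows = [{"cell_id": cid, "dots_per_cell": counts[cid]} for cid in cell_ids]
    if counts[0]:
        rows.append({"cell_id": 0, "dots_per_cell": counts[0]})
    table = pd.DataFrame(rows, columns=["cell_id", "dots_per_cell"])
    log_operation("clusters.count_pla_spots", n_cells=len(cell_ids),
                  total_spots=int(table["dots_per_cell"].sum()))
    return table, LabelMask(spot_labels)


# ---------------------------------------------------------------------------
# bead calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """log10(MFI) = intercept + slope * log10(ABC) least-squares line."""

    slope: float
    intercept: float
    r_squared: float
    mfi_min: float
    mfi_max: float

    def abc_of_mfi(self, mfi: float) -> float:
        return float(10 ** ((np.log10(mfi) - self.intercept) / self.slope))

    def in_range(self, mfi: float) -> bool:
        return self.mfi_min <= mfi <= self.mfi_max


def fit_calibration(beads: pd.DataFrame) -> CalibrationCurve:
    """Fit the bead standard line on log-log axes.

    ``beads`` needs columns ``abc`` and ``mfi``; at least 3 distinct
    positive ABC values are required.
    """
    b = beads.dropna(subset=["abc"])
    abc = b["abc"].to_numpy(dtype=np.float64)
    mfi = b["mfi"].to_numpy(dtype=np.float64)
    if len(np.unique(abc[abc > 0])) < 3:
        raise ValueError("need at least 3 bead populations with distinct ABC > 0")
    if np.any(abc <= 0) or np.any(mfi <= 0):
        raise ValueError("bead ABC and MFI must be positive")
    x = np.log10(abc)
    y = np.log10(mfi)
    slope, intercept = np.polyfit(x, y, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        mfi_min=float(mfi.min()),
        mfi_max=float(mfi.max()),
    )


def calibrate_molecules(
    beads: pd.DataFrame, sample_mfis: list[float]
) -> pd.DataFrame:
    """Convert sample MFIs to molecule numbers via the bead standard line."""
    if any(m <= 0 for m in sample_mfis):
        raise ValueError("sample MFIs must be positive")
    curve = fit_calibration(beads)
    rows = [
        {
            "sample": i,
            "mfi": m,
            "molecules": curve.abc_of_mfi(m),
            "in_range": curve.in_range(m),
        }
        for i, m in enumerate(sample_mfis)
    ]
    log_operation("clusters.calibrate_molecules", n_beads=len(beads),
                  n_samples=len(sample_mfis), slope=curve.slope,
                  r_squared=curve.r_squared)
    return pd.DataFrame(rows, columns=["sample", "mfi", "molecules", "in_range"])


def molecules_per_cluster(
    clusters: pd.DataFrame, cell_total_molecules: float
) -> pd.DataFrame:
    """Apportion a cell's total molecule count across its clusters.

    Proportional to integrated intensity; outputs sum exactly to the
    input total.
    """
    if clusters.empty:
        return clusters.assign(molecules=pd.Series(dtype=float))
    weights = clusters["integrated_intensity"].to_numpy(dtype=np.float64)
    total = weights.sum()
    if total <= 0:
        raise ValueError("total integrated intensity must be positive")
    out = clusters.copy()
    out["molecules"] = weights / total * cell_total_molecules
    return out
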