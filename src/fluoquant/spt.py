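"""Single-particle tracking: linking, MSD, motion-state classification, speed.

Linking is greedy mutual-nearest-neighbor between consecutive frames with
bounded gap closing — a documented simplification of LAP-style trackers
that is adequate at low particle densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import log_operation

__all__ = [
    "Track",
    "TrajectorySet",
    "link_detections",
    "msd_curve",
    "fit_msd_alpha",
    "classify_motion",
    "mean_speed",
]

ALPHA_CONFINED_DEFAULT = 0.6
ALPHA_ACTIVE_DEFAULT = 1.4


@dataclass
class Track:
    """One linked trajectory: frame indices plus positions in micrometers."""

    frames: np.ndarray
    xy_um: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy_um = np.asarray(self.xy_um, dtype=np.float64)
        if self.xy_um.shape != (len(self.frames), 2):
            raise ValueError("xy_um must be (n, 2) matching frames")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames within a track must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrajectorySet:
    tracks: list[Track]
    dt_s: float
    labels: list[np.ndarray] = field(default_factory=list)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, track in enumerate(self.tracks):
            lab = self.labels[tid] if tid < len(self.labels) else None
            for i in range(len(track)):
                rows.append(
                    {
                        "track_id": tid,
                        "frame": int(track.frames[i]),
                        "x_um": track.xy_um[i, 0],
                        "y_um": track.xy_um[i, 1],
                        "label": lab[i] if lab is not None else "",
                    }
                )
        return pd.DataFrame(
            rows, columns=["track_id", "frame", "x_um", "y_um", "label"]
        )


def _mutual_nearest(
    a: np.ndarray, b: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Pairs (i, j) where a[i] and b[j] are mutually nearest within max_dist."""
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    nearest_b = d.argmin(axis=1)
    nearest_a = d.argmin(axis=0)
    pairs = []
    for i, j in enumerate(nearest_b):
        if nearest_a[j] == i and d[i, j] <= max_dist:
            pairs.append((i, int(j)))
    return pairs


def link_detections(
    detections: pd.DataFrame,
    dt_s: float,
    max_link_um: float,
    max_gap: int = 2,
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    ``detections`` needs columns ``frame, x_um, y_um`` sorted by frame.
    Tracks whose last detection is within ``max_gap`` missing frames stay
    eligible for linking; each detection joins at most one track.
    """
    if max_link_um <= 0:
        raise ValueError("max_link_um must be > 0")
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections need columns {sorted(required)}")
    if detections.duplicated(subset=["frame", "x_um", "y_um"]).any():
        raise ValueError("duplicate (frame, x, y) detections")
    if len(detections) and np.any(np.diff(detections["frame"].to_numpy()) < 0):
        raise ValueError("detections must be sorted by frame")

    # active track state: (frames list, xy list, last frame)
    active: list[dict] = []
    finished: list[dict] = []
    for frame, group in detections.groupby("frame", sort=True):
        frame = int(frame)
        pts = group[["x_um", "y_um"]].to_numpy(dtype=np.float64)
        # sort candidates deterministically regardless of row order
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[order]

        still_active = [t for t in active if frame - t["last"] <= max_gap + 1]
        finished.extend(t for t in active if frame - t["last"] > max_gap + 1)
        taken = np.zeros(len(pts), dtype=bool)
        # match closest frame-offsets first so gap closing never steals a
        # detection from a track seen in the immediately preceding frame
        for offset in range(1, max_gap + 2):
            cand = [t for t in still_active if frame - t["last"] == offset]
            if not cand:
                continue
            ends = np.array([t["xy"][-1] for t in cand])
            free_idx = np.nonzero(~taken)[0]
            if len(free_idx) == 0:
                break
            pairs = _mutual_nearest(ends, pts[free_idx], max_link_um * offset)
            for i, j in pairs:
                det = int(free_idx[j])
                cand[i]["frames"].append(frame)
                cand[i]["xy"].append(pts[det])
                cand[i]["last"] = frame
                taken[det] = True
        for det in np.nonzero(~taken)[0]:
            still_active.append(
                {"frames": [frame], "xy": [pts[det]], "last": frame}
            )
        active = still_active
    finished.extend(active)
    finished.sort(key=lambda t: (t["frames"][0], t["xy"][0][0], t["xy"][0][1]))
    tracks = [
        Track(np.array(t["frames"]), np.array(t["xy"])) for t in finished
    ]
    log_operation("spt.link_detections", n_detections=len(detections),
                  n_tracks=len(tracks), max_link_um=max_link_um, max_gap=max_gap)
    return TrajectorySet(tracks=tracks, dt_s=dt_s)


def detect_particles(
    movie: np.ndarray,
    pixel_size_um: float,
    min_distance_px: int = 3,
) -> pd.DataFrame:
    """Per-frame spot detections from a (T, Y, X) movie.

    Same maxima detector as the cluster pipeline: intensity peaks above
    Otsu, separated by ``min_distance_px``. The default spacing matches a
    ~0.35 µm² particle footprint at TIRF pixel sizes.
    """
    from skimage.filters import threshold_otsu

    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, Y, X)")
    rows = []
    for frame in range(movie.shape[0]):
        img = movie[frame]
        if img.max() == img.min():
            continue
        thr = threshold_otsu(img)
        peaks = _peak_coords(img, thr, min_distance_px)
        for y, x in peaks:
            rows.append(
                {
                    "frame": frame,
                    "x_um": x * pixel_size_um,
                    "y_um": y * pixel_size_um,
                }
            )
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


def _peak_coords(img: np.ndarray, thr: float, min_distance: int) -> np.ndarray:
    from skimage.feature import peak_local_max

    return peak_local_max(
        img, min_distance=min_distance, threshold_abs=thr, exclude_border=False
    )


def msd_curve(
    track: Track, dt_s: float, max_lag_frames: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD: ``MSD(d) = mean_t |r(t + d) - r(t)|^2``.

    Assumes a gap-free track (consecutive frames); lags are in frames,
    returned as seconds.
    """
    n = len(track)
    if max_lag_frames is None:
        max_lag_frames = n - 1
    max_lag_frames = min(max_lag_frames, n - 1)
    lags = np.arange(1, max_lag_frames + 1)
    msd = np.empty(len(lags))
    xy = track.xy_um
    for k, lag in enumerate(lags):
        disp = xy[lag:] - xy[:-lag]
        msd[k] = np.mean(np.sum(disp**2, axis=1))
    return lags * dt_s, msd


def fit_msd_alpha(
    lag_s: np.ndarray, msd_um2: np.ndarray, min_lag_index: int = 0
) -> float:
    """Anomalous-diffusion exponent from a log-log MSD fit."""
    lag = np.asarray(lag_s, dtype=np.float64)[min_lag_index:]
    msd = np.asarray(msd_um2, dtype=np.float64)[min_lag_index:]
    keep = msd > 0
    if keep.sum() < 2:
        return 0.0  # flat / zero MSD: no growth
    coef = np.polyfit(np.log(lag[keep]), np.log(msd[keep]), 1)
    return float(coef[0])


def classify_motion(
    track: Track,
    dt_s: float,
    window: int = 16,
    alpha_confined: float = ALPHA_CONFINED_DEFAULT,
    alpha_active: float = ALPHA_ACTIVE_DEFAULT,
) -> np.ndarray:
    """Per-frame motion labels from sliding-window MSD exponents.

    Within each centered window the log-log MSD slope alpha over lags
    ``1 .. max(2, window // 4)`` labels the frame: confined if
    ``alpha < alpha_confined``, active if ``alpha > alpha_active``, else
    free. Tracks shorter than the window get a single whole-track label.
    """
    if window < 8:
        raise ValueError("window must be >= 8 frames")
    n = len(track)
    max_lag = max(2, window // 4)

    def _label(sub: Track) -> str:
        lag_s, msd = msd_curve(sub, dt_s, max_lag)
        alpha = fit_msd_alpha(lag_s, msd)
        if alpha < alpha_confined:
            return "confined"
        if alpha > alpha_active:
            return "active"
        return "free"

    if n < window:
        return np.array([_label(track)] * n)

    labels = np.empty(n, dtype=object)
    half = window // 2
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        sub = Track(track.frames[lo : lo + window], track.xy_um[lo : lo + window])
        labels[i] = _label(sub)
    return labels.astype(str)


def mean_speed(track: Track, dt_s: float) -> float:
    """Mean frame-to-frame speed in micrometers per second."""
    if len(track) < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(track.xy_um, axis=0), axis=1)
    return float(np.mean(steps) / dt_s)


def summarize_tracks(
    ts: TrajectorySet,
    window: int = 16,
    min_track_len: int = 20,
    alpha_confined: float = ALPHA_CONFINED_DEFAULT,
    alpha_active: float = ALPHA_ACTIVE_DEFAULT,
) -> pd.DataFrame:
    """Per-track speed and motion-state fractions for analysis-length tracks."""
    rows = []
    ts.labels = []
    for tid, track in enumerate(ts.tracks):
        if len(track) < min_track_len:
            ts.labels.append(np.array(["short"] * len(track)))
            continue
        labels = classify_motion(
            track, ts.dt_s, window=window,
            alpha_confined=alpha_confined, alpha_active=alpha_active,
        )
        ts.labels.append(labels)
        rows.append(
            {
                "track_id": tid,
                "n_frames": len(track),
                "mean_speed_um_s": mean_speed(track, ts.dt_s),
                "frac_confined": float(np.mean(labels == "confined")),
                "frac_free": float(np.mean(labels == "free")),
                "frac_active": float(np.mean(labels == "active")),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "n_frames", "mean_speed_um_s",
            "frac_confined", "frac_free", "frac_active",
        ],
    )
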