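"""Synthetic fluorescence-microscopy scenes with exact ground truth.

Every generator returns a ``(scene_or_series, truth)`` pair; the truth
record stores the generating parameters and derived quantities that the
analysis pipelines are meant to recover. Geometry is deliberately simple
(cells are discs, membranes are 3-px annuli, the PSF is an isotropic
Gaussian) so that brute-force pixel-counting oracles are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .frap import FRAPSeries
from .io_core import ImageScene
from .spt import Track, TrajectorySet

__all__ = [
    "simulate_cluster_image",
    "simulate_coloc_pair",
    "simulate_frap_series",
    "simulate_trajectories",
    "simulate_pla_image",
    "simulate_synapse_scene",
    "simulate_stamp_scene",
    "simulate_calibration_beads",
]

DEFAULT_PIXEL_SIZE_UM = 0.05
DEFAULT_PSF_SIGMA_UM = 0.1  # Airyscan-regime resolution scale
MAX_PLACEMENT_TRIES = 10_000
MEMBRANE_WIDTH_PX = 3


class PlacementError(RuntimeError):
    """Raised when a requested spot packing cannot be satisfied."""


@dataclass
class GroundTruth:
    """Generating parameters plus derived quantities for one scene.

    ``params`` and ``derived`` hold JSON-serializable scalars/lists;
    ``arrays`` holds raster-valued truth (masks, state sequences) used by
    in-process oracles but excluded from the JSON side-file.
    """

    kind: str
    params: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"kind": self.kind, "params": self.params, "derived": self.derived}
        path.write_text(json.dumps(payload, indent=2, default=_jsonify))
        return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _annulus_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    width: float = MEMBRANE_WIDTH_PX,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (r2 <= radius**2) & (r2 > (radius - width) ** 2)


def _place_in_disc(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    region_radius: float,
    min_sep: float,
    avoid: list[tuple[float, float]] | None = None,
    avoid_sep: float | None = None,
) -> list[tuple[float, float]]:
    """Rejection-sample n points in a disc with pairwise minimum separation."""
    placed: list[tuple[float, float]] = []
    avoid = avoid or []
    avoid_sep = avoid_sep if avoid_sep is not None else min_sep
    for _ in range(n):
        for attempt in range(MAX_PLACEMENT_TRIES):
            r = region_radius * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            cand = (center[0] + r * np.sin(theta), center[1] + r * np.cos(theta))
            ok = all(
                (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep**2
                for p in placed
            ) and all(
                (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= avoid_sep**2
                for p in avoid
            )
            if ok:
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place point {len(placed) + 1}/{n} with min separation "
                f"{min_sep:.2f} px in {MAX_PLACEMENT_TRIES} attempts"
            )
    return placed


def _render_discs(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    radius_px: float,
    intensity: float,
    psf_sigma_px: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    for c in centers:
        img[_disc_mask(shape, c, radius_px)] = intensity
    if psf_sigma_px > 0:
        img = gaussian_filter(img, psf_sigma_px)
    return img


def _add_noise(
    img: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return np.clip(img, 0, None)


# ---------------------------------------------------------------------------
# cluster images
# ---------------------------------------------------------------------------


def simulate_cluster_image(
    n_clusters: int,
    mean_radius_um: float = 0.4,
    intensity: float = 1000.0,
    cell_mask_radius_um: float = 8.0,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    noise_sd: float = 0.0,
    min_separation_um: float | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    image_size_px: int | None = None,
    seed: int = 0,
) -> tuple[ImageScene, GroundTruth]:
    """Gaussian-PSF spot clusters on a dark background inside a cell disc.

    Ground truth records centers (µm) and true areas ``pi r**2``.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    rng = np.random.default_rng(seed)
    radius_px = mean_radius_um / pixel_size_um
    cell_radius_px = cell_mask_radius_um / pixel_size_um
    if min_separation_um is None:
        min_separation_um = 5.0 * mean_radius_um
    min_sep_px = min_separation_um / pixel_size_um
    if image_size_px is None:
        image_size_px = int(np.ceil(2 * cell_radius_px + 8 * radius_px))
    shape = (image_size_px, image_size_px)
    center = (image_size_px / 2.0, image_size_px / 2.0)

    placeable_radius = max(cell_radius_px - radius_px, 1.0)
    centers = _place_in_disc(rng, n_clusters, center, placeable_radius, min_sep_px)
    clean = _render_discs(shape, centers, radius_px, intensity, psf_sigma_um / pixel_size_um)
    img = _add_noise(clean, rng, noise_sd)

    scene = ImageScene(img[np.newaxis], ["CD20"], pixel_size_um)
    truth = GroundTruth(
        kind="cluster_image",
        params={
            "n_clusters": n_clusters,
            "mean_radius_um": mean_radius_um,
            "intensity": intensity,
            "cell_mask_radius_um": cell_mask_radius_um,
            "psf_sigma_um": psf_sigma_um,
            "noise_sd": noise_sd,
            "min_separation_um": min_separation_um,
            "pixel_size_um": pixel_size_um,
            "seed": seed,
        },
        derived={
            "centers_um": [
                [c[0] * pixel_size_um, c[1] * pixel_size_um] for c in centers
            ],
            "area_um2_each": float(np.pi * mean_radius_um**2),
            "total_area_um2": float(n_clusters * np.pi * mean_radius_um**2),
        },
        arrays={"clean": clean},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# colocalization pairs
# ---------------------------------------------------------------------------


def simulate_coloc_pair(
    overlap_fraction: float,
    n_spots: int = 12,
    spot_radius_um: float = 0.3,
    intensity: float = 500.0,
    noise_sd: float = 0.0,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    image_size_px: int = 200,
    seed: int = 0,
) -> tuple[ImageScene, GroundTruth]:
    """Two-channel spot pair with a controlled fraction of shared spots.

    Channel B reuses ``round(overlap_fraction * n_spots)`` of channel A's
    spot positions and places the remainder away from every A spot. Truth
    records the noiseless binary masks and their pixel overlap.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    radius_px = spot_radius_um / pixel_size_um
    shape = (image_size_px, image_size_px)
    center = (image_size_px / 2.0, image_size_px / 2.0)
    region_radius = image_size_px / 2.0 - 4 * radius_px
    min_sep = 4.0 * radius_px

    a_centers = _place_in_disc(rng, n_spots, center, region_radius, min_sep)
    n_shared = int(round(overlap_fraction * n_spots))
    b_centers = list(a_centers[:n_shared])
    b_only = _place_in_disc(
        rng, n_spots - n_shared, center, region_radius, min_sep,
        avoid=a_centers, avoid_sep=min_sep,
    )
    b_centers.extend(b_only)

    sigma_px = psf_sigma_um / pixel_size_um
    clean_a = _render_discs(shape, a_centers, radius_px, intensity, sigma_px)
    clean_b = _render_discs(shape, b_centers, radius_px, intensity, sigma_px)
    mask_a = np.zeros(shape, dtype=bool)
    for c in a_centers:
        mask_a |= _disc_mask(shape, c, radius_px)
    mask_b = np.zeros(shape, dtype=bool)
    for c in b_centers:
        mask_b |= _disc_mask(shape, c, radius_px)

    img_a = _add_noise(clean_a, rng, noise_sd)
    img_b = _add_noise(clean_b, rng, noise_sd)
    scene = ImageScene(np.stack([img_a, img_b]), ["CD20", "CD70"], pixel_size_um)

    inter = int(np.sum(mask_a & mask_b))
    union = int(np.sum(mask_a | mask_b))
    truth = GroundTruth(
        kind="coloc_pair",
        params={
            "overlap_fraction": overlap_fraction,
            "n_spots": n_spots,
            "noise_sd": noise_sd,
            "seed": seed,
            "pixel_size_um": pixel_size_um,
        },
        derived={
            "n_shared": n_shared,
            "overlap_pixels": inter,
            "pixels_a": int(mask_a.sum()),
            "pixels_b": int(mask_b.sum()),
            "pixel_overlap_fraction": inter / union if union else 0.0,
        },
        arrays={
            "mask_a": mask_a,
            "mask_b": mask_b,
            "clean_a": clean_a,
            "clean_b": clean_b,
        },
    )
    return scene, truth


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def simulate_frap_series(
    mobile_fraction: float,
    tau_s: float,
    bleach_depth: float = 0.8,
    acquisition_bleach_rate: float = 0.0,
    n_pre: int = 5,
    n_post: int = 100,
    dt_s: float = 0.5,
    i_pre: float = 1000.0,
    background: float = 50.0,
    cell_intensity: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FRAPSeries, GroundTruth]:
    """Exponential-recovery FRAP trace with acquisition bleaching.

    Post-bleach ROI signal (above background) is
    ``i_pre * exp(-lam t) * [(1 - depth) + depth * Fm * (1 - exp(-t'/tau))]``
    with ``t'`` measured from the bleach; the whole-cell trace decays with
    the same rate ``lam``; background is constant.
    """
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile_fraction must be in [0, 1]")
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if not (0.0 < bleach_depth <= 1.0):
        raise ValueError("bleach_depth must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    t = np.arange(n) * dt_s
    lam = acquisition_bleach_rate
    decay = np.exp(-lam * t)

    roi = i_pre * decay.copy()
    t_post = t[n_pre:] - t[n_pre]
    recovery = (1.0 - bleach_depth) + bleach_depth * mobile_fraction * (
        1.0 - np.exp(-t_post / tau_s)
    )
    roi[n_pre:] = i_pre * decay[n_pre:] * recovery
    cell = cell_intensity * decay
    bg = np.full(n, background)

    if noise_sd > 0:
        roi = roi + rng.normal(0, noise_sd * i_pre, n)
        cell = cell + rng.normal(0, noise_sd * cell_intensity, n)
        bg = bg + rng.normal(0, noise_sd * background, n)

    series = FRAPSeries(t_s=t, roi=roi + bg, cell=cell + bg, bg=bg, bleach_index=n_pre)
    truth = GroundTruth(
        kind="frap_series",
        params={
            "mobile_fraction": mobile_fraction,
            "tau_s": tau_s,
            "bleach_depth": bleach_depth,
            "acquisition_bleach_rate": acquisition_bleach_rate,
            "n_pre": n_pre,
            "n_post": n_post,
            "dt_s": dt_s,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        derived={"t_half_s": float(tau_s * np.log(2.0))},
    )
    return series, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectories(
    n_tracks: int,
    n_frames: int,
    dt_s: float = 0.1,
    d_confined_um2s: float = 0.01,
    d_active_um2s: float = 0.05,
    drift_speed_um_s: float = 0.0,
    switch_prob: float = 0.0,
    confinement_radius_um: float = 0.15,
    loc_error_um: float = 0.0,
    start_state: int | None = None,
    field_um: float = 20.0,
    seed: int = 0,
) -> tuple[TrajectorySet, GroundTruth]:
    """Two-state (confined / active) switching-diffusion trajectories.

    State 0 = confined: Brownian motion with ``d_confined`` reflected in a
    disc of ``confinement_radius`` around the bout anchor. State 1 =
    active: Brownian motion with ``d_active`` plus directed drift along a
    per-bout random direction. The per-frame state sequence is ground
    truth. Default ``dt_s`` is 0.1 s (10 Hz acquisition).
    """
    rng = np.random.default_rng(seed)
    tracks: list[Track] = []
    states_all = np.zeros((n_tracks, n_frames), dtype=np.int8)
    for tid in range(n_tracks):
        pos = rng.uniform(0, field_um, size=2)
        state = (
            start_state if start_state is not None else int(rng.integers(0, 2))
        )
        anchor = pos.copy()
        theta = rng.uniform(0, 2 * np.pi)
        drift = drift_speed_um_s * np.array([np.cos(theta), np.sin(theta)])
        xy = np.empty((n_frames, 2))
        xy[0] = pos
        states = np.empty(n_frames, dtype=np.int8)
        states[0] = state
        for i in range(1, n_frames):
            if switch_prob > 0 and rng.uniform() < switch_prob:
                state = 1 - state
                if state == 0:
                    anchor = pos.copy()
                else:
                    theta = rng.uniform(0, 2 * np.pi)
                    drift = drift_speed_um_s * np.array(
                        [np.cos(theta), np.sin(theta)]
                    )
            if state == 0:
                step = rng.normal(0, np.sqrt(2 * d_confined_um2s * dt_s), 2)
                cand = pos + step
                offset = cand - anchor
                r = np.linalg.norm(offset)
                if r > confinement_radius_um and r > 0:
                    # radial reflection back into the confinement disc
                    r_new = max(2 * confinement_radius_um - r, 0.0)
                    cand = anchor + offset / r * r_new
                pos = cand
            else:
                step = rng.normal(0, np.sqrt(2 * d_active_um2s * dt_s), 2)
                pos = pos + step + drift * dt_s
            xy[i] = pos
            states[i] = state
        observed = xy + (
            rng.normal(0, loc_error_um, xy.shape) if loc_error_um > 0 else 0.0
        )
        tracks.append(Track(np.arange(n_frames), observed))
        states_all[tid] = states

    ts = TrajectorySet(tracks=tracks, dt_s=dt_s)
    truth = GroundTruth(
        kind="trajectories",
        params={
            "n_tracks": n_tracks,
            "n_frames": n_frames,
            "dt_s": dt_s,
            "d_confined_um2s": d_confined_um2s,
            "d_active_um2s": d_active_um2s,
            "drift_speed_um_s": drift_speed_um_s,
            "switch_prob": switch_prob,
            "confinement_radius_um": confinement_radius_um,
            "loc_error_um": loc_error_um,
            "seed": seed,
        },
        derived={"state_names": ["confined", "active"]},
        arrays={"states": states_all},
    )
    return ts, truth


# ---------------------------------------------------------------------------
# PLA dot fields
# ---------------------------------------------------------------------------


def simulate_pla_image(
    n_spots: int,
    cell_count: int = 3,
    spot_sigma_um: float = 0.15,
    cell_radius_um: float = 4.0,
    spot_intensity: float = 800.0,
    cell_intensity: float = 300.0,
    min_spot_separation_um: float | None = None,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    seed: int = 0,
) -> tuple[ImageScene, GroundTruth]:
    """PLA dot field: DAPI cell discs plus Gaussian dots assigned to cells.

    Spots are placed inside cell discs (shrunk by a margin) so that cell
    assignment by containment is unambiguous; per-cell counts are truth.
    """
    rng = np.random.default_rng(seed)
    cell_radius_px = cell_radius_um / pixel_size_um
    sigma_px = spot_sigma_um / pixel_size_um
    if min_spot_separation_um is None:
        min_spot_separation_um = 4.0 * spot_sigma_um
    min_sep_px = min_spot_separation_um / pixel_size_um

    # lay cells on a loose grid with jitter; guarantees disjoint discs
    n_side = int(np.ceil(np.sqrt(cell_count)))
    pitch = 2 * cell_radius_px + 10
    size = int(n_side * pitch + 10)
    shape = (size, size)
    cell_centers = []
    for k in range(cell_count):
        gy, gx = divmod(k, n_side)
        cy = 5 + cell_radius_px + gy * pitch + rng.uniform(-2, 2)
        cx = 5 + cell_radius_px + gx * pitch + rng.uniform(-2, 2)
        cell_centers.append((cy, cx))

    dapi = np.zeros(shape, dtype=np.float64)
    for c in cell_centers:
        dapi[_disc_mask(shape, c, cell_radius_px)] = cell_intensity

    owners = rng.integers(0, cell_count, size=n_spots) if cell_count else np.array([], dtype=int)
    counts = np.bincount(owners, minlength=cell_count) if cell_count else np.array([], dtype=int)
    spot_centers: list[tuple[float, float]] = []
    for k in range(cell_count):
        placed = _place_in_disc(
            rng, int(counts[k]), cell_centers[k],
            cell_radius_px - 3 * sigma_px - 2, min_sep_px,
            avoid=spot_centers,
        )
        spot_centers.extend(placed)

    pla_clean = np.zeros(shape, dtype=np.float64)
    for c in spot_centers:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        pla_clean += spot_intensity * np.exp(
            -((yy - c[0]) ** 2 + (xx - c[1]) ** 2) / (2 * sigma_px**2)
        )
    pla = _add_noise(pla_clean, rng, noise_sd)
    dapi_noisy = _add_noise(dapi, rng, noise_sd)

    scene = ImageScene(np.stack([dapi_noisy, pla]), ["DAPI", "PLA"], pixel_size_um)
    truth = GroundTruth(
        kind="pla_image",
        params={
            "n_spots": n_spots,
            "cell_count": cell_count,
            "spot_sigma_um": spot_sigma_um,
            "noise_sd": noise_sd,
            "seed": seed,
            "pixel_size_um": pixel_size_um,
        },
        derived={
            "counts_per_cell": counts.tolist(),
            "cell_centers_px": [list(c) for c in cell_centers],
            "spot_centers_px": [list(c) for c in spot_centers],
        },
        arrays={"pla_clean": pla_clean, "dapi_clean": dapi},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# synapse conjugate scenes
# ---------------------------------------------------------------------------


def _pair_geometry(
    shape: tuple[int, int],
    b_center: np.ndarray,
    direction: np.ndarray,
    b_radius: float,
    t_radius: float,
    contact_halfwidth_px: float,
) -> dict:
    """Masks for one B–T conjugate: discs, membranes, contact zone."""
    t_center = b_center + direction * (b_radius + t_radius - 1.0)
    touch = b_center + direction * b_radius
    b_disc = _disc_mask(shape, tuple(b_center), b_radius)
    t_disc = _disc_mask(shape, tuple(t_center), t_radius)
    b_mem = _annulus_mask(shape, tuple(b_center), b_radius)
    t_mem = _annulus_mask(shape, tuple(t_center), t_radius)
    near_touch = _disc_mask(shape, tuple(touch), contact_halfwidth_px)
    contact = near_touch & (b_mem | t_mem)
    return {
        "t_center": t_center,
        "b_disc": b_disc,
        "t_disc": t_disc,
        "b_mem": b_mem,
        "t_mem": t_mem,
        "contact": contact,
    }


def simulate_synapse_scene(
    n_pairs: int,
    enrichment_ratio: float = 2.0,
    cd3_contact_boost: float = 3.0,
    contact_halfwidth_um: float = 0.8,
    n_free_b_cells: int = 0,
    n_free_t_cells: int = 0,
    b_radius_um: float = 3.5,
    t_radius_um: float = 3.0,
    cd3_intensity: float = 100.0,
    mhc2_intensity: float = 200.0,
    cd70_out_intensity: float = 100.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    image_size_px: int | None = None,
    seed: int = 0,
) -> tuple[ImageScene, GroundTruth]:
    """Two-cell conjugate scenes with a CD3-boosted contact zone.

    Each conjugate is a CD3+ T-cell disc touching an MHCII+ B-cell disc.
    The contact zone (membrane pixels near the touch point) carries CD3
    boosted by ``cd3_contact_boost`` and CD70 at ``enrichment_ratio`` times
    the out-of-contact B-membrane CD70 level. Ground truth records the
    contact masks, B-membrane masks, the true ratio and the cell counts.
    """
    if enrichment_ratio < 0:
        raise ValueError("enrichment_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    b_r = b_radius_um / pixel_size_um
    t_r = t_radius_um / pixel_size_um
    halfwidth = contact_halfwidth_um / pixel_size_um

    n_units = n_pairs + n_free_b_cells + n_free_t_cells
    n_side = max(int(np.ceil(np.sqrt(max(n_units, 1)))), 1)
    pitch = 2 * (b_r + t_r) + 12
    if image_size_px is None:
        image_size_px = int(n_side * pitch + 2 * b_r)
    shape = (image_size_px, image_size_px)

    cd3 = np.zeros(shape, dtype=np.float64)
    mhc2 = np.zeros(shape, dtype=np.float64)
    cd70 = np.zeros(shape, dtype=np.float64)
    contact_masks: list[np.ndarray] = []
    b_membranes: list[np.ndarray] = []

    slots = []
    for k in range(n_units):
        gy, gx = divmod(k, n_side)
        slots.append(
            np.array(
                [
                    b_r + t_r + 4 + gy * pitch + rng.uniform(-2, 2),
                    b_r + t_r + 4 + gx * pitch + rng.uniform(-2, 2),
                ]
            )
        )

    for k in range(n_pairs):
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(theta), np.cos(theta)])
        geo = _pair_geometry(shape, slots[k], direction, b_r, t_r, halfwidth)
        cd3[geo["t_disc"]] = cd3_intensity
        cd3[geo["contact"]] = cd3_intensity * cd3_contact_boost
        mhc2[geo["b_disc"]] = mhc2_intensity
        cd70[geo["b_mem"]] = cd70_out_intensity
        cd70[geo["contact"]] = cd70_out_intensity * enrichment_ratio
        contact_masks.append(geo["contact"])
        b_membranes.append(geo["b_mem"])

    for k in range(n_pairs, n_pairs + n_free_b_cells):
        b_disc = _disc_mask(shape, tuple(slots[k]), b_r)
        b_mem = _annulus_mask(shape, tuple(slots[k]), b_r)
        mhc2[b_disc] = mhc2_intensity
        cd70[b_mem] = cd70_out_intensity
    for k in range(n_pairs + n_free_b_cells, n_units):
        cd3[_disc_mask(shape, tuple(slots[k]), t_r)] = cd3_intensity

    cd3 = _add_noise(cd3, rng, noise_sd)
    mhc2 = _add_noise(mhc2, rng, noise_sd)
    cd70 = _add_noise(cd70, rng, noise_sd)

    scene = ImageScene(
        np.stack([cd3, mhc2, cd70]), ["CD3", "MHCII", "CD70"], pixel_size_um
    )
    truth = GroundTruth(
        kind="synapse_scene",
        params={
            "n_pairs": n_pairs,
            "enrichment_ratio": enrichment_ratio,
            "cd3_contact_boost": cd3_contact_boost,
            "contact_halfwidth_um": contact_halfwidth_um,
            "n_free_b_cells": n_free_b_cells,
            "n_free_t_cells": n_free_t_cells,
            "noise_sd": noise_sd,
            "seed": seed,
            "pixel_size_um": pixel_size_um,
        },
        derived={
            "n_synapses": n_pairs,
            "n_b_cells": n_pairs + n_free_b_cells,
            "n_t_cells": n_pairs + n_free_t_cells,
        },
        arrays={
            "contact_masks": np.array(contact_masks)
            if contact_masks
            else np.zeros((0,) + shape, dtype=bool),
            "b_membranes": np.array(b_membranes)
            if b_membranes
            else np.zeros((0,) + shape, dtype=bool),
        },
    )
    return scene, truth


# ---------------------------------------------------------------------------
# micropattern stamps
# ---------------------------------------------------------------------------


def simulate_stamp_scene(
    spot_diameter_um: float = 5.0,
    pitch_um: float = 10.0,
    on_stamp_enrichment: float = 2.0,
    stamp_intensity: float = 500.0,
    reporter_base: float = 100.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    image_size_px: int = 300,
    seed: int = 0,
) -> tuple[ImageScene, GroundTruth]:
    """Periodic circular stamp pattern plus an enriched reporter channel."""
    if on_stamp_enrichment < 0:
        raise ValueError("on_stamp_enrichment must be >= 0")
    rng = np.random.default_rng(seed)
    radius_px = spot_diameter_um / 2.0 / pixel_size_um
    pitch_px = pitch_um / pixel_size_um
    shape = (image_size_px, image_size_px)
    stamp_mask = np.zeros(shape, dtype=bool)
    y = pitch_px / 2.0
    while y < image_size_px:
        x = pitch_px / 2.0
        while x < image_size_px:
            stamp_mask |= _disc_mask(shape, (y, x), radius_px)
            x += pitch_px
        y += pitch_px

    stamp = np.where(stamp_mask, stamp_intensity, 0.0)
    reporter = np.where(
        stamp_mask, reporter_base * on_stamp_enrichment, reporter_base
    )
    stamp = _add_noise(stamp, rng, noise_sd)
    reporter = _add_noise(reporter, rng, noise_sd)
    scene = ImageScene(np.stack([stamp, reporter]), ["STAMP", "CD70"], pixel_size_um)
    truth = GroundTruth(
        kind="stamp_scene",
        params={
            "spot_diameter_um": spot_diameter_um,
            "pitch_um": pitch_um,
            "on_stamp_enrichment": on_stamp_enrichment,
            "noise_sd": noise_sd,
            "seed": seed,
            "pixel_size_um": pixel_size_um,
        },
        derived={"stamp_pixels": int(stamp_mask.sum())},
        arrays={"stamp_mask": stamp_mask},
    )
    return scene, truth


# ---------------------------------------------------------------------------
# calibration beads
# ---------------------------------------------------------------------------


def simulate_calibration_beads(
    abc_values: list[float] | None = None,
    sample_abcs: list[float] | None = None,
    gain: float = 0.02,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bead calibration table: ``MFI = gain * ABC * (1 + noise)``.

    Returns a table with bead rows (known ABC, measured MFI) and sample
    rows (measured MFI only; true ABC held in ground truth).
    """
    if abc_values is None:
        abc_values = [2500.0, 8000.0, 25000.0, 70000.0, 240000.0]
    if sample_abcs is None:
        sample_abcs = []
    rng = np.random.default_rng(seed)

    def mfi_of(abc: float) -> float:
        noise = rng.normal(0, noise_cv) if noise_cv > 0 else 0.0
        return gain * abc * (1.0 + noise)

    rows = [
        {"kind": "bead", "abc": abc, "mfi": mfi_of(abc)} for abc in abc_values
    ]
    rows += [
        {"kind": "sample", "abc": np.nan, "mfi": mfi_of(abc)}
        for abc in sample_abcs
    ]
    table = pd.DataFrame(rows, columns=["kind", "abc", "mfi"])
    truth = GroundTruth(
        kind="calibration_beads",
        params={
            "gain": gain,
            "noise_cv": noise_cv,
            "seed": seed,
        },
        derived={
            "abc_values": list(abc_values),
            "sample_abcs": list(sample_abcs),
        },
    )
    return table, truth
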