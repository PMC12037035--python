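"""Immune-synapse detection, recruitment scoring and group comparison.

Synapse candidates are the top percentile of CD3 signal over the CD3
foreground; recruitment compares mean reporter intensity inside the
contact to seeded random control regions on the partner-cell membrane.
Recruitment is called when in-contact signal reaches 150% of the
out-of-contact signal (inclusive threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .io_core import ImageScene, LabelMask, log_operation

logger = logging.getLogger("fluoquant")

__all__ = [
    "SynapseRecord",
    "detect_synapses",
    "score_recruitment",
    "synapses_per_cell",
    "stamp_enrichment",
    "compare_groups",
]

RECRUITMENT_THRESHOLD_PCT = 150.0
CD3_TOP_PERCENT_DEFAULT = 1.0
N_CONTROL_ROIS_DEFAULT = 5


@dataclass
class SynapseRecord:
    synapse_id: int
    in_mean: float
    out_mean: float
    enrichment_pct: float
    recruited: bool
    scored: bool
    n_control_rois: int

    def as_dict(self) -> dict:
        return {
            "synapse_id": self.synapse_id,
            "in_mean": self.in_mean,
            "out_mean": self.out_mean,
            "enrichment_pct": self.enrichment_pct,
            "recruited": self.recruited,
            "scored": self.scored,
            "n_control_rois": self.n_control_rois,
        }


def _foreground(img: np.ndarray) -> np.ndarray:
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    return img >= threshold_otsu(img)


def detect_synapses(
    scene: ImageScene,
    cd3_channel: str = "CD3",
    mhc2_channel: str = "MHCII",
    cd3_top_percent: float = CD3_TOP_PERCENT_DEFAULT,
    min_region_px: int = 20,
    mhc2_adjacency_px: int = 3,
) -> list[LabelMask]:
    """Candidate synapse contacts from the top percentile of CD3 signal.

    The CD3 percentile is taken over the CD3 foreground (above Otsu), not
    the whole field, so field-of-view size does not change the threshold.
    Components are kept when their ``mhc2_adjacency_px`` dilation touches
    the MHC II foreground (the B cell) — an automated stand-in for manual
    B-cell-contact curation.
    """
    if not (0 < cd3_top_percent <= 100):
        raise ValueError("cd3_top_percent must be in (0, 100]")
    cd3 = scene.channel(cd3_channel)
    mhc2 = scene.channel(mhc2_channel)
    fg = _foreground(cd3)
    mhc2_mask = _foreground(mhc2)
    if not mhc2_mask.any():
        logger.warning("detect_synapses: no MHC II signal; zero synapses")
        return []
    if not fg.any():
        return []
    thr = np.percentile(cd3[fg], 100.0 - cd3_top_percent)
    top = fg & (cd3 >= thr)
    labeled = cc_label(top, connectivity=2)
    out: list[LabelMask] = []
    structure = np.ones((3, 3), dtype=bool)
    for region_id in range(1, labeled.max() + 1):
        region = labeled == region_id
        if region.sum() < min_region_px:
            continue
        dilated = ndimage.binary_dilation(
            region, structure=structure, iterations=mhc2_adjacency_px
        )
        if not (dilated & mhc2_mask).any():
            continue
        out.append(LabelMask(region.astype(np.int32)))
    log_operation("synapse.detect_synapses", n_candidates=len(out),
                  cd3_top_percent=cd3_top_percent, threshold=float(thr))
    return out


def _place_control_rois(
    roi_mask: np.ndarray,
    allowed: np.ndarray,
    n_rois: int,
    rng: np.random.Generator,
    min_overlap_frac: float = 0.35,
    max_attempts: int = 1000,
) -> list[np.ndarray]:
    """Translate copies of the ROI onto the allowed mask by random search.

    A placement is accepted when at least ``min_overlap_frac`` of the
    translated ROI lands on allowed pixels; the measured control region is
    that intersection. Placements must not reuse a previous anchor.
    """
    ys, xs = np.nonzero(roi_mask)
    cy, cx = ys.mean(), xs.mean()
    ay, ax = np.nonzero(allowed)
    if len(ay) == 0:
        return []
    h, w = roi_mask.shape
    roi_n = len(ys)
    placed: list[np.ndarray] = []
    used: set[tuple[int, int]] = set()
    for _ in range(max_attempts):
        if len(placed) >= n_rois:
            break
        k = int(rng.integers(0, len(ay)))
        dy = int(round(ay[k] - cy))
        dx = int(round(ax[k] - cx))
        if (dy, dx) in used:
            continue
        ny = ys + dy
        nx = xs + dx
        inside = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        if inside.sum() < roi_n * min_overlap_frac:
            continue
        cand = np.zeros_like(roi_mask)
        cand[ny[inside], nx[inside]] = True
        cand &= allowed
        if cand.sum() < roi_n * min_overlap_frac:
            continue
        used.add((dy, dx))
        placed.append(cand)
    return placed


def score_recruitment(
    scene: ImageScene,
    contact_mask: LabelMask | np.ndarray,
    reporter_channel: str = "CD70",
    membrane_channel: str | None = None,
    n_control_rois: int = N_CONTROL_ROIS_DEFAULT,
    recruitment_threshold_pct: float = RECRUITMENT_THRESHOLD_PCT,
    synapse_id: int = 1,
    seed: int = 0,
) -> SynapseRecord:
    """Score reporter enrichment of one contact against membrane controls.

    ``out_mean`` averages the reporter over up to ``n_control_rois``
    regions congruent to the contact, translated onto the partner-cell
    membrane (reporter foreground) excluding the contact and its 2-px
    dilation. The recruited flag is inclusive at the threshold.
    """
    contact = (
        contact_mask.labels > 0
        if isinstance(contact_mask, LabelMask)
        else np.asarray(contact_mask, dtype=bool)
    )
    if not contact.any():
        raise ValueError("contact mask is empty")
    reporter = scene.channel(reporter_channel)
    membrane_src = scene.channel(membrane_channel) if membrane_channel else reporter
    membrane = _foreground(membrane_src)
    excluded = ndimage.binary_dilation(contact, np.ones((3, 3), dtype=bool), 2)
    # restrict controls to the partner cell: the membrane component(s)
    # touching the contact, not some other cell's (possibly enriched) membrane
    mem_labels = cc_label(membrane, connectivity=2)
    partner_ids = np.unique(mem_labels[excluded & membrane])
    partner_ids = partner_ids[partner_ids > 0]
    partner = (
        np.isin(mem_labels, partner_ids) if len(partner_ids) else membrane
    )
    allowed = partner & ~excluded

    rng = np.random.default_rng(seed)
    rois = _place_control_rois(contact, allowed, n_control_rois, rng)
    if len(rois) < n_control_rois:
        logger.warning(
            "score_recruitment: placed %d/%d control ROIs", len(rois), n_control_rois
        )
    in_mean = float(reporter[contact].mean())
    if not rois:
        return SynapseRecord(synapse_id, in_mean, np.nan, np.nan, False, False, 0)
    out_mean = float(np.mean([reporter[r].mean() for r in rois]))
    if out_mean == 0:
        logger.warning("score_recruitment: zero out-of-contact signal; unscored")
        return SynapseRecord(synapse_id, in_mean, 0.0, np.nan, False, False, len(rois))
    enrichment_pct = 100.0 * in_mean / out_mean
    recruited = enrichment_pct >= recruitment_threshold_pct
    log_operation("synapse.score_recruitment", synapse_id=synapse_id,
                  enrichment_pct=enrichment_pct, recruited=recruited,
                  n_control_rois=len(rois), seed=seed)
    return SynapseRecord(
        synapse_id, in_mean, out_mean, enrichment_pct, recruited, True, len(rois)
    )


def _count_cells(img: np.ndarray, min_area_px: int = 50) -> int:
    mask = _foreground(img)
    mask = ndimage.binary_fill_holes(mask)
    labeled = cc_label(mask, connectivity=2)
    return int(
        sum(
            1
            for rid in range(1, labeled.max() + 1)
            if (labeled == rid).sum() >= min_area_px
        )
    )


def synapses_per_cell(
    scene: ImageScene,
    detected: list[LabelMask],
    cd3_channel: str = "CD3",
    mhc2_channel: str = "MHCII",
    min_cell_area_px: int = 50,
) -> pd.DataFrame:
    """Synapse counts normalized per B cell and per T cell.

    Zero cells of a type gives a missing ratio rather than an exception.
    """
    n_b = _count_cells(scene.channel(mhc2_channel), min_cell_area_px)
    n_t = _count_cells(scene.channel(cd3_channel), min_cell_area_px)
    n_syn = len(detected)
    row = {
        "n_synapses": n_syn,
        "n_b_cells": n_b,
        "n_t_cells": n_t,
        "synapses_per_b_cell": n_syn / n_b if n_b else np.nan,
        "synapses_per_t_cell": n_syn / n_t if n_t else np.nan,
    }
    return pd.DataFrame([row])


def stamp_enrichment(
    scene: ImageScene,
    stamp_channel: str = "STAMP",
    reporter_channel: str = "CD70",
    cell_mask: LabelMask | None = None,
) -> pd.DataFrame:
    """On-stamp vs off-stamp mean reporter intensity and their ratio."""
    stamp = scene.channel(stamp_channel)
    reporter = scene.channel(reporter_channel)
    if stamp.max() == stamp.min():
        raise ValueError("stamp channel is empty or constant")
    on = _foreground(stamp)
    footprint = (
        cell_mask.labels > 0 if cell_mask is not None else np.ones_like(on)
    )
    on_sel = on & footprint
    off_sel = ~on & footprint
    if not on_sel.any() or not off_sel.any():
        raise ValueError("stamp mask leaves no on- or off-stamp pixels")
    on_mean = float(reporter[on_sel].mean())
    off_mean = float(reporter[off_sel].mean())
    ratio = on_mean / off_mean if off_mean else np.nan
    log_operation("synapse.stamp_enrichment", on_mean=on_mean,
                  off_mean=off_mean, ratio=ratio)
    return pd.DataFrame(
        [{"on_mean": on_mean, "off_mean": off_mean, "ratio": ratio}]
    )


def summarize_image(records: list[SynapseRecord]) -> dict:
    """Per-image recruited fraction and mean enrichment."""
    scored = [r for r in records if r.scored]
    if not scored:
        return {
            "n_synapses": len(records),
            "n_scored": 0,
            "recruited_fraction": np.nan,
            "mean_enrichment_pct": np.nan,
        }
    return {
        "n_synapses": len(records),
        "n_scored": len(scored),
        "recruited_fraction": float(np.mean([r.recruited for r in scored])),
        "mean_enrichment_pct": float(np.mean([r.enrichment_pct for r in scored])),
    }


def compare_groups(
    group_a: list[list[SynapseRecord]],
    group_b: list[list[SynapseRecord]],
) -> pd.DataFrame:
    """Per-image summaries of two conditions plus a rank-sum comparison.

    The statistical unit is the image. With fewer than two images in
    either group the p-value is reported missing.
    """
    rows = []
    for name, group in (("a", group_a), ("b", group_b)):
        for i, records in enumerate(group):
            rows.append({"group": name, "image": i, **summarize_image(records)})
    table = pd.DataFrame(rows)
    fa = table.loc[table["group"] == "a", "recruited_fraction"].dropna()
    fb = table.loc[table["group"] == "b", "recruited_fraction"].dropna()
    if len(fa) < 2 or len(fb) < 2:
        p = np.nan
    else:
        p = float(mannwhitneyu(fa, fb, alternative="two-sided").pvalue)
    table["rank_test_p"] = p
    return table
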