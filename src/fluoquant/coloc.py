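"""Pearson and Manders colocalization with Costes bisection auto-threshold."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import ImageScene, LabelMask, log_operation

logger = logging.getLogger("fluoquant")

__all__ = ["ColocResult", "pearson_coefficient", "manders_coefficients"]

BISECTION_MAX_ITER = 64
BISECTION_R_TOL = 0.01  # stop when below-threshold Pearson is in (-tol, 0]
# relative interval-collapse criterion keeps thresholds exactly covariant
# under positive rescaling of either channel
BISECTION_INTERVAL_REL = 1e-9


@dataclass
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_ch1: float
    threshold_ch2: float
    n_pixels_analyzed: int
    threshold_mode: str

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "manders_m1": self.manders_m1,
            "manders_m2": self.manders_m2,
            "threshold_ch1": self.threshold_ch1,
            "threshold_ch2": self.threshold_ch2,
            "n_pixels_analyzed": self.n_pixels_analyzed,
            "threshold_mode": self.threshold_mode,
        }


def _masked_pixels(
    scene: ImageScene, ch_a: str, ch_b: str, mask: LabelMask | None
) -> tuple[np.ndarray, np.ndarray]:
    a = scene.channel(ch_a)
    b = scene.channel(ch_b)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if mask is not None:
        keep = mask.labels > 0
        if keep.shape != a.shape:
            raise ValueError("mask shape does not match channels")
        a, b = a[keep], b[keep]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels to correlate")
    return a, b


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either vector is constant."""
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt(np.sum(am**2) * np.sum(bm**2))
    if denom == 0:
        return np.nan
    return float(np.sum(am * bm) / denom)


def pearson_coefficient(
    scene: ImageScene, ch_a: str, ch_b: str, mask: LabelMask | None = None
) -> float:
    """Pearson correlation of two channels over the (optional) mask.

    Zero-zero pixels inside the mask are retained. Constant channels give
    NaN with a warning rather than an exception.
    """
    a, b = _masked_pixels(scene, ch_a, ch_b, mask)
    r = _pearson(a, b)
    if np.isnan(r):
        logger.warning("pearson_coefficient: constant channel, correlation undefined")
    log_operation("coloc.pearson", ch_a=ch_a, ch_b=ch_b, n_pixels=a.size, r=r)
    return r


def _axis_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Reduced-major-axis line b = m a + c.

    Slope sd(b)/sd(a) with the sign of the correlation; unlike plain
    orthogonal regression this is exactly equivariant under rescaling of
    either channel, which keeps Manders coefficients scale-invariant.
    """
    sd_a = float(np.std(a))
    sd_b = float(np.std(b))
    if sd_a == 0 or sd_b == 0:
        raise ValueError("degenerate regression: constant channel")
    r = _pearson(a, b)
    m = np.sign(r if r != 0 else 1.0) * sd_b / sd_a
    c = b.mean() - m * a.mean()
    return float(m), float(c)


def _costes_thresholds(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Bisection search for the Costes auto-threshold pair.

    Candidate thresholds move along the orthogonal-regression line; the
    kept pair is the highest for which the Pearson correlation of pixels
    below both thresholds is <= 0 (undefined correlations of near-constant
    background count as uncorrelated).
    """
    m, c = _axis_regression(a, b)  # raises on constant channel
    overall = _pearson(a, b)
    if np.isnan(overall) or overall <= 0 or m <= 0:
        # anticorrelated or uncorrelated image: nothing colocalized
        return float(a.max()), float(b.max())
    lo, hi = float(a.min()), float(a.max())

    def below_r(t: float) -> float:
        sel = (a < t) & (b < m * t + c)
        if sel.sum() < 2:
            return 0.0
        r = _pearson(a[sel], b[sel])
        return 0.0 if np.isnan(r) else r

    t = lo
    for _ in range(BISECTION_MAX_ITER):
        mid = (lo + hi) / 2.0
        r = below_r(mid)
        if r > 0:
            hi = mid
        else:
            lo = mid
            t = mid
            if -BISECTION_R_TOL < r <= 0:
                break
        if hi - lo < BISECTION_INTERVAL_REL * (float(a.max()) - float(a.min())):
            break
    return t, m * t + c


def manders_coefficients(
    scene: ImageScene,
    ch_a: str,
    ch_b: str,
    mask: LabelMask | None = None,
    threshold_mode: str = "bisection_costes",
    fixed_thresholds: tuple[float, float] = (0.0, 0.0),
) -> ColocResult:
    """Manders M1/M2 with Costes bisection auto-thresholds.

    ``M1 = sum(a over pixels with b > T_b) / sum(a)`` and symmetrically
    for M2. Degenerate regression (constant channel) falls back to fixed
    thresholds with a warning.
    """
    if threshold_mode not in ("bisection_costes", "fixed"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    a, b = _masked_pixels(scene, ch_a, ch_b, mask)
    mode = threshold_mode
    if mode == "bisection_costes":
        try:
            t_a, t_b = _costes_thresholds(a, b)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning(
                "manders_coefficients: %s; falling back to fixed thresholds", exc
            )
            mode = "fixed"
    if mode == "fixed":
        t_a, t_b = fixed_thresholds

    sum_a = a.sum()
    sum_b = b.sum()
    m1 = float(a[b > t_b].sum() / sum_a) if sum_a > 0 else np.nan
    m2 = float(b[a > t_a].sum() / sum_b) if sum_b > 0 else np.nan
    result = ColocResult(
        pearson_r=_pearson(a, b),
        manders_m1=m1,
        manders_m2=m2,
        threshold_ch1=float(t_a),
        threshold_ch2=float(t_b),
        n_pixels_analyzed=int(a.size),
        threshold_mode=mode,
    )
    log_operation("coloc.manders", ch_a=ch_a, ch_b=ch_b, mode=mode,
                  m1=m1, m2=m2, t_a=result.threshold_ch1, t_b=result.threshold_ch2)
    return result
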