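"""Fluorescence-recovery-after-photobleaching normalization and fitting.

Traces are double-normalized against whole-cell acquisition bleaching and
background, then fit with a single-exponential recovery model to report the
mobile fraction and half-time of recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_core import log_operation

__all__ = ["FRAPSeries", "FRAPFit", "normalize_series", "fit_recovery", "batch_frap"]

MOBILE_FRACTION_CAP = 1.05


@dataclass
class FRAPSeries:
    """Raw bleach-ROI / whole-cell / background intensity traces.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    ``0 .. bleach_index - 1`` are pre-bleach.
    """

    t_s: np.ndarray
    roi: np.ndarray
    cell: np.ndarray
    bg: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.float64)
        self.roi = np.asarray(self.roi, dtype=np.float64)
        self.cell = np.asarray(self.cell, dtype=np.float64)
        self.bg = np.asarray(self.bg, dtype=np.float64)
        n = len(self.t_s)
        if not (len(self.roi) == len(self.cell) == len(self.bg) == n):
            raise ValueError("trace lengths differ")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.bleach_index < 1:
            raise ValueError("need at least one pre-bleach frame")
        if n - self.bleach_index < 5:
            raise ValueError("need at least five post-bleach frames")
        pre = slice(0, self.bleach_index)
        if np.mean(self.roi[pre] - self.bg[pre]) <= 0:
            raise ValueError("mean pre-bleach (roi - bg) must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.t_s)


@dataclass
class FRAPFit:
    """Single-exponential recovery fit summary."""

    mobile_fraction: float
    t_half_s: float
    plateau: float
    tau_s: float
    i0: float
    rss: float
    n_points: int
    converged: bool
    mobile_fraction_capped: bool = False

    def as_dict(self) -> dict:
        return {
            "mobile_fraction": self.mobile_fraction,
            "t_half_s": self.t_half_s,
            "plateau": self.plateau,
            "tau_s": self.tau_s,
            "i0": self.i0,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "mobile_fraction_capped": self.mobile_fraction_capped,
        }


def normalize_series(series: FRAPSeries) -> tuple[np.ndarray, np.ndarray]:
    """Double-normalize a FRAP trace for background and acquisition bleaching.

    ``I_norm(t) = [(roi - bg) / (cell - bg)] * [mean_pre(cell - bg) / mean_pre(roi - bg)]``

    The pre-bleach mean of the normalized trace is 1 by construction when
    whole-cell and ROI traces bleach at the same rate.
    """
    roi_bg = series.roi - series.bg
    cell_bg = series.cell - series.bg
    bad = np.nonzero(cell_bg <= 0)[0]
    if bad.size:
        raise ValueError(
            f"whole-cell minus background is non-positive at frame {int(bad[0])}"
        )
    pre = slice(0, series.bleach_index)
    scale = np.mean(cell_bg[pre]) / np.mean(roi_bg[pre])
    i_norm = roi_bg / cell_bg * scale
    log_operation("frap.normalize_series", n_frames=series.n_frames,
                  bleach_index=series.bleach_index)
    return series.t_s.copy(), i_norm


def _recovery_model(t: np.ndarray, i0: float, amp: float, tau: float) -> np.ndarray:
    return i0 + amp * (1.0 - np.exp(-t / tau))


def fit_recovery(
    t_s: np.ndarray,
    i_norm: np.ndarray,
    bleach_index: int,
    n_restarts: int = 3,
) -> FRAPFit:
    """Fit ``I(t') = I0 + A (1 - exp(-t'/tau))`` on post-bleach frames.

    Mobile fraction is ``A / (1 - I0)`` (recovered share of the bleached
    signal, using the fitted plateau); ``t_half = tau ln 2``.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    i_norm = np.asarray(i_norm, dtype=np.float64)
    if len(t_s) - bleach_index < 5:
        raise ValueError("need at least five post-bleach points")
    t_post = t_s[bleach_index:] - t_s[bleach_index]
    y = i_norm[bleach_index:]

    i0_init = float(y[0])
    amp_init = float(y[-1] - y[0])
    # time at which the curve first passes I0 + A/2, as tau guess
    half_level = i0_init + amp_init / 2.0
    above = np.nonzero(y >= half_level)[0] if amp_init > 0 else np.array([])
    tau_init = float(t_post[above[0]]) if len(above) and t_post[above[0]] > 0 else max(
        float(t_post[-1]) / 4.0, 1e-3
    )

    bounds = ([-1.0, -0.5, 1e-6], [2.0, 2.0, 1e7])
    rng = np.random.default_rng(0)
    best = None
    converged = False
    for attempt in range(1 + n_restarts):
        p0 = [i0_init, max(amp_init, 1e-6), tau_init]
        if attempt > 0:
            p0 = [
                i0_init + rng.normal(0, 0.05),
                max(amp_init, 1e-6) * float(rng.uniform(0.5, 2.0)),
                tau_init * float(rng.uniform(0.3, 3.0)),
            ]
        p0 = np.clip(p0, np.array(bounds[0]) + 1e-9, np.array(bounds[1]) - 1e-9)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _recovery_model, t_post, y, p0=p0, bounds=bounds, maxfev=20000
                )
            converged = True
            best = popt
            break
        except (RuntimeError, ValueError):
            continue
    if best is None:
        best = np.array([i0_init, amp_init, tau_init])

    i0, amp, tau = (float(v) for v in best)
    resid = y - _recovery_model(t_post, i0, amp, tau)
    rss = float(np.sum(resid**2))
    plateau = i0 + amp
    denom = 1.0 - i0
    fm = amp / denom if abs(denom) > 1e-12 else np.nan
    capped = False
    if np.isfinite(fm) and fm > MOBILE_FRACTION_CAP:
        fm = MOBILE_FRACTION_CAP
        capped = True
    if np.isfinite(fm):
        fm = max(fm, 0.0)
    log_operation("frap.fit_recovery", n_points=len(y), converged=converged,
                  tau_s=tau, mobile_fraction=fm)
    return FRAPFit(
        mobile_fraction=fm,
        t_half_s=tau * np.log(2.0),
        plateau=plateau,
        tau_s=tau,
        i0=i0,
        rss=rss,
        n_points=len(y),
        converged=converged,
        mobile_fraction_capped=capped,
    )


def mobile_fraction_last_frames(
    t_s: np.ndarray, i_norm: np.ndarray, bleach_index: int, k: int = 5
) -> float:
    """Plateau-free estimator: mean of the last ``k`` frames as the plateau."""
    y = np.asarray(i_norm, dtype=np.float64)[bleach_index:]
    plateau = float(np.mean(y[-k:]))
    i0 = float(y[0])
    denom = 1.0 - i0
    return (plateau - i0) / denom if abs(denom) > 1e-12 else np.nan


def batch_frap(
    traces: list[FRAPSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every trace and build the across-trace mean recovery curve.

    Returns ``(fits, curve)``: one FRAPFit row per trace, and the mean ±
    SEM normalized intensity on a common post-bleach time grid (linear
    interpolation of each trace onto the grid).
    """
    if not traces:
        raise ValueError("no traces given")
    rows = []
    post = []
    for i, series in enumerate(traces):
        t, i_norm = normalize_series(series)
        fit = fit_recovery(t, i_norm, series.bleach_index)
        rows.append({"trace": i, **fit.as_dict()})
        t_post = t[series.bleach_index:] - t[series.bleach_index]
        post.append((t_post, i_norm[series.bleach_index:]))

    t_max = min(tp[-1] for tp, _ in post)
    dt = float(np.median(np.diff(post[0][0])))
    grid = np.arange(0.0, t_max + dt / 2, dt)
    interped = np.vstack([np.interp(grid, tp, yp) for tp, yp in post])
    mean = interped.mean(axis=0)
    sem = (
        interped.std(axis=0, ddof=1) / np.sqrt(len(post))
        if len(post) > 1
        else np.zeros_like(mean)
    )
    fits = pd.DataFrame(rows)
    curve = pd.DataFrame({"t_s": grid, "mean_i_norm": mean, "sem_i_norm": sem})
    return fits, curve
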