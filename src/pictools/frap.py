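"""FRAP quantification: trace extraction, normalization, aggregation, fitting.

A bleached anchor-site spot is followed over time together with a local
background region and the whole field. Traces are background-subtracted,
divided by the whole-field trace to remove acquisition photobleaching, and
full-scale normalized (pre-bleach mean = 1, first post-bleach point = 0), so
the normalized curve reads directly as the recovered — i.e. exchanged —
fraction. Replicates are aggregated as pointwise mean ± sample SD, and a
single-exponential model ``mobile·(1 − exp(−k_app·t))`` can be fitted to the
post-bleach curve. A flat curve near 0 indicates a stable complex with
little exchange over the observation window; fast recovery toward 1
indicates a short-lived, rapidly exchanging interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .simgen import FrapTrace

__all__ = [
    "NormalizedTrace",
    "FrapCurve",
    "RecoveryFit",
    "FitError",
    "extract_trace",
    "normalize_frap",
    "aggregate_curves",
    "fit_recovery",
]


class FitError(RuntimeError):
    """Recovery fit failed to converge; carries the best rss found."""

    def __init__(self, message: str, rss: float = float("inf")) -> None:
        super().__init__(message)
        self.rss = rss


@dataclass
class NormalizedTrace:
    """Bleach-corrected, full-scale-normalized single-spot recovery."""

    times: np.ndarray
    values: np.ndarray
    bleach_frame: int


@dataclass
class FrapCurve:
    """Replicate-aggregated recovery curve (pointwise mean ± sample SD)."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    bleach_frame: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("aggregate needs n >= 2 replicates")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class RecoveryFit:
    """Single-exponential recovery parameters."""

    k_app: float
    mobile_fraction: float
    rss: float


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def extract_trace(
    stack: np.ndarray,
    spot_roi: tuple[float, float, float],
    background_roi: tuple[float, float, float],
    bleach_frame: int,
    frame_interval: float = 1.0,
) -> FrapTrace:
    """Per-frame mean intensities over the spot and background ROIs.

    ROIs are circles given as (center_row, center_col, radius); they must lie
    within the frame and not overlap. The whole-field mean is recorded for
    acquisition-bleach correction. Output is raw (uncorrected).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    if stack.shape[0] < 2:
        raise ValueError("stack must contain pre- and post-bleach frames")
    h, w = stack.shape[1:]
    for name, (r, c, rad) in (("spot", spot_roi), ("background", background_roi)):
        if rad <= 0:
            raise ValueError(f"{name} ROI radius must be > 0")
        if r - rad < 0 or r + rad > h - 1 or c - rad < 0 or c + rad > w - 1:
            raise ValueError(f"{name} ROI extends outside the image")
    spot_mask = _disk_mask((h, w), spot_roi[:2], spot_roi[2])
    bg_mask = _disk_mask((h, w), background_roi[:2], background_roi[2])
    if np.any(spot_mask & bg_mask):
        raise ValueError("spot and background ROIs overlap")

    times = np.arange(stack.shape[0]) * frame_interval
    return FrapTrace(
        times=times,
        spot_intensity=stack[:, spot_mask].mean(axis=1),
        background_intensity=stack[:, bg_mask].mean(axis=1),
        whole_field_intensity=stack.mean(axis=(1, 2)),
        bleach_frame=bleach_frame,
    )


def normalize_frap(trace: FrapTrace, full_scale: bool = True) -> NormalizedTrace:
    """Double normalization with optional full-scale rescale.

    The background-subtracted spot trace is divided by the
    background-subtracted whole-field trace (removing acquisition
    photobleaching), scaled so the pre-bleach mean equals 1 and — when
    ``full_scale`` — affinely rescaled so the first post-bleach point is 0.
    The resulting curve is the recovered fraction of the bleached signal.
    """
    b = trace.bleach_frame
    if b < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    field = trace.whole_field_intensity - trace.background_intensity
    if np.any(field <= 0):
        raise ValueError("whole-field intensity must exceed background in every frame")
    ratio = (trace.spot_intensity - trace.background_intensity) / field
    pre = ratio[:b].mean()
    if pre == 0:
        raise ValueError("pre-bleach spot intensity equals background")
    values = ratio / pre
    if full_scale:
        v0 = values[b]
        if v0 >= 1.0:
            raise ValueError("no bleach detected: first post-bleach point >= pre-bleach")
        values = (values - v0) / (1.0 - v0)
    return NormalizedTrace(times=trace.times.copy(), values=values, bleach_frame=b)


def aggregate_curves(traces: Sequence[NormalizedTrace]) -> FrapCurve:
    """Pointwise mean and sample SD over replicates on a common time grid."""
    if len(traces) < 2:
        raise ValueError("need >= 2 replicates to aggregate")
    t0 = traces[0].times
    b0 = traces[0].bleach_frame
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("traces must share an identical time grid (no resampling)")
        if tr.bleach_frame != b0:
            raise ValueError("traces must share the bleach frame")
    values = np.stack([tr.values for tr in traces])
    return FrapCurve(
        times=t0.copy(),
        mean=values.mean(axis=0),
        sd=values.std(axis=0, ddof=1),
        n=len(traces),
        bleach_frame=b0,
    )


def fit_recovery(
    curve: FrapCurve | NormalizedTrace,
    k_max: float = 10.0,
) -> RecoveryFit:
    """Least-squares fit of ``mobile·(1 − exp(−k_app·t'))`` post-bleach.

    ``t'`` is time since the bleach. Parameters are bounded: mobile in
    [0, 1], k_app in [0, k_max]. For a flat curve (no exchange) the mobile
    fraction converges to ~0; for instantaneous full recovery k_app pegs at
    the upper bound.
    """
    values = curve.mean if isinstance(curve, FrapCurve) else curve.values
    b = curve.bleach_frame
    t = curve.times[b:] - curve.times[b]
    y = values[b:]
    if t.size < 5:
        raise ValueError("need >= 5 post-bleach points to fit")

    def model(tt: np.ndarray, mobile: float, k: float) -> np.ndarray:
        return mobile * (1.0 - np.exp(-k * tt))

    plateau = float(np.clip(np.mean(y[-max(3, t.size // 5) :]), 1e-6, 1.0))
    # crude rate guess: time to reach half the plateau
    half_idx = np.argmax(y >= plateau / 2) if np.any(y >= plateau / 2) else t.size - 1
    k0 = float(np.clip(np.log(2) / max(t[half_idx], t[1]), 1e-5, k_max))
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[plateau, k0],
            bounds=([0.0, 0.0], [1.0, k_max]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        rss = float(np.sum((y - model(t, plateau, k0)) ** 2))
        raise FitError(f"recovery fit did not converge: {exc}", rss=rss) from exc
    mobile, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - model(t, mobile, k)) ** 2))
    return RecoveryFit(k_app=k, mobile_fraction=mobile, rss=rss)
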