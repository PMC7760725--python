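"""Graphical (Logan) kinetic analysis and late-window SUV metrics.

Plasma-input Logan plot: with running integrals from time 0,

    int_0^T Ct / Ct(T)  =  DV * int_0^T Cp / Ct(T)  +  b,

so an ordinary-least-squares slope over the late linear phase
(frame midpoints >= t*) estimates the total distribution volume DV
(mL/g).  Replacing Cp by a reference-tissue TAC gives the reference
Logan plot whose slope is the distribution volume ratio DVR directly.
The reference form here is the pure two-integral variant; an optional
k2' (reference efflux) term can be supplied but is off by default.

Integrals are trapezoidal from an implied (0, 0) sample, with frame
midpoints as sample times — exact for piecewise-linear TACs of
decay-corrected frame-averaged data.  Voxels whose late-phase activity
is not strictly positive (or whose design is degenerate) are flagged
invalid and set to 0 rather than propagating NaNs.

SUV = concentration / (injected dose / body weight); SUVR divides the
50–70 min static SUV image by its cerebellar mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .idif import TimeActivityCurve
from .images import DynamicImage, MetricImage
from .phantom import SubjectInfo

__all__ = [
    "AnalysisConfig",
    "LoganFit",
    "logan_slope",
    "logan_reference_slope",
    "logan_dv_image",
    "logan_reference_image",
    "normalize_to_reference",
    "static_image",
    "suv_image",
    "suvr_image",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the graphical analysis."""

    t_star_min: float = 50.0
    static_window_min: tuple[float, float] = (50.0, 70.0)
    reference_region: str = "cerebellum"
    k2_ref: float | None = None  # optional reference-efflux term, per minute
    # plausibility window for voxelwise Logan slopes (DV mL/g or DVR);
    # with few late frames the slope is heavy-tailed under noise, and
    # voxels outside this range are masked invalid rather than allowed
    # to dominate regional means
    slope_range: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.static_window_min[1] <= self.static_window_min[0]:
            raise ValueError("static window must have positive length")
        if self.slope_range[1] <= self.slope_range[0]:
            raise ValueError("slope range must have positive length")


@dataclass(frozen=True)
class LoganFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _running_integral(activity: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Trapezoid integral from t=0 with an implied (0, 0) sample."""
    t0 = np.concatenate([[0.0], t_min])
    a0 = np.concatenate(
        [np.zeros(activity.shape[:-1] + (1,)), activity], axis=-1
    )
    seg = 0.5 * (a0[..., 1:] + a0[..., :-1]) * np.diff(t0)
    return np.cumsum(seg, axis=-1)


def _logan_xy(ct, cx, t_min, t_star, k2_ref=None):
    ict = _running_integral(ct, t_min)
    icx = _running_integral(cx, t_min)
    if k2_ref is not None:
        icx = icx + cx / k2_ref
    late = t_min >= t_star
    if late.sum() < 2:
        raise ValueError(
            f"need at least 2 frames with midpoint >= t*={t_star} min, found {late.sum()}"
        )
    ct_late = ct[..., late]
    return icx[..., late] / ct_late, ict[..., late] / ct_late, late


def _fit_line(x: np.ndarray, y: np.ndarray) -> LoganFit:
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate Logan plot: no spread in the abscissa")
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = 1.0 if syy == 0 else float(sxy**2 / (sxx * syy))
    return LoganFit(float(slope), float(intercept), r2, n)


def logan_slope(ct: TimeActivityCurve, cp: TimeActivityCurve, t_star_min: float = 50.0) -> LoganFit:
    """Plasma-input Logan fit of one TAC; the slope is DV (mL/g)."""
    if ct.time_min.shape != cp.time_min.shape or not np.allclose(ct.time_min, cp.time_min):
        raise ValueError("tissue and input TACs must share one time grid")
    x, y, late = _logan_xy(ct.activity, cp.activity, ct.time_min, t_star_min)
    if np.any(ct.activity[late] <= 0):
        raise ValueError("tissue activity must be positive at all frames past t*")
    return _fit_line(x, y)


def logan_reference_slope(
    ct: TimeActivityCurve,
    cref: TimeActivityCurve,
    t_star_min: float = 50.0,
    k2_ref: float | None = None,
) -> LoganFit:
    """Reference-tissue Logan fit; the slope is DVR (unitless)."""
    if ct.time_min.shape != cref.time_min.shape or not np.allclose(ct.time_min, cref.time_min):
        raise ValueError("tissue and reference TACs must share one time grid")
    x, y, late = _logan_xy(ct.activity, cref.activity, ct.time_min, t_star_min, k2_ref)
    if np.any(ct.activity[late] <= 0):
        raise ValueError("tissue activity must be positive at all frames past t*")
    return _fit_line(x, y)


def _logan_image(dyn: DynamicImage, cx: np.ndarray, t_star: float, kind: str,
                 k2_ref: float | None = None,
                 slope_range: tuple[float, float] = (0.0, 20.0)) -> MetricImage:
    """Vectorized per-voxel Logan slope against a common input curve."""
    t = dyn.frames.midpoint_min
    nvox = int(np.prod(dyn.shape))
    ct = dyn.data.reshape(nvox, dyn.n_frames).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        x, y, late = _logan_xy(ct, np.broadcast_to(cx, ct.shape), t, t_star, k2_ref)

    valid = np.all(ct[:, late] > 0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = np.sum((x - xm) ** 2, axis=1)
        sxy = np.sum((x - xm) * (y - ym), axis=1)
        slope = sxy / sxx
    valid &= np.isfinite(slope) & (sxx > 0)
    valid &= (slope > slope_range[0]) & (slope < slope_range[1])
    slope = np.where(valid, slope, 0.0)
    return MetricImage(
        slope.reshape(dyn.shape), kind=kind, valid=valid.reshape(dyn.shape),
        voxel_size_mm=dyn.voxel_size_mm, affine=dyn.affine,
    )


def logan_dv_image(dyn: DynamicImage, cp: TimeActivityCurve, cfg: AnalysisConfig = AnalysisConfig()) -> MetricImage:
    """Per-voxel plasma-input Logan DV image (mL/g)."""
    if cp.time_min.shape != dyn.frames.midpoint_min.shape or not np.allclose(
        cp.time_min, dyn.frames.midpoint_min
    ):
        raise ValueError("input TAC must be sampled on the image frame grid")
    return _logan_image(dyn, cp.activity, cfg.t_star_min, "DV", slope_range=cfg.slope_range)


def logan_reference_image(
    dyn: DynamicImage, cref: TimeActivityCurve, cfg: AnalysisConfig = AnalysisConfig()
) -> MetricImage:
    """Per-voxel reference-tissue Logan DVR image."""
    if cref.time_min.shape != dyn.frames.midpoint_min.shape or not np.allclose(
        cref.time_min, dyn.frames.midpoint_min
    ):
        raise ValueError("reference TAC must be sampled on the image frame grid")
    return _logan_image(dyn, cref.activity, cfg.t_star_min, "DVR_r", cfg.k2_ref,
                        slope_range=cfg.slope_range)


def normalize_to_reference(metric: MetricImage, labels: np.ndarray, reference_label: int,
                           kind: str = "DVR_L") -> MetricImage:
    """Divide a metric image by its mean over the reference region."""
    labels = np.asarray(labels)
    if labels.shape != metric.data.shape:
        raise ValueError("label volume shape does not match metric image")
    ref_mask = (labels == reference_label) & metric.valid
    if not ref_mask.any():
        raise ValueError(f"reference region (label {reference_label}) has no valid voxels")
    ref_mean = float(metric.data[ref_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference-region mean must be positive, got {ref_mean:g}")
    out = np.where(metric.valid, metric.data / ref_mean, 0.0)
    return MetricImage(out, kind=kind, valid=metric.valid.copy(), reference_value=ref_mean,
                       voxel_size_mm=metric.voxel_size_mm, affine=metric.affine)


def static_image(dyn: DynamicImage, window_min: tuple[float, float] = (50.0, 70.0)) -> np.ndarray:
    """Frame-duration-weighted mean image over a late time window (kBq/mL)."""
    lo, hi = float(window_min[0]) * 60.0, float(window_min[1]) * 60.0
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    overlap = np.minimum(dyn.frames.end_s, hi) - np.maximum(dyn.frames.start_s, lo)
    weights = np.clip(overlap, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError(f"no frame overlaps window [{window_min[0]}, {window_min[1]}] min")
    return np.tensordot(dyn.data, weights / weights.sum(), axes=([3], [0]))


def suv_image(static: np.ndarray, subject: SubjectInfo,
              voxel_size_mm=(2.0, 2.0, 2.76), affine=None) -> MetricImage:
    """SUV = concentration (kBq/mL) / (injected dose MBq / body weight kg)."""
    scale = subject.injected_dose_mbq / subject.body_weight_kg
    static = np.asarray(static, float)
    return MetricImage(static / scale, kind="SUV", valid=static > 0,
                       voxel_size_mm=voxel_size_mm, affine=affine)


def suvr_image(suv: MetricImage, labels: np.ndarray, reference_label: int) -> MetricImage:
    """SUV ratio image, normalized by the cerebellar (reference) SUV mean."""
    return normalize_to_reference(suv, labels, reference_label, kind="SUVR")
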