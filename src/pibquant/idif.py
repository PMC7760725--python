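"""Image-derived input function (IDIF) and metabolite correction.

The arterial input is read off the dynamic image itself: the hottest
voxels of an early-phase average image inside the internal-carotid-artery
(ICA) search region form a small VOI, whose two-phase TAC (max-based
early, mean-based late) is the whole-blood IDIF.  A Hill-type
unmetabolized ("parent") fraction

    R(t) = alpha * t**beta / (t**beta + gamma)      [t in minutes]

then converts whole blood to the metabolite-corrected plasma input
Cp(t) = clip(R(t), 0, 1) * IDIF(t).

With the shipped [11C]PiB constants (alpha=1.62, beta=-0.92, gamma=0.47)
the raw R exceeds 1 at early times; since a parent fraction cannot, R is
clipped to [0, 1] and clipping events are counted for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .frames import FrameSchedule
from .images import DynamicImage

__all__ = [
    "TimeActivityCurve",
    "HillParams",
    "InputFunction",
    "VoiMask",
    "PIB_HILL",
    "early_average_image",
    "select_hottest_voxels",
    "extract_idif",
    "hill_fraction",
    "hill_fraction_raw",
    "fit_hill",
    "plasma_input",
]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity (kBq/mL) sampled at frame midpoints (minutes)."""

    time_min: np.ndarray
    activity: np.ndarray
    frame_duration_min: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        d = np.asarray(self.frame_duration_min, dtype=float)
        if not (t.size == a.size == d.size):
            raise ValueError("time, activity and duration must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("activity must be finite")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "activity", a)
        object.__setattr__(self, "frame_duration_min", d)

    @classmethod
    def from_schedule(cls, activity, frames: FrameSchedule) -> "TimeActivityCurve":
        return cls(frames.midpoint_min, np.asarray(activity, float), frames.duration_min)


@dataclass(frozen=True)
class HillParams:
    """Constants of the Hill-type unmetabolized-fraction model."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


#: Fitted [11C]PiB parent-fraction constants shipped as defaults.
PIB_HILL = HillParams(alpha=1.62, beta=-0.92, gamma=0.47)


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood IDIF and metabolite-corrected plasma input on one grid."""

    idif: TimeActivityCurve
    cp: TimeActivityCurve
    hill: HillParams
    n_clipped: int = 0  # frames where raw R(t) was clipped to 1

    def __post_init__(self) -> None:
        if self.idif.time_min.shape != self.cp.time_min.shape or not np.allclose(
            self.idif.time_min, self.cp.time_min
        ):
            raise ValueError("idif and cp must share one time grid")


@dataclass(frozen=True)
class VoiMask:
    """Voxel coordinates of the arterial VOI, in (x, y, z) index triples.

    Slices are indices along the z axis.  ``slice_counts`` maps z-slice
    index to the number of VOI voxels it holds.
    """

    voxels: np.ndarray  # (n, 3) int
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) array of indices")
        object.__setattr__(self, "voxels", v)

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_counts(self) -> dict[int, int]:
        z, counts = np.unique(self.voxels[:, 2], return_counts=True)
        return dict(zip(z.tolist(), counts.tolist()))

    @property
    def n_slices(self) -> int:
        return np.unique(self.voxels[:, 2]).size


def early_average_image(dyn: DynamicImage, window_s: tuple[float, float] = (10.0, 40.0)) -> np.ndarray:
    """Duration-weighted mean image over an early time window.

    Each frame contributes with weight equal to its overlap (in seconds)
    with ``window_s``; a fractional overlap gets a fractional weight, so
    the result is exact for constant TACs regardless of the schedule.
    """
    lo, hi = float(window_s[0]), float(window_s[1])
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    overlap = np.minimum(dyn.frames.end_s, hi) - np.maximum(dyn.frames.start_s, lo)
    weights = np.clip(overlap, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError(f"no frame overlaps window [{lo}, {hi}] s")
    return np.tensordot(dyn.data, weights / weights.sum(), axes=([3], [0]))


def select_hottest_voxels(early: np.ndarray, search_mask: np.ndarray, n: int = 30) -> VoiMask:
    """Pick the ``n`` most intense early-image voxels inside a search region.

    Ties are broken by ascending flattened (C-order) voxel index, so the
    selection is deterministic and invariant to positive affine rescaling
    of the image.
    """
    early = np.asarray(early, dtype=float)
    search_mask = np.asarray(search_mask, dtype=bool)
    if early.shape != search_mask.shape:
        raise ValueError("image and search mask shapes differ")
    flat_idx = np.flatnonzero(search_mask)
    if flat_idx.size < n:
        raise ValueError(f"search region has {flat_idx.size} voxels, fewer than n={n}")
    values = early.ravel()[flat_idx]
    # stable sort on descending value keeps ascending flat index among ties
    order = np.argsort(-values, kind="stable")[:n]
    chosen = flat_idx[order]
    coords = np.column_stack(np.unravel_index(chosen, early.shape))
    return VoiMask(coords, early.shape)


def extract_idif(
    dyn: DynamicImage,
    voi: VoiMask,
    phase_switch_s: float = 45.0,
    slices_phase1: int = 4,
) -> TimeActivityCurve:
    """Two-phase whole-blood TAC from the arterial VOI.

    Early frames (midpoint <= ``phase_switch_s``) track the bolus with a
    max-based rule that resists partial-volume dilution: the mean, over
    the ``slices_phase1`` VOI slices holding the most VOI voxels, of each
    slice's maximum VOI value.  Later frames use the max over VOI slices
    of the per-slice mean, a lower-noise statistic for the tail.
    """
    if voi.n_slices < 3:
        raise ValueError(f"VOI spans only {voi.n_slices} slices; at least 3 required")
    if slices_phase1 < 1 or slices_phase1 > voi.n_slices:
        raise ValueError("slices_phase1 must be between 1 and the number of VOI slices")

    x, y, z = voi.voxels.T
    voi_values = dyn.data[x, y, z, :]  # (n_voxels, n_frames)
    z_slices = np.unique(z)
    per_slice = [voi_values[z == zi] for zi in z_slices]

    # slices with most VOI voxels; ties resolved by ascending slice index
    counts = np.array([p.shape[0] for p in per_slice])
    order = np.argsort(-counts, kind="stable")[:slices_phase1]

    slice_max = np.stack([p.max(axis=0) for p in per_slice])  # (n_slices, n_frames)
    slice_mean = np.stack([p.mean(axis=0) for p in per_slice])
    phase1 = slice_max[order].mean(axis=0)
    phase2 = slice_mean.max(axis=0)

    early = dyn.frames.midpoint_s <= phase_switch_s
    activity = np.where(early, phase1, phase2)
    return TimeActivityCurve.from_schedule(activity, dyn.frames)


def hill_fraction_raw(hp: HillParams, t_min) -> np.ndarray:
    """Unclipped Hill fraction; the t -> 0+ limit is alpha for beta < 0,
    0 for beta > 0 and alpha/(1+gamma) for beta = 0."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = np.empty_like(t, dtype=float)
    zero = t == 0
    if hp.beta < 0:
        out[zero] = hp.alpha
    elif hp.beta > 0:
        out[zero] = 0.0
    else:
        out[zero] = hp.alpha / (1.0 + hp.gamma)
    tb = np.power(t[~zero], hp.beta)
    out[~zero] = hp.alpha * tb / (tb + hp.gamma)
    return out if out.ndim else float(out)


def hill_fraction(hp: HillParams, t_min) -> np.ndarray:
    """Parent fraction R(t), clipped to [0, 1]."""
    return np.clip(hill_fraction_raw(hp, t_min), 0.0, 1.0)


_HILL_STARTS = [
    (a0, b0, g0)
    for a0 in (0.5, 1.0, 1.6, 2.0)
    for b0 in (-1.5, -0.9, -0.3, 0.5)
    for g0 in (0.1, 0.5, 1.0, 2.0)
]


def fit_hill(times_min, fractions, starts=None) -> tuple[HillParams, float]:
    """Nonlinear least-squares fit of the Hill fraction to observed data.

    Minimizes sum((R(t_i) - f_i)**2) on the *raw* (unclipped) model, with
    a multi-start grid of initial values to avoid local minima.  Returns
    the best parameters and the residual sum of squares.  alpha and gamma
    are a weakly identified pair when the data are nearly constant (only
    alpha/(1+gamma) is then determined).
    """
    t = np.asarray(times_min, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size != f.size:
        raise ValueError("times and fractions must have equal length")
    if t.size < 4:
        raise ValueError("at least 4 samples are required to fit 3 parameters")
    if np.any(t <= 0):
        raise ValueError("times must be positive")

    def resid(p):
        a, b, g = p
        tb = np.power(t, b)
        return a * tb / (tb + g) - f

    best = None
    for a0, b0, g0 in starts or _HILL_STARTS:
        try:
            sol = least_squares(
                resid,
                x0=[a0, b0, g0],
                bounds=([1e-6, -5.0, 0.0], [10.0, 5.0, 50.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best[1]):
            best = (sol.x, rss)
    if best is None:
        raise RuntimeError(
            "Hill fit failed to converge from any initial point; "
            f"n={t.size}, t range [{t.min():g}, {t.max():g}] min"
        )
    params, rss = best
    return HillParams(*map(float, params)), rss


def plasma_input(
    idif: TimeActivityCurve,
    hp: HillParams = PIB_HILL,
    blood_to_plasma: float = 1.0,
) -> InputFunction:
    """Metabolite-corrected plasma input from the whole-blood IDIF.

    Cp(t) = clip(R(t), 0, 1) * IDIF(t) / blood_to_plasma.  The whole-
    blood-to-plasma partition ratio defaults to 1 (scanner calibration is
    assumed to absorb the scaling); it is exposed as a single scalar.
    """
    if blood_to_plasma <= 0:
        raise ValueError("blood_to_plasma must be positive")
    raw = hill_fraction_raw(hp, idif.time_min)
    r = np.clip(raw, 0.0, 1.0)
    cp = TimeActivityCurve(
        idif.time_min, r * idif.activity / blood_to_plasma, idif.frame_duration_min
    )
    return InputFunction(idif=idif, cp=cp, hill=hp, n_clipped=int(np.sum(raw > 1.0)))
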