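"""Synthetic dynamic [11C]PiB PET studies with known ground truth.

The generator produces the statistical structure the analysis assumes —
nothing more: a parametric arterial whole-blood curve sampled into a
small internal-carotid region, two-tissue-compartment (2TC) tissue
kinetics per brain region driven by the Hill-corrected plasma input, and
frame-duration-averaged voxel values with count-statistics-like Gaussian
noise (SD proportional to sqrt(activity / frame duration)).  Everything
is decay-corrected by construction, so no decay simulation is needed.

Ground truth per region is the analytic total distribution volume

    DV = (K1 / k2) * (1 + k3 / k4)        (K1/k2 when k3 = 0)

and the DVR is DV normalized to the cerebellar (reference) DV.  Cohorts
draw per-subject regional DVR from configurable group means/SDs, with
between-subject variability in delivery (K1), clearance (k4), reference
DV and the arterial curve, emulating the biological spread a real
control / early-AD contrast exhibits.

No tomograph physics is simulated: no reconstruction, attenuation,
scatter, partial volume, spillover or head motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .frames import FrameSchedule, pib_frame_schedule
from .idif import HillParams, PIB_HILL, hill_fraction
from .images import DynamicImage

__all__ = [
    "KineticParams",
    "BloodCurveParams",
    "SubjectInfo",
    "PhantomSpec",
    "PhantomStudy",
    "InputTruth",
    "REGION_LABELS",
    "CTL_DVR_TARGETS",
    "EAD_DVR_TARGETS",
    "blood_input_curve",
    "simulate_tissue_tac",
    "default_region_boxes",
    "kinetics_for_dvr",
    "default_region_kinetics",
    "build_phantom",
    "simulate_cohort",
    "frame_average",
]


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue-compartment rate constants.

    K1 (mL/min/g) is delivery, k2 (1/min) efflux, k3 (1/min) binding and
    k4 (1/min) release.  Reversible binding is assumed: k3 > 0 requires
    k4 > 0.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be nonnegative")
        if self.k3 > 0 and self.k4 <= 0:
            raise ValueError("k3 > 0 requires k4 > 0 (reversible binding)")
        if self.K1 > 0 and self.k2 <= 0:
            raise ValueError("K1 > 0 requires k2 > 0 (finite distribution volume)")

    @property
    def dv(self) -> float:
        """Total distribution volume (mL/g)."""
        if self.K1 == 0:
            return 0.0
        ratio = self.k3 / self.k4 if self.k3 > 0 else 0.0
        return (self.K1 / self.k2) * (1.0 + ratio)


@dataclass(frozen=True)
class BloodCurveParams:
    """Parametric arterial whole-blood curve: linear rise to a bolus peak
    at ``peak_time_min``, then a sum of decaying exponentials.

    The peak value is ``sum(amplitudes_kbq_ml)``; the default tail decay
    of 0.004/min keeps the late input nearly flat, sustaining the
    quasi-equilibrium the graphical methods rely on in the 50–70 min
    window.
    """

    peak_time_min: float = 0.75
    amplitudes_kbq_ml: tuple[float, ...] = (14.0, 5.0, 3.5)
    decay_per_min: tuple[float, ...] = (4.0, 0.3, 0.004)

    def __post_init__(self) -> None:
        if self.peak_time_min <= 0:
            raise ValueError("peak time must be positive")
        if len(self.amplitudes_kbq_ml) != len(self.decay_per_min):
            raise ValueError("amplitudes and decay rates must pair up")
        if any(a < 0 for a in self.amplitudes_kbq_ml):
            raise ValueError("amplitudes must be nonnegative")
        if any(l < 0 for l in self.decay_per_min):
            raise ValueError("decay rates must be nonnegative")


@dataclass(frozen=True)
class SubjectInfo:
    """Injected dose (MBq) and body weight (kg), the SUV denominators."""

    injected_dose_mbq: float = 725.0
    body_weight_kg: float = 60.0

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0 or self.body_weight_kg <= 0:
            raise ValueError("dose and weight must be positive")


#: Fixed integer labels of the phantom parcellation.
REGION_LABELS: dict[str, int] = {
    "cerebellum": 1,
    "frontal_l": 2,
    "frontal_r": 3,
    "temporal_l": 4,
    "temporal_r": 5,
    "parietal_l": 6,
    "parietal_r": 7,
    "occipital_l": 8,
    "occipital_r": 9,
    "pcc": 10,
    "white_matter": 11,
    "ica": 12,
}

CORTICAL_REGIONS = (
    "frontal_l", "frontal_r", "temporal_l", "temporal_r",
    "parietal_l", "parietal_r", "occipital_l", "occipital_r",
)

# Group regional DVR targets (mean, SD) for cohort simulation: a
# control-like and an early-AD-like contrast, plasma-input Logan scale.
CTL_DVR_TARGETS: dict[str, tuple[float, float]] = {
    "frontal_l": (1.22, 0.14), "frontal_r": (1.24, 0.13),
    "temporal_l": (1.13, 0.06), "temporal_r": (1.13, 0.06),
    "parietal_l": (1.18, 0.12), "parietal_r": (1.19, 0.13),
    "occipital_l": (1.16, 0.07), "occipital_r": (1.16, 0.08),
    "pcc": (1.30, 0.16), "white_matter": (1.45, 0.10),
}
EAD_DVR_TARGETS: dict[str, tuple[float, float]] = {
    "frontal_l": (2.14, 0.32), "frontal_r": (2.17, 0.38),
    "temporal_l": (1.72, 0.22), "temporal_r": (1.74, 0.23),
    "parietal_l": (2.11, 0.31), "parietal_r": (2.19, 0.38),
    "occipital_l": (1.73, 0.25), "occipital_r": (1.78, 0.24),
    "pcc": (2.43, 0.42), "white_matter": (1.45, 0.10),
}


def blood_input_curve(params: BloodCurveParams, t_min) -> np.ndarray:
    """Whole-blood activity (kBq/mL) at times ``t_min`` (minutes).

    Zero at t = 0, linear rise to a single early peak, then monotone
    multi-exponential decline (for nonnegative decay rates).
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    peak = float(sum(params.amplitudes_kbq_ml))
    rise = peak * t / params.peak_time_min
    tail = np.zeros_like(t)
    dt = t - params.peak_time_min
    for a, lam in zip(params.amplitudes_kbq_ml, params.decay_per_min):
        tail += a * np.exp(-lam * np.clip(dt, 0.0, None))
    out = np.where(t < params.peak_time_min, rise, tail)
    return out if out.ndim else float(out)


def _expconv(a: float, u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(-a t) convolved with a piecewise-linear input u(t), exactly.

    Uses the closed-form update over each linear segment; on a uniform
    grid the first-order recurrence is evaluated with an IIR filter.
    """
    dt = np.diff(t)
    if a == 0.0:
        # kernel == 1: running trapezoid integral
        seg = 0.5 * (u[1:] + u[:-1]) * dt
        return np.concatenate([[0.0], np.cumsum(seg)])
    uniform = np.allclose(dt, dt[0])
    if uniform:
        h = dt[0]
        e = np.exp(-a * h)
        w1 = -np.expm1(-a * h) / a  # int_0^h exp(-a(h-s)) ds
        ws = (h - w1) / a           # int_0^h exp(-a(h-s)) s/h ds * h ... see below
        # contribution of segment with endpoints u0, u1:
        #   u0 * w1 + (u1 - u0)/h * (h*w1 - (1 - e - a*h*e)/a**2)
        w_slope = (h * w1 - (1.0 - e - a * h * e) / a**2) / h
        g = u[:-1] * (w1 - w_slope) + u[1:] * w_slope
        y = np.empty_like(u, dtype=float)
        y[0] = 0.0
        y[1:] = lfilter([1.0], [1.0, -e], g)
        return y
    y = np.zeros_like(u, dtype=float)
    for i, h in enumerate(dt):
        e = np.exp(-a * h)
        w1 = -np.expm1(-a * h) / a
        w_slope = (h * w1 - (1.0 - e - a * h * e) / a**2) / h
        y[i + 1] = y[i] * e + u[i] * (w1 - w_slope) + u[i + 1] * w_slope
    return y


def simulate_tissue_tac(kp: KineticParams, cp, t_grid_min) -> np.ndarray:
    """Tissue TAC of a 2TC system driven by plasma input ``cp``.

    Solves Ct = h (*) Cp with the bi-exponential impulse response

        h(t) = K1/(a2-a1) * [(k3+k4-a1) e^(-a1 t) + (a2-k3-k4) e^(-a2 t)]

    where a1, a2 are the eigen-rates of (k2, k3, k4); for k3 = 0 this
    reduces to the one-tissue response K1 exp(-k2 t).  The convolution is
    exact for a piecewise-linear Cp on ``t_grid_min``.
    """
    t = np.asarray(t_grid_min, dtype=float)
    u = np.asarray(cp, dtype=float)
    if t.size != u.size:
        raise ValueError("cp and t_grid must have equal length")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing from 0")
    if kp.K1 == 0:
        return np.zeros_like(t)
    if kp.k3 == 0:
        return kp.K1 * _expconv(kp.k2, u, t)
    s = kp.k2 + kp.k3 + kp.k4
    disc = max(s * s - 4.0 * kp.k2 * kp.k4, 0.0)
    root = np.sqrt(disc)
    a1, a2 = (s - root) / 2.0, (s + root) / 2.0
    if a2 - a1 < 1e-10 * max(a2, 1.0):  # coincident eigen-rates: nudge apart
        a2 = a1 + 1e-8
    c1 = kp.K1 * (kp.k3 + kp.k4 - a1) / (a2 - a1)
    c2 = kp.K1 * (a2 - kp.k3 - kp.k4) / (a2 - a1)
    return c1 * _expconv(a1, u, t) + c2 * _expconv(a2, u, t)


def frame_average(curve_fine: np.ndarray, t_fine_min: np.ndarray, frames: FrameSchedule) -> np.ndarray:
    """Frame-duration averages of a densely sampled curve.

    Frame boundaries must fall on grid points (the phantom's fine step
    divides every frame boundary of the default schedule).
    """
    t_s = t_fine_min * 60.0
    lo = np.searchsorted(t_s, frames.start_s - 1e-9)
    hi = np.searchsorted(t_s, frames.end_s + 1e-9) - 1
    out = np.empty(frames.n_frames)
    for k in range(frames.n_frames):
        sl = slice(lo[k], hi[k] + 1)
        out[k] = np.trapezoid(curve_fine[sl], t_fine_min[sl]) / frames.duration_min[k]
    return out


def default_region_boxes(shape: tuple[int, int, int]) -> dict[str, tuple[slice, slice, slice]]:
    """Disjoint box geometry for the named regions, scaled to ``shape``.

    A crude but sufficient head layout: cerebellum low, white-matter
    core, eight cortical lobe blocks (left/right x anterior/posterior x
    upper/lower), a posterior-cingulate block and an anterior ICA column
    spanning >= 5 slices.  Fractions chosen so every region is nonempty
    down to a 16-voxel grid.
    """
    nx, ny, nz = shape

    def box(fx, fy, fz):
        (x0, x1), (y0, y1), (z0, z1) = fx, fy, fz
        return (
            slice(max(int(round(x0 * nx)), 0), max(int(round(x1 * nx)), 1)),
            slice(max(int(round(y0 * ny)), 0), max(int(round(y1 * ny)), 1)),
            slice(max(int(round(z0 * nz)), 0), max(int(round(z1 * nz)), 1)),
        )

    lx, rx = (0.06, 0.28), (0.72, 0.94)
    ant, post = (0.06, 0.45), (0.55, 0.94)
    upper, lower = (0.56, 0.88), (0.38, 0.53)
    boxes = {
        "cerebellum": box((0.25, 0.75), (0.25, 0.75), (0.06, 0.25)),
        "frontal_l": box(lx, ant, upper),
        "frontal_r": box(rx, ant, upper),
        "parietal_l": box(lx, post, upper),
        "parietal_r": box(rx, post, upper),
        "temporal_l": box(lx, ant, lower),
        "temporal_r": box(rx, ant, lower),
        "occipital_l": box(lx, post, lower),
        "occipital_r": box(rx, post, lower),
        "pcc": box((0.40, 0.60), (0.70, 0.90), (0.50, 0.66)),
        "white_matter": box((0.33, 0.66), (0.30, 0.66), (0.44, 0.80)),
        "ica": box((0.44, 0.56), (0.06, 0.20), (0.06, 0.31)),
    }
    return boxes


def kinetics_for_dvr(
    dvr: float,
    reference_dv: float = 1.5,
    K1: float = 0.45,
    k4: float = 0.3,
) -> KineticParams:
    """Rate constants yielding a target DVR against a reference DV.

    For DVR >= 1 the delivery ratio K1/k2 is pinned to the reference DV
    and binding supplies the excess (k3/k4 = DVR - 1); for DVR < 1 there
    is no specific binding and k2 is raised instead.
    """
    if dvr <= 0:
        raise ValueError("DVR must be positive")
    if dvr >= 1.0:
        return KineticParams(K1=K1, k2=K1 / reference_dv, k3=k4 * (dvr - 1.0), k4=k4)
    return KineticParams(K1=K1, k2=K1 / (dvr * reference_dv), k3=0.0, k4=0.0)


def default_region_kinetics(
    dvr_by_region: dict[str, float] | None = None,
    reference_dv: float = 1.5,
    K1: float = 0.45,
    k4: float = 0.3,
) -> dict[str, KineticParams]:
    """Per-region kinetics from regional DVR targets.

    The cerebellum is always the one-tissue reference with DV =
    ``reference_dv``; unlisted regions default to control-like means.
    """
    targets = {name: mean for name, (mean, _) in CTL_DVR_TARGETS.items()}
    if dvr_by_region:
        targets.update(dvr_by_region)
    kin = {"cerebellum": KineticParams(K1=K1, k2=K1 / reference_dv)}
    for name in list(CORTICAL_REGIONS) + ["pcc", "white_matter"]:
        kin[name] = kinetics_for_dvr(targets[name], reference_dv, K1, k4)
    return kin


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic study; the seed fixes the output."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    frames: FrameSchedule = field(default_factory=pib_frame_schedule)
    kinetics: dict[str, KineticParams] = field(default_factory=default_region_kinetics)
    blood: BloodCurveParams = field(default_factory=BloodCurveParams)
    hill: HillParams = PIB_HILL
    noise_scale: float = 0.2
    ica_gradient: float = 0.0  # fractional intensity drop across the ICA column
    group: str = "CTL"
    seed: int = 0
    subject: SubjectInfo = field(default_factory=SubjectInfo)
    fine_dt_s: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise scale must be nonnegative")
        if not 0.0 <= self.ica_gradient < 1.0:
            raise ValueError("ica_gradient must lie in [0, 1)")


@dataclass(frozen=True)
class InputTruth:
    """Ground-truth input curves on the fine simulation grid."""

    t_min: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray


@dataclass
class PhantomStudy:
    """One simulated study: image + labels + ground truth."""

    spec: PhantomSpec
    dynamic: DynamicImage | None
    labels: np.ndarray | None
    label_map: dict[str, int]
    truth: pd.DataFrame  # region, K1, k2, k3, k4, DV, DVR
    input_truth: InputTruth
    subject_id: str = "sub-000"
    group: str = "CTL"

    @property
    def subject(self) -> SubjectInfo:
        return self.spec.subject


def _paint_regions(labels: np.ndarray, boxes: dict) -> None:
    for name, sl in boxes.items():
        region = labels[sl]
        if region.size == 0:
            raise ValueError(f"region '{name}' is empty at this grid size")
        if np.any(region != 0):
            raise ValueError(f"region '{name}' overlaps a previously placed region")
        labels[sl] = REGION_LABELS[name]


def build_phantom(spec: PhantomSpec, render: bool = True) -> PhantomStudy:
    """Simulate one dynamic study from its spec.

    Voxel values are frame-duration averages of the analytic regional
    TAC; ICA voxels carry the whole-blood curve (times an optional
    linearly decaying intensity profile along the column); zero-mean
    Gaussian noise with SD = noise_scale * sqrt(TAC / frame duration) is
    added to every nonzero-TAC voxel.  Bit-identical output for a given
    seed.  With ``render=False`` only ground truth is produced.
    """
    frames = spec.frames
    t_fine = np.arange(0.0, frames.total_duration_s + spec.fine_dt_s / 2, spec.fine_dt_s) / 60.0
    wb_fine = blood_input_curve(spec.blood, t_fine)
    cp_fine = hill_fraction(spec.hill, t_fine) * wb_fine
    input_truth = InputTruth(t_fine, wb_fine, cp_fine)

    if "cerebellum" not in spec.kinetics:
        raise ValueError("kinetics must include the cerebellum reference region")
    ref_dv = spec.kinetics["cerebellum"].dv
    rows = []
    region_tacs: dict[str, np.ndarray] = {}
    for name, kp in spec.kinetics.items():
        tac_fine = simulate_tissue_tac(kp, cp_fine, t_fine)
        region_tacs[name] = frame_average(tac_fine, t_fine, frames)
        rows.append({
            "region": name, "K1": kp.K1, "k2": kp.k2, "k3": kp.k3, "k4": kp.k4,
            "DV": kp.dv, "DVR": kp.dv / ref_dv,
        })
    truth = pd.DataFrame(rows)

    labels = None
    dyn = None
    if render:
        boxes = default_region_boxes(spec.shape)
        labels = np.zeros(spec.shape, dtype=np.int16)
        _paint_regions(labels, boxes)

        wb_frames = frame_average(wb_fine, t_fine, frames)
        data = np.zeros(spec.shape + (frames.n_frames,), dtype=np.float32)
        rng = np.random.default_rng(spec.seed)
        dur = frames.duration_min
        for name, label in REGION_LABELS.items():
            mask = labels == label
            nvox = int(mask.sum())
            if name == "ica":
                mean_tac = wb_frames
                if spec.ica_gradient > 0:
                    zs = np.argwhere(mask)[:, 2].astype(float)
                    span = max(zs.max() - zs.min(), 1.0)
                    profile = 1.0 - spec.ica_gradient * (zs - zs.min()) / span
                    voxel_tacs = profile[:, None] * mean_tac[None, :]
                else:
                    voxel_tacs = np.broadcast_to(mean_tac, (nvox, frames.n_frames)).copy()
            else:
                mean_tac = region_tacs[name]
                voxel_tacs = np.broadcast_to(mean_tac, (nvox, frames.n_frames)).copy()
            if spec.noise_scale > 0:
                sd = spec.noise_scale * np.sqrt(np.clip(voxel_tacs, 0.0, None) / dur)
                voxel_tacs = voxel_tacs + rng.normal(0.0, 1.0, voxel_tacs.shape) * sd
            data[mask] = voxel_tacs.astype(np.float32)
        dyn = DynamicImage(data, frames, voxel_size_mm=spec.voxel_size_mm)

    return PhantomStudy(
        spec=spec, dynamic=dyn, labels=labels, label_map=dict(REGION_LABELS),
        truth=truth, input_truth=input_truth, group=spec.group,
    )


def simulate_cohort(
    n_ctl: int,
    n_ad: int,
    ctl_targets: dict[str, tuple[float, float]] | None = None,
    ad_targets: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (32, 32, 32),
    noise_scale: float = 0.2,
    render: bool = True,
    k1_cv: float = 0.15,
    k4_cv: float = 0.10,
    reference_dv_cv: float = 0.10,
    blood_amp_cv: float = 0.15,
) -> list[PhantomStudy]:
    """Simulate a two-group cohort with per-subject kinetic variability.

    Regional ground-truth DVR is drawn per subject from the configured
    group (mean, SD) targets; delivery K1, release k4, reference DV and
    the arterial amplitude/peak time vary log-normally between subjects,
    so ratio metrics differ across subjects the way real cohorts do.
    Per-subject seeds are derived deterministically from ``seed``.
    """
    if n_ctl < 1 or n_ad < 1:
        raise ValueError("each group needs at least one subject")
    for targets in (ctl_targets, ad_targets):
        if targets and any(sd < 0 for _, sd in targets.values()):
            raise ValueError("group SDs must be nonnegative")
    ctl = dict(CTL_DVR_TARGETS); ctl.update(ctl_targets or {})
    ead = dict(EAD_DVR_TARGETS); ead.update(ad_targets or {})

    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_ctl + n_ad)
    studies = []
    groups = ["CTL"] * n_ctl + ["eAD"] * n_ad
    for i, (group, sub_seed) in enumerate(zip(groups, sub_seeds)):
        rng = np.random.default_rng(sub_seed)
        targets = ctl if group == "CTL" else ead
        K1 = 0.45 * rng.lognormal(0.0, k1_cv)
        k4 = 0.30 * rng.lognormal(0.0, k4_cv)
        ref_dv = 1.5 * rng.lognormal(0.0, reference_dv_cv)
        amp_scale = rng.lognormal(0.0, blood_amp_cv)
        peak_t = float(np.clip(rng.normal(0.75, 0.10), 0.4, 1.2))
        blood = BloodCurveParams(
            peak_time_min=peak_t,
            amplitudes_kbq_ml=tuple(a * amp_scale for a in BloodCurveParams.amplitudes_kbq_ml),
        )
        kin = {"cerebellum": KineticParams(K1=K1, k2=K1 / ref_dv)}
        for name in list(CORTICAL_REGIONS) + ["pcc", "white_matter"]:
            mean, sd = targets[name]
            dvr = float(np.clip(rng.normal(mean, sd), 0.2, None)) if sd > 0 else mean
            kin[name] = kinetics_for_dvr(dvr, ref_dv, K1, k4)
        subject = SubjectInfo(
            injected_dose_mbq=float(rng.uniform(700.0, 750.0)),
            body_weight_kg=float(np.clip(rng.normal(60.0, 8.0), 40.0, 95.0)),
        )
        spec = PhantomSpec(
            shape=shape, kinetics=kin, blood=blood, noise_scale=noise_scale,
            group=group, seed=int(sub_seed), subject=subject,
        )
        study = build_phantom(spec, render=render)
        study.subject_id = f"sub-{i:03d}"
        studies.append(study)
    return studies
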