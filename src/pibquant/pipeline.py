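"""End-to-end orchestration: IDIF -> Cp -> DV/DVR/SUVR -> regional table.

`quantify_study` runs the whole chain on an in-memory study (simulated
or loaded); `run_pipeline` is its disk-based counterpart operating on a
`StudyBundle` of file paths and writing every output volume, the
regional table and a QC log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .graphical import (
    AnalysisConfig,
    logan_dv_image,
    logan_reference_image,
    normalize_to_reference,
    static_image,
    suv_image,
    suvr_image,
)
from .idif import (
    PIB_HILL,
    HillParams,
    TimeActivityCurve,
    early_average_image,
    extract_idif,
    plasma_input,
    select_hottest_voxels,
)
from .images import DynamicImage
from .phantom import REGION_LABELS, SubjectInfo
from .stats import regional_means

logger = logging.getLogger("pibquant")

__all__ = ["IdifConfig", "StudyBundle", "StudyResult", "quantify_study", "run_pipeline"]


@dataclass(frozen=True)
class IdifConfig:
    """Tunables of the input-function stage."""

    ica_label: int = REGION_LABELS["ica"]
    n_voxels: int = 30
    early_window_s: tuple[float, float] = (10.0, 40.0)
    phase_switch_s: float = 45.0
    slices_phase1: int = 4
    hill: HillParams = PIB_HILL
    blood_to_plasma: float = 1.0


@dataclass
class StudyBundle:
    """File-system description of one study to analyze."""

    dynamic_path: Path
    frames_path: Path
    labels_path: Path
    out_dir: Path
    subject: SubjectInfo | None = None
    subject_id: str = "sub-000"
    group: str = "CTL"
    idif: IdifConfig = field(default_factory=IdifConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    reference_label: int = REGION_LABELS["cerebellum"]
    region_map: dict[str, int] = field(default_factory=lambda: dict(REGION_LABELS))


@dataclass
class StudyResult:
    input_function: object
    metrics: dict[str, object]  # kind -> MetricImage
    regional: pd.DataFrame
    qc: dict


def quantify_study(
    dyn: DynamicImage,
    labels: np.ndarray,
    subject: SubjectInfo | None = None,
    subject_id: str = "sub-000",
    group: str = "CTL",
    idif_cfg: IdifConfig = IdifConfig(),
    cfg: AnalysisConfig = AnalysisConfig(),
    reference_label: int = REGION_LABELS["cerebellum"],
    region_map: dict[str, int] | None = None,
) -> StudyResult:
    """Run IDIF extraction, Logan analyses and SUVR on one study.

    SUV/SUVR are computed only when ``subject`` (dose and weight) is
    given; the regional table then holds one row per (region, metric).
    """
    labels = np.asarray(labels)
    if labels.shape != dyn.shape:
        raise ValueError(f"label grid {labels.shape} does not match image grid {dyn.shape}")
    region_map = region_map or {k: v for k, v in REGION_LABELS.items() if k != "ica"}

    # --- input stage ---------------------------------------------------
    early = early_average_image(dyn, idif_cfg.early_window_s)
    voi = select_hottest_voxels(early, labels == idif_cfg.ica_label, idif_cfg.n_voxels)
    idif_tac = extract_idif(dyn, voi, idif_cfg.phase_switch_s, idif_cfg.slices_phase1)
    inp = plasma_input(idif_tac, idif_cfg.hill, idif_cfg.blood_to_plasma)
    if inp.n_clipped:
        logger.info("parent fraction clipped to 1 in %d early frame(s)", inp.n_clipped)

    # --- graphical stage ----------------------------------------------
    dv = logan_dv_image(dyn, inp.cp, cfg)
    dvr_l = normalize_to_reference(dv, labels, reference_label, kind="DVR_L")
    cref = TimeActivityCurve.from_schedule(dyn.region_tac(labels, reference_label), dyn.frames)
    dvr_r = logan_reference_image(dyn, cref, cfg)
    metrics = {"DV": dv, "DVR_L": dvr_l, "DVR_r": dvr_r}
    if subject is not None:
        static = static_image(dyn, cfg.static_window_min)
        suv = suv_image(static, subject, voxel_size_mm=dyn.voxel_size_mm, affine=dyn.affine)
        metrics["SUVR"] = suvr_image(suv, labels, reference_label)

    # --- regional summaries ---------------------------------------------
    tables = [
        regional_means(metrics[kind], labels, region_map, subject=subject_id, group=group)
        for kind in ("DVR_L", "DVR_r", *(["SUVR"] if "SUVR" in metrics else []))
    ]
    regional = pd.concat(tables, ignore_index=True)

    qc = {
        "voi_voxels": voi.n_voxels,
        "voi_slices": voi.n_slices,
        "hill_clipped_frames": inp.n_clipped,
        "reference_dv_mean": dvr_l.reference_value,
        "invalid_voxels": {kind: m.n_invalid for kind, m in metrics.items()},
    }
    return StudyResult(input_function=inp, metrics=metrics, regional=regional, qc=qc)


def run_pipeline(bundle: StudyBundle) -> dict[str, Path]:
    """Disk-based pipeline: read the bundle, analyze, write everything.

    Outputs (under ``bundle.out_dir``): input_function.csv, voi_mask.nii,
    one NIfTI per metric, regional.csv and qc.json.  Deterministic given
    identical inputs.
    """
    dyn = pio.read_dynamic(bundle.dynamic_path, bundle.frames_path)
    labels, label_map = pio.read_labels(bundle.labels_path, grid_shape=dyn.shape)
    region_map = {k: v for k, v in (label_map or bundle.region_map).items() if k != "ica"}

    result = quantify_study(
        dyn, labels,
        subject=bundle.subject, subject_id=bundle.subject_id, group=bundle.group,
        idif_cfg=bundle.idif, cfg=bundle.analysis,
        reference_label=bundle.reference_label, region_map=region_map,
    )

    out = Path(bundle.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    early = early_average_image(dyn, bundle.idif.early_window_s)
    voi = select_hottest_voxels(early, labels == bundle.idif.ica_label, bundle.idif.n_voxels)
    paths["voi_mask"] = out / "voi_mask.nii"
    pio.write_voi_mask(voi, paths["voi_mask"], affine=dyn.affine)
    paths["input_function"] = out / "input_function.csv"
    pio.write_input_function(result.input_function, paths["input_function"])
    for kind, metric in result.metrics.items():
        paths[kind] = out / f"{kind.lower()}.nii"
        pio.write_metric(metric, paths[kind])
    paths["regional"] = out / "regional.csv"
    result.regional.to_csv(paths["regional"], index=False)
    paths["qc"] = out / "qc.json"
    paths["qc"].write_text(json.dumps(result.qc, indent=1, sort_keys=True))
    return paths
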