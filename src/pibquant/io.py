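"""Readers and writers: NIfTI-1 volumes, frame-schedule JSON, TAC CSVs.

Conventions: frame files store seconds, TAC CSVs store minutes; volumes
are written uncompressed ``.nii`` by default so repeated runs are
byte-identical.  Activity units are kBq/mL, decay-corrected to scan
start.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameSchedule
from .idif import HillParams, InputFunction, TimeActivityCurve, VoiMask, hill_fraction
from .images import DynamicImage, MetricImage
from .phantom import PhantomStudy

__all__ = [
    "read_dynamic", "write_dynamic", "read_labels", "write_labels",
    "write_metric", "read_metric", "write_input_function", "read_input_function",
    "write_voi_mask", "write_phantom_study",
]


def write_dynamic(dyn: DynamicImage, image_path: str | Path, frames_path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(dyn.data, dtype=np.float32), dyn.affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(image_path))
    dyn.frames.to_json(frames_path)


def read_dynamic(image_path: str | Path, frames_path: str | Path) -> DynamicImage:
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D dynamic volume, got {data.ndim}-D")
    frames = FrameSchedule.from_json(frames_path)
    if data.shape[3] != frames.n_frames:
        raise ValueError(
            f"frame count mismatch: {image_path} has {data.shape[3]} frames but "
            f"{frames_path} lists {frames.n_frames}"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(data, frames, voxel_size_mm=tuple(float(z) for z in zooms),
                        affine=np.asarray(img.affine))


def write_labels(labels: np.ndarray, label_map: dict[str, int], path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))
    Path(path).with_suffix("").with_suffix(".labels.json").write_text(
        json.dumps(label_map, indent=1)
    )


def read_labels(path: str | Path, grid_shape: tuple[int, int, int] | None = None):
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int16)
    if grid_shape is not None and labels.shape != tuple(grid_shape):
        raise ValueError(
            f"label grid {labels.shape} does not match image grid {tuple(grid_shape)}"
        )
    map_path = Path(path).with_suffix("").with_suffix(".labels.json")
    label_map = json.loads(map_path.read_text()) if map_path.exists() else None
    return labels, label_map


def write_metric(metric: MetricImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(metric.data.astype(np.float32), metric.affine), str(path))


def read_metric(path: str | Path, kind: str) -> MetricImage:
    img = nib.load(str(path))
    return MetricImage(np.asanyarray(img.dataobj).astype(float), kind=kind,
                       affine=np.asarray(img.affine))


def write_input_function(inp: InputFunction, path: str | Path) -> None:
    pd.DataFrame({
        "time_min": inp.idif.time_min,
        "idif_kBq_per_mL": inp.idif.activity,
        "R": hill_fraction(inp.hill, inp.idif.time_min),
        "cp_kBq_per_mL": inp.cp.activity,
        "frame_duration_min": inp.idif.frame_duration_min,
    }).to_csv(path, index=False)


def read_input_function(path: str | Path, hill: HillParams) -> InputFunction:
    df = pd.read_csv(path)
    t = df["time_min"].to_numpy()
    dur = df["frame_duration_min"].to_numpy()
    idif = TimeActivityCurve(t, df["idif_kBq_per_mL"].to_numpy(), dur)
    cp = TimeActivityCurve(t, df["cp_kBq_per_mL"].to_numpy(), dur)
    return InputFunction(idif=idif, cp=cp, hill=hill)


def write_voi_mask(voi: VoiMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    vol = np.zeros(voi.source_shape, dtype=np.int16)
    x, y, z = voi.voxels.T
    vol[x, y, z] = 1
    nib.save(nib.Nifti1Image(vol, np.eye(4) if affine is None else affine), str(path))


def write_phantom_study(study: PhantomStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write one simulated study: dynamic NIfTI + frames JSON + labels +
    ground-truth CSV + subject CSV.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if study.dynamic is None:
        raise ValueError("study was generated without rendering; nothing to write")
    paths = {
        "dynamic": out / "dynamic.nii",
        "frames": out / "frames.json",
        "labels": out / "labels.nii",
        "truth": out / "ground_truth.csv",
        "subject": out / "subject.csv",
    }
    write_dynamic(study.dynamic, paths["dynamic"], paths["frames"])
    write_labels(study.labels, study.label_map, paths["labels"], affine=study.dynamic.affine)
    study.truth.to_csv(paths["truth"], index=False)
    pd.DataFrame([{
        "id": study.subject_id, "group": study.group,
        "dose_MBq": study.subject.injected_dose_mbq,
        "weight_kg": study.subject.body_weight_kg,
        "seed": study.spec.seed,
    }]).to_csv(paths["subject"], index=False)
    return paths
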