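"""In-memory containers for dynamic and parametric PET volumes.

Conventions
-----------
* Volumes are numpy arrays in ``(x, y, z)`` order; dynamic data add a
  trailing time axis ``(x, y, z, frame)``.  "Slice" always means an index
  along the last spatial axis (``z``).
* Activity concentrations are kBq/mL, decay-corrected to scan start.
* All voxel coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSchedule

__all__ = ["DynamicImage", "MetricImage"]


@dataclass
class DynamicImage:
    """A 4-D dynamic PET volume plus its frame timing and geometry."""

    data: np.ndarray  # (nx, ny, nz, n_frames), kBq/mL
    frames: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.76)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"dynamic data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != self.frames.n_frames:
            raise ValueError(
                f"frame count mismatch: image has {self.data.shape[3]} frames, "
                f"schedule has {self.frames.n_frames}"
            )
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def region_tac(self, labels: np.ndarray, label: int) -> np.ndarray:
        """Mean TAC over all voxels carrying ``label`` (kBq/mL per frame)."""
        labels = np.asarray(labels)
        if labels.shape != self.shape:
            raise ValueError(
                f"label volume shape {labels.shape} does not match image grid {self.shape}"
            )
        mask = labels == label
        if not mask.any():
            raise ValueError(f"label {label} has no voxels")
        return self.data[mask].mean(axis=0)


@dataclass
class MetricImage:
    """A 3-D parametric map (DV, DVR_L, DVR_r, SUV or SUVR).

    ``valid`` marks voxels where the underlying fit or ratio succeeded;
    invalid voxels carry 0.  ``reference_value`` records the reference
    (cerebellar) mean used for ratio metrics.
    """

    data: np.ndarray
    kind: str
    valid: np.ndarray | None = None
    reference_value: float | None = None
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.76)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("metric data must be 3-D")
        if self.valid is None:
            self.valid = np.isfinite(self.data)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("validity mask shape does not match data")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())
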