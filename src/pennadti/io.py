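"""Readers/writers for the on-disk artifacts and the shared coordinate conventions.

Conventions used throughout the package:

* Voxel indices are 0-based ``(i, j, k)``; the 4th axis of a diffusion stack
  indexes volumes.
* World coordinates are millimetres, obtained via the NIfTI affine.  All
  geometry (angles, streamline lengths) is computed in the world frame.
* Gradient directions (``bvecs``) are interpreted as unit vectors in the world
  frame, so tensor eigenvectors come out in the world frame directly.
* Angles are reported in degrees.

File formats: NIfTI-1 for volumes and label maps, FSL-style ``.bval``/``.bvec``
text for gradient tables, a small JSON schema for tendon annotations (no
standard exists for in-plane polylines), CSV for ratings tables, and TCK for
streamlines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientTable",
    "DWIStack",
    "TendonAnnotation",
    "ROILabelMap",
    "load_dwi",
    "save_dwi",
    "load_tendon",
    "save_tendon",
    "load_roi_map",
    "save_roi_map",
    "load_ratings",
    "save_ratings",
    "validate_ratings",
    "write_streamlines",
    "read_streamlines",
]

#: b-values at or below this (s/mm^2) count as unweighted reference volumes.
B0_THRESHOLD = 10.0

#: |norm - 1| tolerance within which a diffusion direction is re-normalized.
BVEC_NORM_TOL = 1e-3


@dataclass(frozen=True)
class GradientTable:
    """Acquisition geometry: per-volume b-value and unit gradient direction.

    ``bvals`` has shape ``(n,)`` in s/mm^2; ``bvecs`` has shape ``(n, 3)``.
    Directions of weighted volumes are unit vectors; b=0 rows may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"gradient table length mismatch: {bvals.shape[0]} b-values "
                f"vs {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-values")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > B0_THRESHOLD
        off = np.abs(norms[weighted] - 1.0)
        if np.any(off > BVEC_NORM_TOL):
            i = int(np.flatnonzero(weighted)[np.argmax(off)])
            raise ValueError(
                f"gradient direction {i} has norm {norms[i]:.6f}, "
                f"beyond the {BVEC_NORM_TOL} re-normalization tolerance"
            )
        bvecs = bvecs.copy()
        bvecs[weighted] /= norms[weighted, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b0_mask)


@dataclass
class DWIStack:
    """A 4D diffusion-weighted volume with its voxel-to-world affine.

    ``data`` is ``(i, j, k, volume)`` with non-negative intensities;
    ``slice_axis`` is the through-plane voxel axis (default 2, the
    slice-select direction of an axial-oblique acquisition).
    """

    data: np.ndarray
    affine: np.ndarray
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D stack, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, dtype=float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def in_plane_axes(self) -> tuple[int, int]:
        """The two voxel axes spanning the imaging plane, in ascending order."""
        return tuple(a for a in (0, 1, 2) if a != self.slice_axis)  # type: ignore[return-value]

    def plane_normal(self) -> np.ndarray:
        """Unit normal of the imaging plane in the world frame."""
        u, v = self.in_plane_axes()
        n = np.cross(self.affine[:3, u], self.affine[:3, v])
        return n / np.linalg.norm(n)


@dataclass
class TendonAnnotation:
    """An ordered in-plane polyline marking the intramuscular tendon.

    ``vertices`` are 2D voxel-unit points on slice ``slice_index`` (coordinates
    along the two in-plane axes, ascending axis order).  ``direction`` is the
    derived unit tendon vector in the world frame, lying in the slice plane.
    """

    slice_index: int
    vertices: np.ndarray
    slice_axis: int = 2
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (m, 2)")
        distinct = np.unique(self.vertices, axis=0)
        if distinct.shape[0] < 2:
            raise ValueError("tendon annotation needs at least 2 distinct vertices")


@dataclass
class ROILabelMap:
    """Integer label volume aligned to a DWI stack (0 = background)."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("ROI labels must be integers")
            self.labels = rounded.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("ROI label map must be 3D")
        if self.labels.min() < 0:
            raise ValueError("ROI labels must be non-negative")


# ---------------------------------------------------------------------------
# diffusion volumes + gradient tables


def _read_fsl_table(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2:
        raise ValueError(f"malformed bvec file {bvec_path}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is 3 rows of x/y/z components
        bvecs = bvecs.T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def load_dwi(volume_path, bval_path, bvec_path, slice_axis: int = 2):
    """Load a 4D NIfTI and its FSL-style gradient table as a validated pair.

    Negative intensities (interpolation ringing from upstream tools) are
    clamped to zero.  Raises if the table length does not match the number of
    volumes or a weighted direction is non-unit beyond tolerance.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 4D volume, got {data.ndim}D")
    table = _read_fsl_table(bval_path, bvec_path)
    if len(table) != data.shape[3]:
        raise ValueError(
            f"gradient table has {len(table)} entries but the volume has "
            f"{data.shape[3]} frames"
        )
    stack = DWIStack(data=np.clip(data, 0.0, None), affine=img.affine,
                     slice_axis=slice_axis)
    return stack, table


def save_dwi(stack: DWIStack, table: GradientTable, volume_path, bval_path,
             bvec_path) -> None:
    nib.save(nib.Nifti1Image(stack.data.astype(np.float32), stack.affine),
             str(volume_path))
    np.savetxt(bval_path, table.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, table.bvecs.T, fmt="%.10f")


# ---------------------------------------------------------------------------
# tendon annotations

def save_tendon(annotation: TendonAnnotation, path) -> None:
    payload = {
        "format": "pennadti-tendon-annotation",
        "version": 1,
        "slice_axis": int(annotation.slice_axis),
        "slice_index": int(annotation.slice_index),
        "vertices_vox": np.asarray(annotation.vertices, float).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_tendon(path, affine: np.ndarray, slice_axis: int = 2) -> TendonAnnotation:
    """Load a tendon polyline and derive its world-frame direction.

    All vertices live on one slice; the direction is the total-least-squares
    line through the in-plane world coordinates (see
    :func:`pennadti.pennation.fit_tendon_direction`).
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "pennadti-tendon-annotation":
        raise ValueError(f"{path} is not a tendon annotation file")
    file_axis = int(payload.get("slice_axis", 2))
    if file_axis != slice_axis:
        raise ValueError(
            f"annotation slice axis {file_axis} does not match the stack's "
            f"slice axis {slice_axis}"
        )
    ann = TendonAnnotation(
        slice_index=int(payload["slice_index"]),
        vertices=np.asarray(payload["vertices_vox"], dtype=float),
        slice_axis=slice_axis,
    )
    from .pennation import fit_tendon_direction

    ann.direction = fit_tendon_direction(
        ann.vertices, affine, slice_axis, ann.slice_index
    )
    return ann


# ---------------------------------------------------------------------------
# ROI label maps

def load_roi_map(path, legend: dict[int, str] | None = None) -> ROILabelMap:
    img = nib.load(str(path))
    return ROILabelMap(labels=np.asarray(img.dataobj), legend=legend or {})


def save_roi_map(rois: ROILabelMap, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(rois.labels.astype(np.int16), affine), str(path))


# ---------------------------------------------------------------------------
# ratings tables

RATINGS_COLUMNS = ("subject", "rater", "session", "value")


def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format ratings contract: unique keys, finite values."""
    missing = [c for c in RATINGS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table missing columns {missing}")
    keys = ["subject", "rater", "session"]
    if "occasion" in table.columns:
        keys.append("occasion")
    if table.duplicated(subset=keys).any():
        raise ValueError("duplicate (subject, rater, session) measurements")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite rating values")
    return table


def load_ratings(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))


def save_ratings(table: pd.DataFrame, path) -> None:
    validate_ratings(table).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# streamlines

def write_streamlines(streamlines, path) -> None:
    """Write streamlines (ordered 3D point lists, world mm) as a TCK file.

    An empty set produces a valid header-only file.  TCK stores float32, so a
    round-trip is exact to well under 1e-4 mm at anatomical coordinates.
    """
    arrays = [np.asarray(s, dtype=float) for s in streamlines]
    for i, arr in enumerate(arrays):
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"streamline {i} is not an (n, 3) point list")
        if not np.isfinite(arr).all():
            raise ValueError(f"streamline {i} contains non-finite points")
    tractogram = nib.streamlines.Tractogram(arrays, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def read_streamlines(path) -> list[np.ndarray]:
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tck.streamlines]
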