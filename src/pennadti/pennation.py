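"""2D pennation-angle maps: in-plane projection of the principal eigenvector
against a manually drawn tendon line, plus ROI aggregation.

The pennation angle of a voxel is computed from the tensor's first
eigenvector ``v``, the unit tendon direction ``T`` and the imaging-plane
normal ``n`` (all world frame)::

    v_p = v - (v . n) n                      # project into the plane
    PA  = arccos(|v_p . T| / |v_p|)          # fold into [0, 90] degrees

The fold reflects fiber axiality: +v and -v describe the same fascicle, so
only the acute angle against the tendon is meaningful (reported muscle values
sit around 10-16 degrees).  Fibers perpendicular to the plane (|v_p| ~ 0)
have no defined in-plane angle and map to NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ROILabelMap, TendonAnnotation
from .tensor import DiffusionTensorField

__all__ = [
    "PAMap",
    "fit_tendon_direction",
    "pennation_angle",
    "compute_pa_map",
    "summarize_rois",
]

#: |v_p| below this is treated as a degenerate (through-plane) projection.
PROJECTION_EPS = 1e-6

#: Unit-norm tolerance on the direction inputs of :func:`pennation_angle`.
UNIT_TOL = 1e-3


@dataclass
class PAMap:
    """Per-voxel pennation angle (degrees, [0, 90] or NaN) on one slice.

    ``pa`` is a 2D array over the in-plane axes (ascending axis order).
    """

    slice_index: int
    slice_axis: int
    pa: np.ndarray
    tendon_direction: np.ndarray
    plane_normal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tendon_direction, dtype=float)
        n = np.asarray(self.plane_normal, dtype=float)
        if abs(float(t @ n)) > 1e-6:
            raise ValueError("tendon direction must lie in the slice plane")
        finite = self.pa[np.isfinite(self.pa)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 90 + 1e-9):
            raise ValueError("pennation angles must lie in [0, 90] degrees")


def _plane_basis(affine: np.ndarray, slice_axis: int):
    axes = [a for a in (0, 1, 2) if a != slice_axis]
    cols = [affine[:3, a] for a in axes]
    normal = np.cross(cols[0], cols[1])
    return axes, normal / np.linalg.norm(normal)


def fit_tendon_direction(
    vertices: np.ndarray,
    affine: np.ndarray,
    slice_axis: int = 2,
    slice_index: int = 0,
) -> np.ndarray:
    """Unit tendon direction: total-least-squares line through the vertices.

    Vertices (2D, voxel units on the in-plane axes) are mapped to the world
    frame, centered, and the principal axis of their scatter taken as the
    tendon direction.  The result lies exactly in the slice plane and has its
    sign canonicalized (first non-zero component positive).  One global
    direction per slice is used — the annotation is treated as one straight
    tendon, not a curve with local tangents.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("vertices must be (m, 2)")
    if np.unique(verts, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct vertices")

    axes, normal = _plane_basis(affine, slice_axis)
    vox = np.zeros((verts.shape[0], 3))
    vox[:, axes[0]] = verts[:, 0]
    vox[:, axes[1]] = verts[:, 1]
    vox[:, slice_axis] = slice_index
    world = vox @ affine[:3, :3].T + affine[:3, 3]

    centered = world - world.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("all vertices coincide; tendon direction undefined")
    t = vt[0]
    t = t - (t @ normal) * normal  # exact in-plane (guards rounding)
    t /= np.linalg.norm(t)
    for c in t:
        if abs(c) > 1e-12:
            if c < 0:
                t = -t
            break
    return t


def pennation_angle(v: np.ndarray, t: np.ndarray, n: np.ndarray) -> float:
    """Angle (degrees, [0, 90]) between the in-plane projection of ``v`` and
    the tendon direction ``t``; NaN when ``v`` is perpendicular to the plane.
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    n = np.asarray(n, dtype=float)
    for name, vec in (("v", v), ("t", t), ("n", n)):
        if abs(np.linalg.norm(vec) - 1.0) > UNIT_TOL:
            raise ValueError(f"{name} must be a unit vector")
    if abs(float(t @ n)) > 1e-6:
        raise ValueError("tendon direction must be perpendicular to the plane normal")
    v_p = v - (v @ n) * n
    norm = np.linalg.norm(v_p)
    if norm < PROJECTION_EPS:
        return float("nan")
    cosang = np.clip(abs(v_p @ t) / norm, 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _pennation_angles_vec(v: np.ndarray, t: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized pennation angle over an (..., 3) eigenvector array."""
    v_p = v - (v @ n)[..., None] * n
    norm = np.linalg.norm(v_p, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.abs(v_p @ t) / norm, 0.0, 1.0)
        pa = np.degrees(np.arccos(cosang))
    return np.where(norm < PROJECTION_EPS, np.nan, pa)


def compute_pa_map(
    field: DiffusionTensorField,
    annotation: TendonAnnotation,
    mask: np.ndarray | None = None,
) -> PAMap:
    """Pennation-angle map on the annotation slice.

    One global tendon direction is applied to every masked, validly fitted
    voxel of the slice; everything else is NaN.  ``mask`` is a 3D boolean
    array (defaults to the field's fit mask).
    """
    if annotation.slice_axis != field.slice_axis:
        raise ValueError("annotation and tensor field use different slice axes")
    k = int(annotation.slice_index)
    n_slices = field.mask.shape[field.slice_axis]
    if not 0 <= k < n_slices:
        raise ValueError(f"annotation slice {k} outside volume (0..{n_slices - 1})")

    if annotation.direction is None:
        t = fit_tendon_direction(
            annotation.vertices, field.affine, field.slice_axis, k
        )
    else:
        t = np.asarray(annotation.direction, dtype=float)

    _, n = _plane_basis(field.affine, field.slice_axis)
    t = t - (t @ n) * n
    t /= np.linalg.norm(t)

    if mask is None:
        mask = field.mask
    usable = np.asarray(mask, dtype=bool) & field.usable()

    sl = [slice(None)] * 3
    sl[field.slice_axis] = k
    sl = tuple(sl)
    usable_2d = usable[sl]
    e1_2d = field.e1[sl]

    pa = np.full(usable_2d.shape, np.nan)
    if usable_2d.any():
        pa[usable_2d] = _pennation_angles_vec(e1_2d[usable_2d], t, n)
    else:
        warnings.warn(f"no usable voxels on slice {k}; PA map is all NaN")
    return PAMap(slice_index=k, slice_axis=field.slice_axis, pa=pa,
                 tendon_direction=t, plane_normal=n)


def summarize_rois(pa_map: PAMap, rois: ROILabelMap) -> pd.DataFrame:
    """NaN-excluding mean/SD/count of the PA map per ROI label.

    Returns a DataFrame with columns ``label, name, mean, sd, n``; labels whose
    ROI contains no finite PA voxel are dropped with a warning.
    """
    sl = [slice(None)] * 3
    sl[pa_map.slice_axis] = pa_map.slice_index
    labels_2d = rois.labels[tuple(sl)]
    if labels_2d.shape != pa_map.pa.shape:
        raise ValueError("ROI grid does not match the PA map grid")

    rows = []
    for label in np.unique(labels_2d):
        if label == 0:
            continue
        values = pa_map.pa[labels_2d == label]
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            warnings.warn(f"ROI label {label} contains no finite PA voxels; dropped")
            continue
        rows.append({
            "label": int(label),
            "name": rois.legend.get(int(label), ""),
            "mean": float(finite.mean()),
            "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
            "n": int(finite.size),
        })
    return pd.DataFrame(rows, columns=["label", "name", "mean", "sd", "n"])
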