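"""Intensity-based alignment of diffusion volumes to the first b=0 image.

Eddy-current and motion inconsistencies between diffusion-weighted volumes
are reduced by registering every volume to the first unweighted (b=0)
reference with a rigid or affine transform (normalized cross-correlation
metric, multi-resolution, linear resampling).  Non-rigid correction — the
method of choice on real in-vivo data — is out of scope here; the
``nonrigid_hook`` argument lets callers plug in an external tool that maps
``(moving 3D array, reference 3D array) -> aligned 3D array``.

Translation convention: ``VolumeTransform.translation_mm`` reports the
content shift the registration undoes.  A volume whose content was shifted
by +s mm along an axis is reported with translation -s along that axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk

from .io import DWIStack, GradientTable

__all__ = ["VolumeTransform", "register_to_b0"]

logger = logging.getLogger(__name__)

MODES = ("none", "rigid", "affine")


@dataclass
class VolumeTransform:
    """Per-volume registration record."""

    index: int
    mode: str
    parameters: tuple[float, ...]
    translation_mm: np.ndarray   # content shift undone, numpy (i, j, k) axes
    is_reference: bool = False
    converged: bool = True

    def as_text(self) -> str:
        t = ", ".join(f"{x:+.4f}" for x in self.translation_mm)
        return (f"volume {self.index}: mode={self.mode} "
                f"translation_mm=({t}) converged={self.converged}")


def _to_sitk(vol: np.ndarray, voxel_size: Sequence[float]) -> sitk.Image:
    # sitk index (x, y, z) <- numpy (i, j, k) via the axis transpose
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in voxel_size))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def _register_pair(fixed: sitk.Image, moving: sitk.Image, mode: str):
    if mode == "rigid":
        initial = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
    else:
        initial = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=200,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SetInitialTransform(initial, inPlace=True)
    return reg.Execute(fixed, moving)


def register_to_b0(
    stack: DWIStack,
    table: GradientTable,
    mode: str = "rigid",
    nonrigid_hook: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> tuple[DWIStack, list[VolumeTransform]]:
    """Align every volume of the stack to the first b=0 volume.

    The reference volume is passed through bit-identically; each moving
    volume is resampled once with linear interpolation onto the input grid
    and clamped at zero.  ``mode="none"`` bypasses registration entirely.
    A failed optimization falls back to the identity transform with a logged
    warning instead of raising.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if len(table) != stack.n_volumes:
        raise ValueError("gradient table does not match stack")
    b0 = table.b0_indices
    if b0.size == 0:
        raise ValueError("no b=0 volume available as registration reference")
    ref_idx = int(b0[0])

    if mode == "none" and nonrigid_hook is None:
        transforms = [
            VolumeTransform(index=i, mode="none", parameters=(),
                            translation_mm=np.zeros(3),
                            is_reference=(i == ref_idx))
            for i in range(stack.n_volumes)
        ]
        return DWIStack(data=stack.data.copy(), affine=stack.affine.copy(),
                        slice_axis=stack.slice_axis), transforms

    ref_np = stack.data[..., ref_idx]
    fixed = _to_sitk(ref_np, stack.voxel_size)
    out = np.empty_like(stack.data)
    out[..., ref_idx] = ref_np
    transforms: list[VolumeTransform] = []

    for i in range(stack.n_volumes):
        if i == ref_idx:
            transforms.append(VolumeTransform(
                index=i, mode=mode, parameters=(), translation_mm=np.zeros(3),
                is_reference=True))
            continue
        moving_np = stack.data[..., i]
        if nonrigid_hook is not None:
            out[..., i] = np.clip(nonrigid_hook(moving_np, ref_np), 0.0, None)
            transforms.append(VolumeTransform(
                index=i, mode="nonrigid-hook", parameters=(),
                translation_mm=np.full(3, np.nan)))
            continue
        moving = _to_sitk(moving_np, stack.voxel_size)
        try:
            tf = _register_pair(fixed, moving, mode)
            converged = True
        except RuntimeError as exc:
            logger.warning("registration of volume %d diverged (%s); "
                           "falling back to identity", i, exc)
            tf = sitk.Euler3DTransform()
            converged = False
        resampled = sitk.Resample(moving, fixed, tf, sitk.sitkLinear, 0.0)
        out[..., i] = np.clip(_from_sitk(resampled), 0.0, None)
        params = tuple(tf.GetParameters())
        # sitk transforms map fixed-frame points into the moving frame, so the
        # fitted translation equals the content shift; negate to report the
        # shift undone.  sitk (x, y, z) == numpy (i, j, k) by construction.
        trans = np.array(params[-3:]) if params else np.zeros(3)
        transforms.append(VolumeTransform(
            index=i, mode=mode, parameters=params, translation_mm=-trans,
            converged=converged))

    aligned = DWIStack(data=out, affine=stack.affine.copy(),
                       slice_axis=stack.slice_axis)
    return aligned, transforms
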