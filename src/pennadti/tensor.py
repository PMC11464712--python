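"""Per-voxel diffusion tensor estimation and derived scalar maps.

The signal model is the monoexponential tensor model
``S(b, g) = S0 * exp(-b g^T D g)``, fitted voxel-wise by ordinary least
squares on log-signals (weighted least squares available behind a flag).
Eigenvectors are returned in the world frame with a deterministic sign
convention, since fiber orientation is axial (+v and -v are equivalent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .io import DWIStack, GradientTable

__all__ = [
    "DiffusionTensorField",
    "ScalarMaps",
    "design_matrix",
    "default_mask",
    "fit_tensor",
    "scalar_maps",
    "fractional_anisotropy",
    "mean_diffusivity",
]

#: Floor applied to non-positive signals, as a fraction of the voxel's S0.
SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass
class DiffusionTensorField:
    """Voxel-wise tensor fit result.

    ``tensors`` is ``(i, j, k, 3, 3)`` in mm^2/s; ``evals`` are sorted
    descending (lambda1 >= lambda2 >= lambda3); ``evecs[..., :, m]`` is the
    unit eigenvector of ``evals[..., m]`` in the world frame, with the first
    non-zero component made positive.  ``valid`` is False where the fit input
    was degenerate (too few usable samples); ``mask`` marks fitted voxels.
    """

    tensors: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray
    ln_s0: np.ndarray
    mask: np.ndarray
    valid: np.ndarray
    affine: np.ndarray
    slice_axis: int = 2

    @property
    def e1(self) -> np.ndarray:
        """Principal eigenvector field, shape ``(i, j, k, 3)``."""
        return self.evecs[..., :, 0]

    @property
    def s0(self) -> np.ndarray:
        return np.exp(self.ln_s0)

    def usable(self) -> np.ndarray:
        return self.mask & self.valid


@dataclass
class ScalarMaps:
    """Fractional anisotropy (unitless) and mean diffusivity (mm^2/s)."""

    fa: np.ndarray
    md: np.ndarray


def design_matrix(table: GradientTable) -> np.ndarray:
    """Log-linear design matrix mapping (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).

    Row for volume m: ``ln S_m = ln S0 - b_m g^T D g`` expanded over the six
    unique tensor components.  b=0 rows have zero diffusion entries.  Raises
    if the scheme cannot determine all seven parameters (fewer than six
    non-collinear weighted directions).
    """
    b = table.bvals
    g = table.bvecs
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ])
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme underdetermined")
    return X


def _tensors_from_coefs(d: np.ndarray) -> np.ndarray:
    """(..., 6) components (xx, yy, zz, xy, xz, yz) -> (..., 3, 3) tensors."""
    T = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    T[..., 0, 0] = d[..., 0]
    T[..., 1, 1] = d[..., 1]
    T[..., 2, 2] = d[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = d[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = d[..., 4]
    T[..., 1, 2] = T[..., 2, 1] = d[..., 5]
    return T


def canonical_sign(vecs: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip axial vectors so their first non-zero component is positive.

    Accepts a single vector ``(3,)`` or column stacks ``(..., 3, k)`` where
    components run along the last-but-one axis.
    """
    v = np.asarray(vecs, dtype=float)
    comp_axis = -1 if v.ndim == 1 else -2
    sign = np.zeros(np.delete(np.array(v.shape), comp_axis))
    for c in range(2, -1, -1):
        comp = np.take(v, c, axis=comp_axis)
        sign = np.where(np.abs(comp) > tol, np.sign(comp), sign)
    sign = np.where(sign == 0, 1.0, sign)
    return v * np.expand_dims(sign, comp_axis)


def default_mask(stack: DWIStack, table: GradientTable) -> np.ndarray:
    """Foreground mask: mean b=0 signal above an Otsu threshold."""
    b0_mean = stack.data[..., table.b0_mask].mean(axis=3)
    try:
        thr = threshold_otsu(b0_mean)
    except ValueError:  # constant image
        return np.ones(stack.shape, dtype=bool)
    return b0_mean > thr


def fit_tensor(
    stack: DWIStack,
    table: GradientTable,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> DiffusionTensorField:
    """Fit the diffusion tensor per masked voxel.

    Ordinary least squares on log-signals (``weighted=True`` re-weights each
    row by the squared model signal, one reweighting pass).  Non-positive
    samples are excluded per voxel; if fewer than 7 usable samples remain, the
    voxel is fitted on floored signals and flagged ``valid=False``.
    """
    if len(table) != stack.n_volumes:
        raise ValueError("gradient table does not match stack")
    X = design_matrix(table)
    if mask is None:
        mask = default_mask(stack, table)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError("mask shape does not match stack grid")
    if not mask.any():
        raise ValueError("empty fit mask")

    sig = stack.data[mask]  # (V, n)
    n_vox = sig.shape[0]
    coefs = np.empty((n_vox, 7), dtype=float)
    valid = np.ones(n_vox, dtype=bool)

    pinv = np.linalg.pinv(X)
    positive = sig > 0
    clean = positive.all(axis=1)
    if clean.any():
        coefs[clean] = np.log(sig[clean]) @ pinv.T

    for idx in np.flatnonzero(~clean):
        s = sig[idx]
        keep = s > 0
        if keep.sum() >= 7 and np.linalg.matrix_rank(X[keep]) == 7:
            coefs[idx], *_ = np.linalg.lstsq(X[keep], np.log(s[keep]), rcond=None)
        else:
            s0 = s[table.b0_mask]
            ref = s0[s0 > 0].mean() if (s0 > 0).any() else 1.0
            floored = np.maximum(s, SIGNAL_FLOOR_FRACTION * ref)
            coefs[idx] = pinv @ np.log(floored)
            valid[idx] = False

    if weighted:
        # one reweighting pass: weights proportional to the fitted signal
        pred = coefs @ X.T
        w = np.exp(pred)
        w[~positive] = 0.0
        logs = np.where(positive, np.log(np.maximum(sig, 1e-300)), 0.0)
        for idx in range(n_vox):
            W = w[idx]
            A = X * W[:, None]
            coefs[idx], *_ = np.linalg.lstsq(A, W * logs[idx], rcond=None)

    tensors_flat = _tensors_from_coefs(coefs[:, 1:])
    evals_flat, evecs_flat = np.linalg.eigh(tensors_flat)
    evals_flat = evals_flat[:, ::-1]                 # descending
    evecs_flat = canonical_sign(evecs_flat[:, :, ::-1])

    shape = stack.shape
    field = DiffusionTensorField(
        tensors=np.full(shape + (3, 3), np.nan),
        evals=np.full(shape + (3,), np.nan),
        evecs=np.full(shape + (3, 3), np.nan),
        ln_s0=np.full(shape, np.nan),
        mask=mask,
        valid=np.zeros(shape, dtype=bool),
        affine=stack.affine,
        slice_axis=stack.slice_axis,
    )
    field.tensors[mask] = tensors_flat
    field.evals[mask] = evals_flat
    field.evecs[mask] = evecs_flat
    field.ln_s0[mask] = coefs[:, 0]
    field.valid[mask] = valid
    return field


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, negatives clamped to 0.

    An all-zero eigenvalue triple maps to FA 0.
    """
    lam = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - md, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def mean_diffusivity(evals: np.ndarray) -> np.ndarray:
    return np.asarray(evals, dtype=float).mean(axis=-1)


def scalar_maps(field: DiffusionTensorField) -> ScalarMaps:
    """FA and MD maps; NaN outside the usable (masked & valid) voxels."""
    usable = field.usable()
    fa = np.full(field.mask.shape, np.nan)
    md = np.full(field.mask.shape, np.nan)
    if usable.any():
        fa[usable] = fractional_anisotropy(field.evals[usable])
        md[usable] = mean_diffusivity(field.evals[usable])
    if not usable.any():
        warnings.warn("no usable voxels; scalar maps are all NaN")
    return ScalarMaps(fa=fa, md=md)
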