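"""Digital bipennate-muscle phantom with known ground truth.

The phantom emulates the supraspinatus geometry at desk scale: a straight
intramuscular tendon running in-plane, an anterior bipennate compartment
whose two sub-bundles mirror each other at +/-PA_ant about the tendon line,
and a posterior "strap-like" compartment of parallel fibers at PA_post.
Each voxel carries a prescribed diffusion tensor; the diffusion-weighted
signal is ``S = S0 exp(-b g^T D g)`` with optional Rician noise
(``sigma = S0 / SNR``), matching the statistics of magnitude MRI.

Everything downstream — tendon annotation, ROI labels, per-voxel principal
direction and pennation angle — is returned as ground truth, so tensor
fitting, PA mapping, tractography and the reliability statistics can all be
validated without any acquired data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io import DWIStack, GradientTable, ROILabelMap, TendonAnnotation

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "fibonacci_directions",
    "muscle_gradient_table",
    "generate_phantom",
    "generate_ratings",
]

#: Default tensor eigenvalues for skeletal muscle, mm^2/s.
MUSCLE_EVALS = (2.1e-3, 1.6e-3, 1.4e-3)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic bipennate muscle.

    Geometry is laid out on the in-plane axes (i, j) with the tendon running
    along +i at row ``tendon_j``; compartments are j-bands.  Defaults mirror
    a 15-slice, 3 mm acquisition at a reduced 64x64 in-plane matrix, with
    anterior/posterior pennation angles of 16 and 11 degrees — the scale of
    in-vivo supraspinatus values.  ``snr`` is S0/sigma; ``math.inf`` disables
    noise.
    """

    shape: tuple[int, int, int] = (64, 64, 15)
    voxel_size: tuple[float, float, float] = (0.75, 0.75, 3.0)
    slice_axis: int = 2
    tendon_slice: int | None = None          # default: middle slice
    tendon_j: int | None = None              # default: middle of anterior band
    tendon_halfwidth: int = 1
    anterior_pa: float = 16.0
    posterior_pa: float = 11.0
    anterior_elevation: float = 0.0
    posterior_elevation: float = 0.0
    anterior_band: tuple[int, int] | None = None   # default: front half minus margins
    posterior_band: tuple[int, int] | None = None  # default: back half minus margins
    margin_i: tuple[int, int] | None = None
    evals: tuple[float, float, float] = MUSCLE_EVALS
    s0: float = 1000.0
    background_s0_fraction: float = 0.02
    snr: float = math.inf
    n_directions: int = 64
    bval: float = 450.0
    n_b0: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        ni, nj, nk = self.shape
        defaults = {
            "tendon_slice": nk // 2,
            "anterior_band": (2, nj // 2 - 2),
            "posterior_band": (nj // 2 + 2, nj - 2),
            "margin_i": (2, ni - 2),
        }
        for name, value in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)
        if self.tendon_j is None:
            a, b = self.anterior_band
            object.__setattr__(self, "tendon_j", (a + b) // 2)
        if not 0 <= self.tendon_slice < nk:
            raise ValueError("tendon slice outside the volume")
        lam = self.evals
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        for pa in (self.anterior_pa, self.posterior_pa):
            if not 0 <= pa <= 90:
                raise ValueError("pennation angles must lie in [0, 90] degrees")
        if self.snr <= 0:
            raise ValueError("SNR must be positive (or infinite)")
        lo, hi = self.tendon_j - self.tendon_halfwidth, self.tendon_j + self.tendon_halfwidth
        for name, (a, b) in (("anterior", self.anterior_band),
                             ("posterior", self.posterior_band)):
            if a >= b:
                raise ValueError(f"{name} band is empty")
        pa, pb = self.posterior_band
        if pa <= hi and pb > lo:
            raise ValueError("posterior compartment overlaps the tendon exclusion zone")
        if not (self.anterior_band[0] <= lo and hi < self.anterior_band[1]):
            raise ValueError("tendon line must run inside the anterior compartment")
        if self.anterior_band[1] > pa:
            raise ValueError("compartments must be disjoint")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    pa_map: np.ndarray          # 2D, degrees, NaN outside compartments
    pa_volume: np.ndarray       # 3D, degrees, NaN outside compartments
    e1: np.ndarray              # (i, j, k, 3) unit fiber directions
    tensors: np.ndarray         # (i, j, k, 3, 3), mm^2/s
    rois: ROILabelMap           # anterior=1, posterior=2
    annotation: TendonAnnotation
    tendon_direction: np.ndarray
    plane_normal: np.ndarray
    muscle_mask: np.ndarray     # foreground (all fibered voxels incl. tendon zone)
    roi_means: dict[int, float] = dc_field(default_factory=dict)


def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit directions on the sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def muscle_gradient_table(n_directions: int = 64, bval: float = 450.0,
                          n_b0: int = 3) -> GradientTable:
    """Reference-first gradient scheme: ``n_b0`` unweighted volumes, then
    ``n_directions`` quasi-uniform directions at one b-value."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def _fiber_direction(t: np.ndarray, u: np.ndarray, n: np.ndarray,
                     inplane_deg: float, elev_deg: float) -> np.ndarray:
    a = math.radians(inplane_deg)
    e = math.radians(elev_deg)
    d = math.cos(e) * (math.cos(a) * t + math.sin(a) * u) + math.sin(e) * n
    return d / np.linalg.norm(d)


def _tensor_from_e1(e1: np.ndarray, u_ref: np.ndarray,
                    lam: tuple[float, float, float]) -> np.ndarray:
    """Tensor with principal axis e1; secondary axes chosen orthonormal."""
    e2 = u_ref - (u_ref @ e1) * e1
    if np.linalg.norm(e2) < 1e-8:
        u_alt = np.array([0.0, 0.0, 1.0])
        e2 = u_alt - (u_alt @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(lam) @ R.T


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build the phantom: returns ``(DWIStack, GradientTable, PhantomTruth)``.

    Deterministic for a fixed spec (the RNG is seeded from ``spec.seed``).
    Voxels in the tendon exclusion zone carry tendon-parallel fibers but are
    labeled 0, mirroring the study practice of excluding the tendon itself
    from the ROIs.  Background voxels are near-signal-free isotropic medium.
    """
    if spec.slice_axis != 2:
        raise NotImplementedError("phantom geometry is laid out for slice_axis=2")
    ni, nj, nk = spec.shape
    affine = np.diag(list(spec.voxel_size) + [1.0])

    # world-frame plane basis: tendon along +i, in-plane perpendicular +j
    t_dir = affine[:3, 0] / np.linalg.norm(affine[:3, 0])
    u_dir = affine[:3, 1] / np.linalg.norm(affine[:3, 1])
    n_dir = np.cross(t_dir, u_dir)
    n_dir /= np.linalg.norm(n_dir)

    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    in_i = (ii >= spec.margin_i[0]) & (ii < spec.margin_i[1])
    ant = in_i & (jj >= spec.anterior_band[0]) & (jj < spec.anterior_band[1])
    post = in_i & (jj >= spec.posterior_band[0]) & (jj < spec.posterior_band[1])
    tendon_zone = ant & (np.abs(jj - spec.tendon_j) <= spec.tendon_halfwidth)
    ant_up = ant & (jj < spec.tendon_j) & ~tendon_zone
    ant_down = ant & (jj > spec.tendon_j) & ~tendon_zone

    regions = {
        # label, signed in-plane angle, elevation
        "ant_up": (1, +spec.anterior_pa, spec.anterior_elevation, ant_up),
        "ant_down": (1, -spec.anterior_pa, spec.anterior_elevation, ant_down),
        "post": (2, +spec.posterior_pa, spec.posterior_elevation, post),
        "tendon": (0, 0.0, 0.0, tendon_zone),
    }

    labels_2d = np.zeros((ni, nj), dtype=np.int16)
    pa_2d = np.full((ni, nj), np.nan)
    e1_2d = np.zeros((ni, nj, 3))
    tensor_2d = np.zeros((ni, nj, 3, 3))
    muscle_2d = np.zeros((ni, nj), dtype=bool)

    iso_bg = np.eye(3) * np.mean(spec.evals)
    for label, angle, elev, region in regions.values():
        e1 = _fiber_direction(t_dir, u_dir, n_dir, angle, elev)
        D = _tensor_from_e1(e1, u_dir, spec.evals)
        labels_2d[region] = label
        e1_2d[region] = e1
        tensor_2d[region] = D
        muscle_2d |= region
        if label > 0:
            pa_2d[region] = abs(angle)

    tensor_2d[~muscle_2d] = iso_bg
    s0_2d = np.where(muscle_2d, spec.s0, spec.background_s0_fraction * spec.s0)

    # broadcast the 2D layout through all slices
    labels = np.repeat(labels_2d[:, :, None], nk, axis=2)
    pa_vol = np.repeat(pa_2d[:, :, None], nk, axis=2)
    e1_field = np.repeat(e1_2d[:, :, None, :], nk, axis=2)
    tensors = np.repeat(tensor_2d[:, :, None, :, :], nk, axis=2)
    muscle = np.repeat(muscle_2d[:, :, None], nk, axis=2)
    s0_map = np.repeat(s0_2d[:, :, None], nk, axis=2)

    table = muscle_gradient_table(spec.n_directions, spec.bval, spec.n_b0)
    g = table.bvecs
    # attenuation exponent b * g^T D g per voxel/volume
    gdg = np.einsum("na,ijkab,nb->ijkn", g, tensors, g)
    signal = s0_map[..., None] * np.exp(-table.bvals * gdg)

    if math.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        real = signal + rng.normal(0.0, sigma, signal.shape)
        imag = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt(real**2 + imag**2)

    stack = DWIStack(data=signal, affine=affine, slice_axis=spec.slice_axis)

    i0, i1 = spec.margin_i
    annotation = TendonAnnotation(
        slice_index=spec.tendon_slice,
        vertices=np.array([[i0, spec.tendon_j], [i1 - 1, spec.tendon_j]], float),
        slice_axis=spec.slice_axis,
        direction=t_dir.copy(),
    )
    truth = PhantomTruth(
        pa_map=pa_2d,
        pa_volume=pa_vol,
        e1=e1_field,
        tensors=tensors,
        rois=ROILabelMap(labels=labels, legend={1: "anterior", 2: "posterior"}),
        annotation=annotation,
        tendon_direction=t_dir,
        plane_normal=n_dir,
        muscle_mask=muscle,
        roi_means={1: spec.anterior_pa, 2: spec.posterior_pa},
    )
    return stack, table, truth


def generate_ratings(
    true_mean: float,
    n_subjects: int = 10,
    n_raters: int = 3,
    n_sessions: int = 3,
    sigma2_subject: float = 4.0,
    sigma2_rater: float = 0.0,
    sigma2_session: float = 0.0,
    sigma2_error: float = 1.0,
    n_occasions: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a balanced ratings table from additive variance components.

    ``value = true_mean + subject_i + rater_j + session_k + residual``, all
    Gaussian.  The expected single-measures absolute-agreement ICC of the
    subjects x raters design (one session) is
    ``sigma2_subject / (sigma2_subject + sigma2_rater + sigma2_error)``.
    Defaults mirror the study design: 10 subjects, 3 raters, 3 sessions.
    """
    for name, v in (("sigma2_subject", sigma2_subject), ("sigma2_rater", sigma2_rater),
                    ("sigma2_session", sigma2_session), ("sigma2_error", sigma2_error)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, math.sqrt(sigma2_subject), n_subjects)
    rater = rng.normal(0.0, math.sqrt(sigma2_rater), n_raters)
    sess = rng.normal(0.0, math.sqrt(sigma2_session), n_sessions)
    rows = []
    for i in range(n_subjects):
        for j in range(n_raters):
            for k in range(n_sessions):
                for o in range(n_occasions):
                    value = (true_mean + subj[i] + rater[j] + sess[k]
                             + rng.normal(0.0, math.sqrt(sigma2_error)))
                    rows.append({
                        "subject": f"S{i + 1:03d}",
                        "rater": f"R{j + 1}",
                        "session": k + 1,
                        "occasion": o + 1,
                        "value": value,
                    })
    df = pd.DataFrame(rows)
    if n_occasions == 1:
        df = df.drop(columns="occasion")
    return df
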