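"""Absolute 3D respiratory motion tracking.

Each heartbeat's low-resolution volume is registered to a reference beat
with a multi-resolution deformable registration; the displacement field is
then averaged over a central box covering 1/4 of the field of view per
axis — the region dominated by the heart — giving one (dx, dy, dz) in mm
per beat.  The sign convention follows the short-axis display: positive x
means the heart moved up (towards end-expiration).

Registration is delegated to SimpleITK: symmetric-forces demons
(intensity-difference driven, the default, suited to the monomodal
magnitude volumes produced here) or a mutual-information B-spline
registration (``similarity="mi"``) whose transform is sampled into the same
dense displacement-field representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "RegistrationParams",
    "DeformationField",
    "MotionTrace",
    "register3d",
    "central_roi_mean",
    "track_motion",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationParams:
    similarity: str = "demons"       # "demons" (SSD-like) or "mi"
    iterations: tuple[int, ...] = (100, 80, 60)  # per pyramid level, coarse->fine
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    # anti-alias smoothing (mm, scaled by the shrink factor) applied before
    # each pyramid level; none at full resolution
    anti_alias_mm: float = 2.0
    field_sigma_vox: float = 0.8     # Gaussian regularisation of the field (voxels)
    mi_bins: int = 32
    mi_grid_spacing_mm: float = 32.0


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) mapping the target back to the reference,
    on the target's grid, array layout (Nx, Ny, Nz, 3)."""

    vectors_mm: np.ndarray
    spacing_mm: tuple[float, float, float]
    similarity_value: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.vectors_mm.ndim != 4 or self.vectors_mm.shape[-1] != 3:
            raise ValueError("field must have shape (Nx, Ny, Nz, 3)")
        if not np.all(np.isfinite(self.vectors_mm)):
            raise ValueError("deformation field contains non-finite values")


@dataclass
class MotionTrace:
    """Per-heartbeat absolute heart displacement relative to a reference beat."""

    beat_ids: np.ndarray
    displacement_mm: np.ndarray      # (n_beats, 3)
    reference_beat_id: int = 0
    flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        ref_row = np.where(self.beat_ids == self.reference_beat_id)[0]
        if len(ref_row) and np.linalg.norm(self.displacement_mm[ref_row[0]]) > 0.2:
            log.warning("trace at reference beat is %.2f mm from zero",
                        np.linalg.norm(self.displacement_mm[ref_row[0]]))
        if self.flags is None:
            self.flags = np.zeros(len(self.beat_ids), dtype=bool)

    @property
    def si_mm(self) -> np.ndarray:
        return self.displacement_mm[:, 0]


def _to_sitk(vol: np.ndarray, spacing) -> sitk.Image:
    # numpy (x, y, z) -> sitk expects (z, y, x) array layout
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.T).astype(np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _normalize(vol: np.ndarray) -> np.ndarray:
    peak = np.percentile(vol, 99.5)
    return np.clip(vol / peak, 0.0, 1.2) if peak > 0 else vol


def register3d(target: np.ndarray, reference: np.ndarray,
               spacing_mm, params: RegistrationParams | None = None
               ) -> DeformationField:
    """Dense displacement field (mm) aligning ``target`` to ``reference``.

    The field points from the target's coordinates back to the reference,
    i.e. for a target rigidly shifted by +d relative to the reference the
    central field value is ~ +d.
    """
    if target.shape != reference.shape:
        raise ValueError("target and reference must share a grid")
    params = params or RegistrationParams()
    tgt = _to_sitk(_normalize(target), spacing_mm)
    ref = _to_sitk(_normalize(reference), spacing_mm)

    if params.similarity == "demons":
        field_img, metric, converged = _demons_multires(ref, tgt, params)
    elif params.similarity in ("mi", "mutual_information"):
        field_img, metric, converged = _bspline_mi(ref, tgt, params)
    else:
        raise ValueError(f"unknown similarity {params.similarity!r}")

    vec = sitk.GetArrayFromImage(field_img)   # (z, y, x, 3) with (dx,dy,dz) comps
    vectors = np.transpose(vec, (2, 1, 0, 3))
    # registration maps reference coords to the matching target location,
    # i.e. the displacement *of the target relative to the reference*
    vectors = np.nan_to_num(vectors, nan=0.0, posinf=0.0, neginf=0.0)
    return DeformationField(
        vectors_mm=vectors, spacing_mm=tuple(spacing_mm),
        similarity_value=metric, converged=converged,
    )


def _demons_multires(ref: sitk.Image, tgt: sitk.Image,
                     params: RegistrationParams):
    """Coarse-to-fine symmetric-forces demons with Gaussian field smoothing."""
    field = None
    metric = float("nan")
    levels = list(zip(params.shrink_factors, params.iterations))
    for shrink, iters in levels:
        sigma = params.anti_alias_mm * shrink if shrink > 1 else 0.0
        ref_l = _shrink(ref, shrink, sigma)
        tgt_l = _shrink(tgt, shrink, sigma)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetStandardDeviations(params.field_sigma_vox)
        demons.SetSmoothDisplacementField(True)
        demons.SetSmoothUpdateField(False)
        if field is not None:
            field = sitk.Resample(field, ref_l, sitk.Transform(),
                                  sitk.sitkLinear, 0.0,
                                  sitk.sitkVectorFloat64)
            field = demons.Execute(ref_l, tgt_l, field)
        else:
            field = demons.Execute(ref_l, tgt_l)
        metric = float(demons.GetMetric())
    if field.GetSize() != ref.GetSize():
        field = sitk.Resample(field, ref, sitk.Transform(), sitk.sitkLinear,
                              0.0, sitk.sitkVectorFloat64)
    arr = sitk.GetArrayFromImage(field)
    converged = bool(np.all(np.isfinite(arr)))
    if not converged:
        log.warning("demons produced non-finite field values; clamped")
        field = sitk.GetImageFromArray(
            np.nan_to_num(arr, nan=0.0, posinf=0.0, neginf=0.0), isVector=True)
        field.CopyInformation(ref)
    return field, metric, converged


def _shrink(img: sitk.Image, factor: int, sigma_mm: float) -> sitk.Image:
    if sigma_mm > 0:
        img = sitk.SmoothingRecursiveGaussian(img, sigma_mm)
    if factor > 1:
        img = sitk.Shrink(img, [factor] * 3)
    return img


def _bspline_mi(ref: sitk.Image, tgt: sitk.Image, params: RegistrationParams):
    """Mattes mutual-information B-spline registration, sampled to a dense
    displacement field on the reference grid."""
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(params.mi_bins)
    reg.SetInterpolator(sitk.sitkLinear)
    mesh = [max(1, int(round(sz * sp / params.mi_grid_spacing_mm)))
            for sz, sp in zip(ref.GetSize(), ref.GetSpacing())]
    tx0 = sitk.BSplineTransformInitializer(ref, mesh)
    reg.SetInitialTransform(tx0, inPlace=True)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=sum(params.iterations))
    reg.SetShrinkFactorsPerLevel(list(params.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(
        [float(max(s - 1, 0)) for s in params.shrink_factors])
    try:
        tx = reg.Execute(ref, tgt)
        converged = True
        metric = float(reg.GetMetricValue())
    except RuntimeError as err:   # non-convergence: keep the initial transform
        log.warning("MI registration failed (%s); returning best iterate", err)
        tx, converged, metric = tx0, False, float("nan")
    field = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64, ref.GetSize(), ref.GetOrigin(),
        ref.GetSpacing(), ref.GetDirection())
    return field, metric, converged


def central_roi_mean(field: DeformationField, fraction: float = 0.25
                     ) -> np.ndarray:
    """Mean displacement over the centred box spanning ``fraction`` of the
    field of view per axis."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    v = field.vectors_mm
    sl = []
    for n in v.shape[:3]:
        half = max(1, int(round(n * fraction / 2)))
        c = n // 2
        sl.append(slice(max(0, c - half), min(n, c + half)))
    return v[sl[0], sl[1], sl[2]].reshape(-1, 3).mean(axis=0)


def track_motion(beat_volumes: np.ndarray, spacing_mm,
                 reference_beat_id: int = 0, roi_fraction: float = 0.25,
                 params: RegistrationParams | None = None,
                 beat_ids: np.ndarray | None = None) -> MotionTrace:
    """Per-beat absolute 3D displacement relative to the reference beat."""
    n = len(beat_volumes)
    if n < 2:
        raise ValueError("need at least 2 beats to track motion")
    if beat_ids is None:
        beat_ids = np.arange(n)
    ref = beat_volumes[list(beat_ids).index(reference_beat_id)]
    disp = np.zeros((n, 3))
    flags = np.zeros(n, dtype=bool)
    for i, vol in enumerate(beat_volumes):
        if beat_ids[i] == reference_beat_id:
            continue
        fld = register3d(vol, ref, spacing_mm, params)
        disp[i] = central_roi_mean(fld, roi_fraction)
        flags[i] = not fld.converged
    return MotionTrace(beat_ids=np.asarray(beat_ids), displacement_mm=disp,
                       reference_beat_id=reference_beat_id, flags=flags)
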