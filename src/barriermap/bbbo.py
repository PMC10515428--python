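"""Whole-brain blood-brain-barrier-opening (BBBo) mapping.

Orchestrates the voxelwise kinetics over a 4D post-contrast series:
rigid motion correction to the first post-contrast frame, voxelwise
normalization and two-exponential fitting inside a brain mask, and
classification of BBBo voxels by the filter set

    r^2 > 0.6  AND  Dyn > 5 %  AND  3D cluster size >= 30 voxels

with 26-connected components.  Surviving clusters form the binary BBBo
mask whose voxel count x voxel volume is the reported BBBo volume.

The brain stage does not loop a scalar optimizer over voxels.  The model
is linear in (x1, x3, x5) once (x2, x4) are fixed, so a variable-projection
sweep over a log-spaced (x2, x4) grid solves all voxels simultaneously by
linear least squares; the best grid node per voxel then seeds a batched
Levenberg-Marquardt refinement of all five parameters, run in parallel
across voxels with per-voxel damping.  The per-curve scipy path
(:func:`barriermap.kinetics.fit_voxel`) remains available as an
independent reference route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .kinetics import AcquisitionTimes, FitConfig

__all__ = [
    "VoxelDims",
    "DceSeries",
    "ParamMaps",
    "BBBoResult",
    "RegistrationOutcome",
    "register_series",
    "fit_brain",
    "classify_bbbo",
    "bbbo_volume",
    "group_ratio",
]

#: 26-connectivity structuring element for 3D cluster labeling
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelDims:
    """Voxel edge lengths in mm."""

    dx: float = 0.39
    dy: float = 0.39
    dz: float = 0.4

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel dimensions must be > 0")

    @property
    def volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz


@dataclass(frozen=True)
class DceSeries:
    """4D post-contrast T1 series: (x, y, z, frame) + times + geometry."""

    volumes: np.ndarray
    times: AcquisitionTimes
    voxel_dims: VoxelDims = VoxelDims()

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes)
        if v.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, frame)")
        if v.shape[3] != len(self.times):
            raise ValueError(
                f"frame count {v.shape[3]} != number of times {len(self.times)}"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("intensities must be finite and >= 0")
        object.__setattr__(self, "volumes", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]


@dataclass(frozen=True)
class ParamMaps:
    """Voxelwise kinetic summary maps (NaN outside ``fitted_mask``)."""

    dyn_map: np.ndarray
    tt_map: np.ndarray
    aot_map: np.ndarray
    r2_map: np.ndarray
    fitted_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.fitted_mask.shape
        for m in (self.dyn_map, self.tt_map, self.aot_map, self.r2_map):
            if m.shape != shape:
                raise ValueError("all maps must share the mask's spatial shape")


@dataclass(frozen=True)
class BBBoResult:
    """Binary BBBo mask plus its cluster inventory and volume summary."""

    mask: np.ndarray
    clusters: tuple  # of (label, voxel_count), largest first
    n_voxels: int
    volume_mm3: float
    label_map: np.ndarray


@dataclass(frozen=True)
class RegistrationOutcome:
    series: "DceSeries"
    transforms: tuple  # per moving frame: dict with parameters + status


def register_series(series: DceSeries, max_iterations: int = 200) -> RegistrationOutcome:
    """Rigidly (6-DOF) align every frame to the first post-contrast frame.

    Uses a correlation metric with linear interpolation.  A frame whose
    registration diverges is passed through unaligned and flagged in the
    transform log.
    """
    import SimpleITK as sitk

    if series.volumes.shape[3] < 2:
        raise ValueError("registration requires at least 2 frames")

    dims = series.voxel_dims
    spacing = (dims.dx, dims.dy, dims.dz)

    def to_img(vol: np.ndarray) -> "sitk.Image":
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.transpose(2, 1, 0)).astype(np.float64))
        img.SetSpacing(spacing)
        return img

    fixed = to_img(series.volumes[..., 0])
    aligned = np.empty_like(series.volumes, dtype=float)
    aligned[..., 0] = series.volumes[..., 0]
    logs = [{"frame": 0, "status": "reference", "translation_mm": (0.0, 0.0, 0.0),
             "rotation_rad": (0.0, 0.0, 0.0)}]

    for fr in range(1, series.volumes.shape[3]):
        moving = to_img(series.volumes[..., fr])
        try:
            initial = sitk.CenteredTransformInitializer(
                fixed, moving, sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            )
            reg = sitk.ImageRegistrationMethod()
            reg.SetMetricAsCorrelation()
            reg.SetInterpolator(sitk.sitkLinear)
            reg.SetOptimizerAsRegularStepGradientDescent(
                learningRate=1.0, minStep=1e-5,
                numberOfIterations=max_iterations,
                relaxationFactor=0.5,
            )
            reg.SetOptimizerScalesFromPhysicalShift()
            reg.SetInitialTransform(initial, inPlace=False)
            transform = reg.Execute(fixed, moving)
            out = sitk.Resample(moving, fixed, transform, sitk.sitkLinear, 0.0)
            arr = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
            aligned[..., fr] = np.clip(arr, 0.0, None)
            p = transform.GetParameters()  # (rx, ry, rz, tx, ty, tz)
            logs.append({
                "frame": fr, "status": "registered",
                "rotation_rad": tuple(p[:3]), "translation_mm": tuple(p[3:]),
                "metric": float(reg.GetMetricValue()),
            })
        except RuntimeError as exc:
            warnings.warn(f"registration diverged on frame {fr}: {exc}")
            aligned[..., fr] = series.volumes[..., fr]
            logs.append({"frame": fr, "status": "failed", "error": str(exc)})

    out_series = DceSeries(aligned, series.times, series.voxel_dims)
    return RegistrationOutcome(series=out_series, transforms=tuple(logs))


# ---------------------------------------------------------------------------
# vectorized voxelwise fitting

def _bases(t: np.ndarray, x2, x4, variant: str):
    """Model basis functions s1(t; x2), s2(t; x4) with broadcasting."""
    s1 = t * np.exp(-t / x2)
    e4 = np.exp(-t / x4)
    s2 = e4 if variant == "accumulation" else 1.0 - e4
    return s1, s2, e4


def _model_batch(params: np.ndarray, t: np.ndarray, variant: str) -> np.ndarray:
    """Evaluate the model for params (N, 5) at times t (T,) -> (N, T)."""
    x1, x2, x3, x4, x5 = (params[:, i][:, None] for i in range(5))
    s1, s2, _ = _bases(t[None, :], x2, x4, variant)
    return x1 * s1 + x3 * s2 + x5


def _varpro_grid_fit(Y: np.ndarray, t: np.ndarray, config: FitConfig) -> np.ndarray:
    """Variable-projection sweep: best (x2, x4) grid node per voxel."""
    x2_grid = np.geomspace(config.tau_min, min(60.0, config.x2_max), 16)
    x4_grid = np.geomspace(config.tau_min, min(60.0, config.x4_max), 12)
    n = Y.shape[0]
    best_sse = np.full(n, np.inf)
    best = np.zeros((n, 5))
    Yt = Y.T  # (T, N)
    for x2 in x2_grid:
        for x4 in x4_grid:
            s1, s2, _ = _bases(t, x2, x4, config.variant)
            B = np.column_stack([s1, s2, np.ones_like(t)])  # (T, 3)
            coef, *_ = np.linalg.lstsq(B, Yt, rcond=None)  # (3, N)
            if np.isfinite(config.x1_min):
                # re-solve the (x3, x5) subproblem where x1 hits its bound
                low = coef[0] < config.x1_min
                if np.any(low):
                    rhs = Yt[:, low] - config.x1_min * s1[:, None]
                    c2, *_ = np.linalg.lstsq(B[:, 1:], rhs, rcond=None)
                    coef[0, low] = config.x1_min
                    coef[1:, low] = c2
            resid = B @ coef - Yt
            sse = np.einsum("tn,tn->n", resid, resid)
            better = sse < best_sse
            if np.any(better):
                best_sse[better] = sse[better]
                best[better, 0] = coef[0, better]
                best[better, 1] = x2
                best[better, 2] = coef[1, better]
                best[better, 3] = x4
                best[better, 4] = coef[2, better]
    return best


def _jacobian_batch(params: np.ndarray, t: np.ndarray, variant: str) -> np.ndarray:
    x1, x2, x3, x4, _ = (params[:, i][:, None] for i in range(5))
    tb = t[None, :]
    s1, s2, e4 = _bases(tb, x2, x4, variant)
    J = np.empty((params.shape[0], t.size, 5))
    J[:, :, 0] = s1
    J[:, :, 1] = x1 * s1 * tb / x2**2
    J[:, :, 2] = s2
    sign = 1.0 if variant == "accumulation" else -1.0
    J[:, :, 3] = sign * x3 * e4 * tb / x4**2
    J[:, :, 4] = 1.0
    return J


def _refine_lm(
    Y: np.ndarray,
    t: np.ndarray,
    params0: np.ndarray,
    config: FitConfig,
    n_iter: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Levenberg-Marquardt over all voxels with per-voxel damping."""
    lb = np.array([config.x1_min, config.tau_min, -np.inf, config.tau_min, -np.inf])
    ub = np.array([np.inf, config.x2_max, np.inf, config.x4_max, np.inf])
    params = np.clip(params0, lb, ub)
    resid = _model_batch(params, t, config.variant) - Y
    sse = np.einsum("nt,nt->n", resid, resid)
    lam = np.full(Y.shape[0], 1e-3)
    eye = np.eye(5)
    for _ in range(n_iter):
        J = _jacobian_batch(params, t, config.variant)
        g = np.einsum("ntk,nt->nk", J, resid)
        H = np.einsum("nti,ntj->nij", J, J)
        diag = np.einsum("nii->ni", H)
        A = H + lam[:, None, None] * (diag[:, :, None] * eye) + 1e-12 * eye
        try:
            step = np.linalg.solve(A, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A = A + 1e-8 * eye
            step = np.linalg.solve(A, -g[..., None])[..., 0]
        trial = np.clip(params + step, lb, ub)
        resid_trial = _model_batch(trial, t, config.variant) - Y
        sse_trial = np.einsum("nt,nt->n", resid_trial, resid_trial)
        accept = sse_trial <= sse
        params[accept] = trial[accept]
        resid[accept] = resid_trial[accept]
        sse[accept] = sse_trial[accept]
        lam = np.where(accept, np.maximum(lam * 0.3, 1e-10), np.minimum(lam * 5.0, 1e8))
    return params, sse


def _summaries_batch(
    params: np.ndarray, window: tuple[float, float], config: FitConfig,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense-grid Dyn/TT/AOT for params (N, 5), chunked to bound memory."""
    grid = np.linspace(window[0], window[1], config.grid_points)
    length = window[1] - window[0]
    n = params.shape[0]
    dyn = np.empty(n)
    tt = np.empty(n)
    aot = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        f = _model_batch(params[lo:hi], grid, config.variant)  # (c, G)
        dyn[lo:hi] = 100.0 * (f.max(axis=1) - f[:, 0])
        above = f >= 1.0 + config.threshold
        tt[lo:hi] = above.mean(axis=1) * length
        excess = np.clip(f - (1.0 + config.threshold), 0.0, None)
        aot[lo:hi] = np.trapezoid(excess, grid, axis=1)
    return dyn, tt, aot


def fit_brain(
    series: DceSeries,
    brain_mask: np.ndarray,
    config: FitConfig = FitConfig(),
    baseline_eps: Optional[float] = None,
) -> ParamMaps:
    """Normalize and fit every in-mask voxel; return Dyn/TT/AOT/r2 maps.

    Voxels whose first-frame intensity is at or below the baseline noise
    floor are flagged unfittable and excluded from ``fitted_mask``.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != series.shape:
        raise ValueError("brain mask shape must match the series' spatial shape")

    if baseline_eps is None:
        dt = series.volumes.dtype
        if np.issubdtype(dt, np.integer):
            baseline_eps = 1e-6 * float(np.iinfo(dt).max)
        else:
            baseline_eps = 1e-6 * float(max(series.volumes[..., 0].max(), 1.0))

    shape = series.shape
    nan_map = np.full(shape, np.nan)
    dyn_map, tt_map, aot_map, r2_map = (nan_map.copy() for _ in range(4))
    fitted = np.zeros(shape, dtype=bool)

    idx = np.nonzero(brain_mask)
    if idx[0].size == 0:
        return ParamMaps(dyn_map, tt_map, aot_map, r2_map, fitted)

    raw = series.volumes[idx].astype(float)  # (N, T)
    baseline = raw[:, 0]
    ok = baseline > baseline_eps
    if not np.any(ok):
        return ParamMaps(dyn_map, tt_map, aot_map, r2_map, fitted)
    Y = raw[ok] / baseline[ok, None]
    t = series.times.times

    params0 = _varpro_grid_fit(Y, t, config)
    params, sse = _refine_lm(Y, t, params0, config)

    sst = np.einsum("nt,nt->n", Y - Y.mean(axis=1, keepdims=True),
                    Y - Y.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / sst
    flat = sst <= 1e-15
    r2[flat] = np.where(sse[flat] <= 1e-15, 1.0, 0.0)

    dyn, tt, aot = _summaries_batch(params, series.times.window, config)

    sub = tuple(ax[ok] for ax in idx)
    dyn_map[sub] = dyn
    tt_map[sub] = tt
    aot_map[sub] = aot
    r2_map[sub] = r2
    fitted[sub] = True
    return ParamMaps(dyn_map, tt_map, aot_map, r2_map, fitted)


def _structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def classify_bbbo(
    maps: ParamMaps,
    r2_min: float = 0.6,
    dyn_min: float = 5.0,
    min_cluster: int = 30,
    voxel_dims: VoxelDims = VoxelDims(1.0, 1.0, 1.0),
    connectivity: int = 6,
) -> BBBoResult:
    """Classify BBBo voxels: r2 > r2_min, Dyn > dyn_min, cluster >= min_cluster.

    Passing voxels are labeled by 3D connected components (face connectivity
    by default; 6/18/26 selectable); components smaller than ``min_cluster``
    voxels are discarded.  Returned cluster labels are 1..K ordered by
    decreasing size.
    """
    with np.errstate(invalid="ignore"):
        passing = (
            maps.fitted_mask
            & (np.nan_to_num(maps.r2_map, nan=-np.inf) > r2_min)
            & (np.nan_to_num(maps.dyn_map, nan=-np.inf) > dyn_min)
        )
    labels, n_comp = ndimage.label(passing, structure=_structure(connectivity))
    label_map = np.zeros_like(labels)
    clusters = []
    if n_comp:
        counts = np.bincount(labels.ravel())[1:]
        kept = [(c, lab) for lab, c in zip(range(1, n_comp + 1), counts)
                if c >= min_cluster]
        kept.sort(key=lambda pair: (-pair[0], pair[1]))
        for new_label, (count, old_label) in enumerate(kept, start=1):
            label_map[labels == old_label] = new_label
            clusters.append((new_label, int(count)))
    mask = label_map > 0
    n_voxels = int(mask.sum())
    return BBBoResult(
        mask=mask,
        clusters=tuple(clusters),
        n_voxels=n_voxels,
        volume_mm3=n_voxels * voxel_dims.volume_mm3,
        label_map=label_map,
    )


def bbbo_volume(result: BBBoResult, dims: VoxelDims) -> float:
    """BBBo volume in mm^3: voxel count x voxel volume."""
    return result.n_voxels * dims.volume_mm3


def group_ratio(mean_treated: float, mean_sham: float) -> int:
    """Fold difference between group-mean BBBo extents, nearest integer."""
    if mean_sham <= 0:
        raise ZeroDivisionError("sham group mean must be > 0 for a fold ratio")
    return round(mean_treated / mean_sham)
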