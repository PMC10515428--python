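"""Synthetic inputs with the statistical structure the analysis assumes.

Three generator families, all pure functions of their spec + seed:

* 4D DCE phantoms — an ellipsoidal "brain" scanned at >= 7 post-contrast
  time points within 30 min at 0.39 x 0.39 x 0.4 mm voxels.  "Treated"
  phantoms carry clustered cortical enhancement (>= 30-voxel blobs in the
  outer shell of the ellipsoid, slow-accumulation kinetics with Dyn in a
  configurable 6-30 % range); "sham" phantoms carry only sparse isolated
  enhancing components below the 30-voxel cluster threshold.  Ground-truth
  Dyn/TT/AOT maps and the true BBBo mask are computed analytically from the
  generating kinetic parameters.
* dose-response plates — 4PL confluence curves with >= 6 wells per
  concentration plus Gaussian well noise, clipped to [0, 100] %.
* efficacy cohorts — per-animal baseline tumor volumes and growth-rate
  draws for two treatment groups.

Intensity noise is Gaussian on the signal (fractional sigma of the local
baseline); a Rician magnitude option is available but the default keeps the
ground truth analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bbbo import DceSeries, VoxelDims
from .kinetics import (
    AcquisitionTimes,
    KineticParams,
    compute_aot,
    compute_dyn,
    compute_tt,
    eval_model,
)
from .pharmacology import DoseResponsePlate, four_param_logistic

__all__ = [
    "ClusterTruth",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_sham_phantom",
    "generate_dose_response",
    "generate_efficacy_cohort",
    "DEFAULT_TIMES",
]

#: default acquisition schedule: 8 frames within [1, 30] min post injection
DEFAULT_TIMES = (1.0, 2.5, 5.0, 8.0, 12.0, 17.0, 23.0, 30.0)


@dataclass(frozen=True)
class ClusterTruth:
    """One generated enhancing component and its true summaries."""

    label: int
    center: tuple[int, int, int]
    n_voxels: int
    params: KineticParams
    dyn: float
    tt: float
    aot: float
    is_bbbo: bool  # False for sub-cluster-size (sham-like) components


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic DCE brain."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: VoxelDims = VoxelDims()
    times: tuple = DEFAULT_TIMES
    n_clusters: int = 3
    cluster_radius: tuple[float, float] = (2.0, 3.2)  # voxels
    dyn_range: tuple[float, float] = (6.0, 30.0)  # percent
    shell: tuple[float, float] = (0.78, 0.88)  # normalized ellipsoid radius
    n_sham_components: int = 6
    sham_component_size: tuple[int, int] = (1, 5)  # voxels, always < 30
    noise_sigma: float = 0.02  # fraction of the local baseline
    rician: bool = False
    brain_baseline: float = 1000.0
    air_baseline: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("phantom grid too small")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.sham_component_size[1] >= 30:
            raise ValueError("sham components must stay below the 30-voxel cluster size")

    @property
    def acquisition_times(self) -> AcquisitionTimes:
        return AcquisitionTimes(np.asarray(self.times, dtype=float))


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    dyn_map: np.ndarray
    tt_map: np.ndarray
    aot_map: np.ndarray
    bbbo_mask: np.ndarray
    brain_mask: np.ndarray
    clusters: tuple  # of ClusterTruth
    spec: PhantomSpec


def _ellipsoid(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Brain mask and normalized ellipsoid radius rho for every voxel."""
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.42 * n for n in shape]
    rho = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))
    return rho <= 1.0, rho


def _ball_voxels(center: np.ndarray, radius: float, shape) -> np.ndarray:
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 1).astype(int) + 1, shape)
    sub = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    pts = np.stack([s.ravel() for s in sub], axis=1)
    d2 = np.sum((pts - center) ** 2, axis=1)
    return pts[d2 <= radius**2]


def _draw_cluster_params(
    rng: np.random.Generator,
    times: AcquisitionTimes,
    dyn_range: tuple[float, float],
    max_tries: int = 50,
) -> tuple[KineticParams, float]:
    """Draw slow-accumulation kinetics with true Dyn inside ``dyn_range``.

    x1 is rescaled by fixed-point iteration toward a target Dyn; x5 is
    solved so the normalized curve equals 1 exactly at the first frame.
    """
    t1 = times.times[0]
    window = times.window
    for _ in range(max_tries):
        x2 = rng.uniform(6.0, 20.0)
        x4 = rng.uniform(10.0, 40.0)
        x3 = rng.uniform(-0.03, 0.03)
        target = rng.uniform(*dyn_range)
        x1 = 0.01
        for _ in range(6):
            x5 = 1.0 - x1 * t1 * np.exp(-t1 / x2) - x3 * np.exp(-t1 / x4)
            p = KineticParams(x1, x2, x3, x4, x5)
            dyn = compute_dyn(p, window)
            if dyn <= 1e-9:
                x1 *= 3.0
                continue
            x1 *= target / dyn
        x5 = 1.0 - x1 * t1 * np.exp(-t1 / x2) - x3 * np.exp(-t1 / x4)
        p = KineticParams(x1, x2, x3, x4, x5)
        dyn = compute_dyn(p, window)
        if dyn_range[0] - 0.25 <= dyn <= dyn_range[1] + 0.25:
            return p, dyn
    raise RuntimeError("failed to draw cluster kinetics in the requested Dyn range")


def _place_component(
    rng: np.random.Generator,
    spec: PhantomSpec,
    occupied: list[tuple[np.ndarray, float]],
    radius: float,
    max_tries: int = 500,
) -> np.ndarray:
    """Sample a component center in the cortical shell, away from others."""
    semi = np.array([0.42 * n for n in spec.shape])
    center0 = np.array([(n - 1) / 2.0 for n in spec.shape])
    # keep the whole component (plus a 1-voxel margin) inside the brain:
    # on small grids this caps the shell below the requested range
    rho_max = 0.99 - (radius + 1.0) / semi.min()
    if rho_max <= 0.1:
        raise ValueError("phantom grid too small for the requested component size")
    rho_hi = min(spec.shell[1], rho_max)
    rho_lo = min(spec.shell[0], max(rho_hi - 0.05, 0.05))
    for _ in range(max_tries):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rho = rng.uniform(rho_lo, rho_hi)
        center = center0 + rho * direction * semi
        if all(
            np.linalg.norm(center - c) > radius + r + 3.0 for c, r in occupied
        ):
            return center
    raise RuntimeError("could not place a non-adjacent enhancing component")


def generate_phantom(spec: PhantomSpec) -> tuple[DceSeries, PhantomTruth]:
    """Generate a treated phantom: clustered cortical enhancement + truth.

    Background voxels carry flat curves (pre-noise); each enhancing
    component shares one set of kinetic parameters.  Components smaller
    than 30 voxels (the ``n_sham_components`` isolated spots) are excluded
    from the true BBBo mask.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.acquisition_times
    t = times.times
    brain, _ = _ellipsoid(spec.shape)

    dyn_map = np.zeros(spec.shape)
    tt_map = np.zeros(spec.shape)
    aot_map = np.zeros(spec.shape)
    bbbo_mask = np.zeros(spec.shape, dtype=bool)
    curve_field = np.ones(spec.shape + (t.size,))

    occupied: list[tuple[np.ndarray, float]] = []
    clusters: list[ClusterTruth] = []
    label = 0

    for _ in range(spec.n_clusters):
        radius = rng.uniform(*spec.cluster_radius)
        center = _place_component(rng, spec, occupied, radius)
        voxels = _ball_voxels(center, radius, spec.shape)
        while voxels.shape[0] < 30:  # spheres of the smallest radius can
            radius += 0.2             # undershoot 30 voxels on the lattice
            voxels = _ball_voxels(center, radius, spec.shape)
        occupied.append((center, radius))
        params, dyn = _draw_cluster_params(rng, times, spec.dyn_range)
        tt = compute_tt(params, times.window)
        aot = compute_aot(params, times.window)
        curve = eval_model(params, t)
        ix = tuple(voxels.T)
        curve_field[ix] = curve
        dyn_map[ix] = dyn
        tt_map[ix] = tt
        aot_map[ix] = aot
        bbbo_mask[ix] = True
        label += 1
        clusters.append(ClusterTruth(
            label=label, center=tuple(int(round(c)) for c in center),
            n_voxels=voxels.shape[0], params=params,
            dyn=dyn, tt=tt, aot=aot, is_bbbo=True,
        ))

    for _ in range(spec.n_sham_components):
        size = int(rng.integers(spec.sham_component_size[0],
                                spec.sham_component_size[1] + 1))
        center = _place_component(rng, spec, occupied, radius=2.0)
        occupied.append((center, 2.0))
        base = np.round(center).astype(int)
        voxels = [base]
        steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        while len(voxels) < size:
            step = steps[rng.integers(0, 6)]
            cand = voxels[rng.integers(0, len(voxels))] + step
            if not any(np.array_equal(cand, v) for v in voxels):
                voxels.append(cand)
        voxels = np.clip(np.array(voxels), 0, np.array(spec.shape) - 1)
        params, dyn = _draw_cluster_params(rng, times, spec.dyn_range)
        tt = compute_tt(params, times.window)
        aot = compute_aot(params, times.window)
        ix = tuple(voxels.T)
        curve_field[ix] = eval_model(params, t)
        dyn_map[ix] = dyn
        tt_map[ix] = tt
        aot_map[ix] = aot
        label += 1
        clusters.append(ClusterTruth(
            label=label, center=tuple(int(c) for c in base),
            n_voxels=len(voxels), params=params,
            dyn=dyn, tt=tt, aot=aot, is_bbbo=False,
        ))

    baseline = np.where(brain, spec.brain_baseline, spec.air_baseline)
    volumes = baseline[..., None] * curve_field
    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * baseline[..., None]
        if spec.rician:
            n1 = rng.normal(0.0, sigma, volumes.shape)
            n2 = rng.normal(0.0, sigma, volumes.shape)
            volumes = np.sqrt((volumes + n1) ** 2 + n2**2)
        else:
            volumes = volumes + rng.normal(0.0, sigma, volumes.shape)
    volumes = np.clip(volumes, 0.0, None).astype(np.float32)

    series = DceSeries(volumes=volumes, times=times, voxel_dims=spec.voxel_dims)
    truth = PhantomTruth(
        dyn_map=dyn_map, tt_map=tt_map, aot_map=aot_map,
        bbbo_mask=bbbo_mask, brain_mask=brain,
        clusters=tuple(clusters), spec=spec,
    )
    return series, truth


def generate_sham_phantom(spec: PhantomSpec) -> tuple[DceSeries, PhantomTruth]:
    """Generate a sham phantom: only sub-cluster-size isolated enhancement."""
    sham_spec = replace(spec, n_clusters=0,
                        n_sham_components=max(spec.n_sham_components, 1))
    series, truth = generate_phantom(sham_spec)
    assert not truth.bbbo_mask.any()
    return series, truth


def generate_dose_response(
    true_ic50: float = 7.1,
    hill: float = 1.0,
    top: float = 90.0,
    bottom: float = 5.0,
    concentrations: Optional[Sequence[float]] = None,
    wells: int = 6,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> DoseResponsePlate:
    """Simulate an endpoint-confluence plate from a 4PL truth.

    Defaults emulate the in vitro design: 6 wells per concentration on a
    3-fold serial dilution spanning the transition, with per-well Gaussian
    noise (confluence percentage points) clipped to [0, 100].
    """
    if concentrations is None:
        concentrations = 0.3 * 3.0 ** np.arange(8)  # 0.3 .. 656 nM
    rng = np.random.default_rng(seed)
    rows = []
    for conc in np.asarray(concentrations, dtype=float):
        mean = four_param_logistic(conc, true_ic50, hill, top, bottom)
        for w in range(wells):
            val = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((conc, w, float(np.clip(val, 0.0, 100.0))))
    df = pd.DataFrame(rows, columns=["concentration_nM", "well", "confluence_pct"])
    return DoseResponsePlate(df)


def generate_efficacy_cohort(
    n_per_group: int = 5,
    mean_rate_a: float = 1.18,
    mean_rate_b: float = 2.6,
    sd: tuple[float, float] = (0.313, 0.984),
    baseline_mean: tuple[float, float] = (8.09, 5.76),
    baseline_sd: tuple[float, float] = (3.47, 3.26),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-group tumor-growth cohort table.

    Group a = combined treatment, group b = drug only.  Default rate means
    1.18 and 2.6 with per-group SDs back-computed from the reported SEMs at
    n = 5 (0.14 * sqrt(5), 0.44 * sqrt(5)); baseline volumes are normal
    draws (mm^3) truncated at a small positive floor, and follow-up volume
    is baseline x an (also truncated) growth-rate draw.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean_rate, rate_sd, v_mean, v_sd in (
        ("combined", mean_rate_a, sd[0], baseline_mean[0], baseline_sd[0]),
        ("drug_only", mean_rate_b, sd[1], baseline_mean[1], baseline_sd[1]),
    ):
        for i in range(n_per_group):
            v0 = max(rng.normal(v_mean, v_sd), 0.5)
            rate = max(rng.normal(mean_rate, rate_sd), 0.05) if rate_sd > 0 else mean_rate
            rows.append((f"{group}_{i:02d}", group, v0, v0 * rate))
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "v_baseline_mm3", "v_day8_mm3"]
    )
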