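"""Deterministic synthetic-data generators.

Three factories produce every input the dosimetry pipelines need, so no
patient data or download is ever required:

* :func:`make_synthetic_patient` — a digital SIRT-like case: body, liver and
  lungs as ellipsoids in CT (HU), activity concentrated in one liver lobe
  with a hot spherical lesion and a small lung shunt, log-normal activity
  texture, and a SPECT-like Gaussian blur;
* :func:`make_benchmark_sphere` — the 60 g water benchmark sphere with a
  uniform source, for S-value validation;
* :func:`make_toy_kernel` — compact analytic kernels for exact mosaicking
  equivalence tests with a deterministic linear dose operator.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluate import VOISet
from .grid import (
    ROLE_ACTIVITY,
    ROLE_DENSITY,
    ROLE_HU,
    ROLE_TIA,
    VoxelGrid,
)
from .kernel import VoxelKernel

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

AIR_HU, LUNG_HU, BODY_HU, LIVER_HU, BONE_HU = -1000.0, -740.0, 0.0, 60.0, 400.0
AIR_DENSITY, WATER_DENSITY = 0.00121, 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity parameters of the synthetic SIRT patient.

    Organ centres are in voxel indices, semi-axes/radii in mm.  Defaults
    emulate a right-lobe treatment on the post-therapy bremsstrahlung SPECT
    grid (64 x 64 x 42 voxels at 9.59 mm) with a 10 mm resolution blur.
    """

    shape: tuple[int, int, int] = (64, 64, 42)
    voxel_mm: float = 9.59
    body_center: tuple[float, float, float] = (31.5, 31.5, 20.5)
    body_semiaxes_mm: tuple[float, float, float] = (230.0, 160.0, 260.0)
    liver_center: tuple[float, float, float] = (38.0, 30.0, 30.0)
    liver_semiaxes_mm: tuple[float, float, float] = (110.0, 95.0, 80.0)
    lung_centers: tuple[tuple[float, float, float], ...] = ((22.0, 30.0, 7.0), (41.0, 30.0, 7.0))
    lung_semiaxes_mm: tuple[float, float, float] = (70.0, 60.0, 55.0)
    lesion_center: tuple[float, float, float] = (42.0, 28.0, 32.0)
    lesion_radius_mm: float = 28.0
    lesion_multiplier: float = 3.0
    treated_lobe: str = "right"
    include_spine: bool = True
    spine_center_xy: tuple[float, float] = (31.5, 16.0)
    spine_radius_mm: float = 15.0
    shunt_fraction: float = 0.05
    administered_gbq: float = 1.2
    texture_sigma: float = 0.4
    blur_fwhm_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shunt_fraction <= 0.2:
            raise ValueError("shunt fraction must be in [0, 0.2]")
        if self.administered_gbq < 0:
            raise ValueError("administered activity must be >= 0")
        if self.treated_lobe not in ("right", "left"):
            raise ValueError("treated_lobe must be 'right' or 'left'")


def _ellipsoid(shape, voxel_mm, center_vox, semiaxes_mm) -> np.ndarray:
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    r2 = sum(((idx[a] - center_vox[a]) * voxel_mm / semiaxes_mm[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def make_synthetic_patient(spec: PhantomSpec = PhantomSpec()
                           ) -> tuple[VoxelGrid, VoxelGrid, VOISet]:
    """Build (CT [HU], activity [Bq], VOI labels) for the synthetic patient.

    The activity map integrates exactly to the administered activity before
    the blur; the blur conserves it up to the (reported-negligible) mass
    clipped at the grid edge.  VOI labels: 1 remainder of body, 2 liver,
    3 lungs; 0 outside the body.
    """
    shape, v = spec.shape, spec.voxel_mm
    spacing = (v, v, v)

    body = _ellipsoid(shape, v, spec.body_center, spec.body_semiaxes_mm)
    liver = _ellipsoid(shape, v, spec.liver_center, spec.liver_semiaxes_mm) & body
    lungs = np.zeros(shape, dtype=bool)
    for c in spec.lung_centers:
        lungs |= _ellipsoid(shape, v, c, spec.lung_semiaxes_mm)
    lungs &= body & ~liver
    lesion = _ellipsoid(shape, v, spec.lesion_center, (spec.lesion_radius_mm,) * 3) & liver
    if not (liver.any() and lungs.any() and body.any()):
        raise ValueError("organs fall outside the grid")

    ct = np.full(shape, AIR_HU)
    ct[body] = BODY_HU
    if spec.include_spine:
        idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        spine = ((idx[0] - spec.spine_center_xy[0]) ** 2 +
                 (idx[1] - spec.spine_center_xy[1]) ** 2) * v**2 <= spec.spine_radius_mm**2
        ct[spine & body] = BONE_HU
    ct[lungs] = LUNG_HU
    ct[liver] = LIVER_HU

    # activity: treated lobe (+ hot lesion) with log-normal texture, lung shunt
    rng = np.random.default_rng(spec.seed)
    cx = spec.liver_center[0]
    half = np.arange(shape[0])[:, None, None] >= cx if spec.treated_lobe == "right" \
        else np.arange(shape[0])[:, None, None] <= cx
    lobe = liver & np.broadcast_to(half, shape)
    activity = np.zeros(shape)
    texture = rng.lognormal(mean=0.0, sigma=spec.texture_sigma, size=shape)
    activity[lobe] = texture[lobe]
    activity[lesion & lobe] *= spec.lesion_multiplier
    a_total = spec.administered_gbq * 1e9
    if activity.sum() > 0:
        activity *= (1.0 - spec.shunt_fraction) * a_total / activity.sum()
    if spec.shunt_fraction > 0 and lungs.any():
        activity[lungs] = spec.shunt_fraction * a_total / lungs.sum()
    if spec.blur_fwhm_mm > 0:
        sigma_vox = spec.blur_fwhm_mm * _FWHM_TO_SIGMA / v
        activity = ndimage.gaussian_filter(activity, sigma_vox, mode="constant")

    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = 1
    labels[liver] = 2
    labels[lungs] = 3
    vois = VOISet(labels, {"rob": 1, "liver": 2, "lungs": 3})
    return (VoxelGrid(ct, spacing, role=ROLE_HU),
            VoxelGrid(activity, spacing, role=ROLE_ACTIVITY),
            vois)


def make_benchmark_sphere(mass_g: float = 60.0, voxel_mm: float = 2.0,
                          margin_voxels: int = 3
                          ) -> tuple[VoxelGrid, VoxelGrid, np.ndarray]:
    """Voxelised water sphere of the requested mass in an air box.

    Radius from ``r = (3 m / 4 pi rho_water)^(1/3)``; the returned TIA grid
    is uniform over the sphere voxels.  Raises if the sphere is not resolved
    by at least 5 voxels across its diameter.
    """
    if mass_g <= 0 or voxel_mm <= 0:
        raise ValueError("mass and voxel size must be positive")
    r_mm = (3.0 * mass_g / (4.0 * np.pi * WATER_DENSITY)) ** (1.0 / 3.0) * 10.0
    if 2.0 * r_mm / voxel_mm < 5.0:
        raise ValueError("sphere under-resolved: < 5 voxels across the diameter")
    n = int(np.ceil(2.0 * r_mm / voxel_mm)) + 2 * margin_voxels
    c = (n - 1) / 2.0
    idx = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
    mask = sum((idx[a] - c) ** 2 for a in range(3)) * voxel_mm**2 <= r_mm**2
    density = np.where(mask, WATER_DENSITY, AIR_DENSITY)
    tia = mask.astype(float)
    spacing = (voxel_mm,) * 3
    return (VoxelGrid(density, spacing, role=ROLE_DENSITY),
            VoxelGrid(tia, spacing, role=ROLE_TIA),
            mask)


def make_toy_kernel(half_width: int, voxel_mm: float = 9.59,
                    shape: str = "tent") -> VoxelKernel:
    """Analytic compact kernel of edge ``2 half_width + 1`` for exact
    mosaicking tests: 'tent' (separable, strictly decreasing from the
    centre) or 'uniform'.  Normalised to unit sum; half_width 0 is the delta
    kernel."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    edge = 2 * half_width + 1
    if shape == "tent":
        w1 = 1.0 - np.abs(np.arange(edge) - half_width) / (half_width + 1.0)
        k = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    elif shape == "uniform":
        k = np.ones((edge, edge, edge))
    else:
        raise ValueError("shape must be 'tent' or 'uniform'")
    return VoxelKernel(k / k.sum(), voxel_mm, medium="analytic_toy",
                       meta={"shape": shape, "half_width": int(half_width)})
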