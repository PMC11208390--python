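"""Voxel S-value (VSV) kernel dosimetry: kernel generation, TIA convolution
and CT-based density correction.

A voxel S-value kernel is the absorbed dose per decay around a source voxel
in a homogeneous reference medium (ICRP soft tissue, rho = 1.03 g/cm^3, by
default).  Convolving it with a time-integrated-activity map gives a fast
dose estimate; multiplying by the ratio of reference to local density
rescales energy-per-mass for tissues that differ from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .grid import ROLE_DENSITY, ROLE_DOSE, ROLE_TIA, VoxelGrid

MEDIUM_DENSITY = {"icrp_soft_tissue": 1.03, "water": 1.0}
SOFT_TISSUE_DENSITY = MEDIUM_DENSITY["icrp_soft_tissue"]


@dataclass(frozen=True)
class VoxelKernel:
    """Cubic Gy-per-decay kernel with odd edge length.

    The central voxel must be the global maximum (energy is deposited
    closest to the source) and values are non-negative.
    """

    values: np.ndarray
    voxel_mm: float = 9.59
    medium: str = "icrp_soft_tissue"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or len(set(v.shape)) != 1 or v.shape[0] % 2 == 0:
            raise ValueError("kernel must be cubic with odd edge length")
        if np.any(v < 0):
            raise ValueError("kernel values must be non-negative")
        c = v.shape[0] // 2
        if v[c, c, c] < v.max():
            raise ValueError("central voxel must be the global maximum")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "values", v)

    @property
    def edge(self) -> int:
        return self.values.shape[0]


def generate_vsv(
    medium: str = "icrp_soft_tissue",
    edge: int = 25,
    voxel_mm: float = 9.59,
    n_primaries: int = 1_000_000,
    seed: int = 0,
    cutoff_kev: float = 5.0,
    n_batches: int = 1,
) -> VoxelKernel:
    """Monte Carlo voxel S-value kernel: all decays uniform in the central
    voxel of a homogeneous medium; the per-primary dose grid is the Gy per
    decay kernel.  The finer 5 keV cutoff (the kernel-grade range cut) is
    the default here."""
    from .mc import TransportConfig, merge_batches, run_simulation

    if edge < 3 or edge % 2 == 0:
        raise ValueError("edge must be odd and >= 3")
    rho = MEDIUM_DENSITY[medium]
    shape = (edge, edge, edge)
    density = VoxelGrid(np.full(shape, rho), (voxel_mm,) * 3, role=ROLE_DENSITY)
    tia = np.zeros(shape)
    c = edge // 2
    tia[c, c, c] = 1.0
    tia_grid = VoxelGrid(tia, (voxel_mm,) * 3, role=ROLE_TIA)
    config = TransportConfig(cutoff_kev=cutoff_kev, seed=seed)
    tally = run_simulation(tia_grid, density, n_primaries, n_batches, config)
    dose_pp, _ = merge_batches(tally)
    return VoxelKernel(dose_pp.values, voxel_mm, medium,
                       meta={"n_primaries": int(n_primaries), "seed": int(seed),
                             "cutoff_kev": float(cutoff_kev)})


def convolve_tia(tia: VoxelGrid, kernel: VoxelKernel,
                 method: str = "auto") -> VoxelGrid:
    """Linear convolution of a TIA map (decays) with a Gy-per-decay kernel,
    zero boundary, output aligned with the input.

    ``method`` 'direct' is exact floating-point spatial convolution (used
    automatically for small kernels), 'fft' is faster for large ones.
    """
    if abs(tia.spacing[0] - kernel.voxel_mm) > 1e-6 or len(set(tia.spacing)) != 1:
        raise ValueError("TIA voxel size must match the kernel voxel size")
    if method == "auto":
        method = "direct" if kernel.edge <= 11 else "fft"
    if method == "direct":
        out = ndimage.convolve(tia.values, kernel.values, mode="constant", cval=0.0)
    elif method == "fft":
        out = signal.fftconvolve(tia.values, kernel.values, mode="same")
        np.maximum(out, 0.0, out=out)  # clip FFT round-off below zero
    else:
        raise ValueError("method must be 'auto', 'direct' or 'fft'")
    return tia.with_values(out, ROLE_DOSE)


def density_correct(
    dose: VoxelGrid,
    density: VoxelGrid,
    rho_ref: float = SOFT_TISSUE_DENSITY,
    orientation: str = "ref_over_voxel",
    air_threshold: float = 0.05,
) -> VoxelGrid:
    """Rescale a reference-medium dose for local density.

    The default orientation multiplies by ``rho_ref / rho_voxel`` (same
    energy imparted into less mass gives more dose, e.g. lung); the
    alternative ``voxel_over_ref`` multiplies by ``rho_voxel / rho_ref``.
    Voxels below the air threshold are set to zero.
    """
    dose.require_aligned(density)
    if rho_ref <= 0:
        raise ValueError("reference density must be positive")
    rho = density.values
    out = np.zeros_like(dose.values)
    ok = rho >= air_threshold
    if orientation == "ref_over_voxel":
        out[ok] = dose.values[ok] * rho_ref / rho[ok]
    elif orientation == "voxel_over_ref":
        out[ok] = dose.values[ok] * rho[ok] / rho_ref
    else:
        raise ValueError("orientation must be 'ref_over_voxel' or 'voxel_over_ref'")
    return dose.with_values(out, ROLE_DOSE)
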