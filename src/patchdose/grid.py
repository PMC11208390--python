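"""Volume data model and geometry bookkeeping.

A :class:`VoxelGrid` is a 3-D scalar lattice on an axis-aligned grid with
per-axis voxel spacing (mm) and a physical origin (the centre of voxel
``(0, 0, 0)``, in mm).  The same carrier is used for CT (HU), density
(g/cm^3), activity (Bq), time-integrated activity (decays), dose (Gy),
dose per primary, and percent uncertainty; the ``role`` tag records which.

All cross-grid operations require exact alignment (same dims, spacing and
origin).  Voxel index ``(i, j, k)`` maps to physical position
``origin + index * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

# Role tags
ROLE_HU = "HU"
ROLE_DENSITY = "density"
ROLE_ACTIVITY = "activity"
ROLE_TIA = "TIA"
ROLE_DOSE = "dose"
ROLE_DOSE_PER_PRIMARY = "dose_per_primary"
ROLE_UNCERTAINTY = "uncertainty"
ROLE_GENERIC = "generic"

_NONNEGATIVE_ROLES = {ROLE_DENSITY, ROLE_ACTIVITY, ROLE_TIA, ROLE_DOSE,
                      ROLE_DOSE_PER_PRIMARY, ROLE_UNCERTAINTY}


@dataclass
class VoxelGrid:
    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = ROLE_GENERIC

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with all dims >= 1")
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing).repeat(
            3 if np.size(self.spacing) == 1 else 1))[:3]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        self.origin = tuple(float(o) for o in self.origin)
        if self.role in _NONNEGATIVE_ROLES and np.any(self.values < 0):
            raise ValueError(f"{self.role} grid must be non-negative everywhere")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def aligned_with(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=0, atol=tol)
        )

    def require_aligned(self, other: "VoxelGrid") -> None:
        if not self.aligned_with(other):
            raise ValueError("grids are not aligned (dims/spacing/origin differ)")

    def with_values(self, values: np.ndarray, role: str | None = None) -> "VoxelGrid":
        """New grid on the same geometry carrying ``values``."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       role=self.role if role is None else role)

    def index_to_physical(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)


@dataclass(frozen=True)
class PaddingRecord:
    """Voxel pads applied per axis; allows exact inversion of zero-padding."""

    low: tuple[int, int, int]
    high: tuple[int, int, int]
    original_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.low + self.high):
            raise ValueError("pads must be >= 0")

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(o + l + h for o, l, h in
                     zip(self.original_shape, self.low, self.high))


def zero_pad(volume: VoxelGrid, stride: int, extra_per_face: int = 0) -> tuple[VoxelGrid, PaddingRecord]:
    """Pad so an integer number of stride cells fits, plus a symmetric halo.

    The stride padding goes entirely on the high-index side; the
    ``extra_per_face`` halo is symmetric.  New voxels are zero.  Each padded
    dimension equals ``stride * ceil(dim / stride) + 2 * extra_per_face``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if extra_per_face < 0:
        raise ValueError("extra_per_face must be >= 0")
    shape = volume.shape
    high = tuple(int(stride * np.ceil(d / stride)) - d + extra_per_face for d in shape)
    low = (extra_per_face,) * 3
    record = PaddingRecord(low=low, high=high, original_shape=shape)
    padded = np.pad(volume.values, list(zip(low, high)), mode="constant")
    origin = tuple(o - l * s for o, l, s in zip(volume.origin, low, volume.spacing))
    return VoxelGrid(padded, volume.spacing, origin, volume.role), record


def crop_back(volume: VoxelGrid, record: PaddingRecord) -> VoxelGrid:
    """Exact inverse of :func:`zero_pad`."""
    if volume.shape != record.padded_shape:
        raise ValueError("volume shape does not match the padding record")
    sl = tuple(slice(l, l + o) for l, o in zip(record.low, record.original_shape))
    origin = tuple(o + l * s for o, l, s in zip(volume.origin, record.low, volume.spacing))
    return VoxelGrid(volume.values[sl].copy(), volume.spacing, origin, volume.role)


# -- HU -> density / material ---------------------------------------------

MATERIAL_NAMES = ("air", "lung", "soft_tissue", "bone")


@dataclass(frozen=True)
class MaterialTable:
    """Piecewise-linear HU -> density anchors plus binned material assignment.

    The default table reproduces the densities a SIRT dosimetry chain relies
    on (lung ~0.26, soft tissue ~1.0, liver ~1.06) with a short auditable
    anchor list in the spirit of the stoichiometric CT calibration used in
    radiotherapy planning.
    """

    hu: np.ndarray
    density: np.ndarray
    material_edges: tuple[float, ...] = (-950.0, -200.0, 200.0)

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        rho = np.asarray(self.density, dtype=float)
        if hu.size == 0:
            raise ValueError("material table is empty")
        if hu.shape != rho.shape:
            raise ValueError("HU and density anchors must match in length")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(np.diff(rho) < 0):
            raise ValueError("densities must be non-decreasing with HU")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "density", rho)

    @classmethod
    def default(cls) -> "MaterialTable":
        return cls(
            hu=np.array([-1000.0, -740.0, -98.0, 0.0, 60.0, 400.0, 1500.0]),
            density=np.array([0.00121, 0.26, 0.93, 1.000, 1.06, 1.25, 1.90]),
        )


def hu_to_density(ct: VoxelGrid, table: MaterialTable | None = None) -> VoxelGrid:
    """Piecewise-linear HU -> density (g/cm^3), clamped at the extreme anchors."""
    if ct.role != ROLE_HU:
        raise ValueError(f"expected an HU grid, got role {ct.role!r}")
    table = table or MaterialTable.default()
    rho = np.interp(ct.values, table.hu, table.density)
    return ct.with_values(rho, ROLE_DENSITY)


def hu_to_material(ct: VoxelGrid, table: MaterialTable | None = None) -> np.ndarray:
    """Material id per voxel: 0 air, 1 lung, 2 soft tissue, 3 bone."""
    if ct.role != ROLE_HU:
        raise ValueError(f"expected an HU grid, got role {ct.role!r}")
    table = table or MaterialTable.default()
    return np.digitize(ct.values, table.material_edges).astype(np.int8)


# -- resampling ------------------------------------------------------------

def resample_to(
    volume: VoxelGrid,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    mode: str = "linear",
    fill_value: float | None = None,
) -> VoxelGrid:
    """Resample onto a target geometry (linear for continuous data, nearest
    for labels).  Voxels outside the source support are filled with
    ``fill_value`` (default: -1000 for HU, i.e. air outside the scanned
    field of view; 0 otherwise)."""
    if mode not in ("nearest", "linear"):
        raise ValueError("mode must be 'nearest' or 'linear'")
    shape = tuple(int(d) for d in shape)
    if min(shape) < 1:
        raise ValueError("degenerate target shape")
    spacing = tuple(float(s) for s in spacing)
    if min(spacing) <= 0:
        raise ValueError("target spacing must be positive")
    if fill_value is None:
        fill_value = -1000.0 if volume.role == ROLE_HU else 0.0

    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = [
        (origin[a] + idx[a] * spacing[a] - volume.origin[a]) / volume.spacing[a]
        for a in range(3)
    ]
    out = ndimage.map_coordinates(
        volume.values, np.stack(coords), order=1 if mode == "linear" else 0,
        mode="constant", cval=fill_value)
    if volume.role in _NONNEGATIVE_ROLES:
        out = np.maximum(out, 0.0)
    return VoxelGrid(out, spacing, tuple(origin), volume.role)


# -- NIfTI I/O -------------------------------------------------------------

def save_nifti(volume: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NIfTI; the role tag goes into a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values, affine), path)
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    (path.parent / f"{name}.json").write_text(json.dumps({"role": volume.role}))


def load_nifti(path: str | Path, role: str | None = None) -> VoxelGrid:
    """Read a NIfTI volume; spacing/origin come from the affine, the role from
    the JSON sidecar when present (explicit ``role`` wins)."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) grids are supported")
    spacing = tuple(float(abs(affine[a, a])) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    if role is None:
        name = path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        sidecar = path.parent / f"{name}.json"
        role = json.loads(sidecar.read_text())["role"] if sidecar.exists() else ROLE_GENERIC
    return VoxelGrid(np.asarray(img.get_fdata(), dtype=np.float64), spacing, origin, role)
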