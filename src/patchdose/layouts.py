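"""Cropping layouts and mosaicking for patch-based Monte Carlo dosimetry.

Three layouts crop a (TIA, geometry) pair into cubic patches and reassemble
per-patch doses into a whole-volume dose map:

CL1 (naive)
    Source and geometry patches coincide with the non-overlapping stride
    cells; mosaicking places them side by side.  Radiation crossing a patch
    face is lost, depressing the dose at patch borders.
CL2 (overlap-average)
    Source and geometry patches are the stride cells expanded by ``OV``
    voxels per face, so adjacent patches share a ``2 OV``-wide band;
    mosaicking averages the overlapping dose patches over the actual
    coverage multiplicity (2, 4 or 8).  Border emissions are retained but
    voxels near the band edge still lose part of their in-range sources.
CL3 (physics-inspired sum)
    Source patches are the disjoint stride cells zero-padded to the enlarged
    geometry size; every decay is simulated in exactly one patch whose
    geometry extends at least a particle range beyond it, and mosaicking
    *sums* the overlapping dose patches.  For any dose operator with compact
    support not exceeding ``OV`` this reconstructs the whole-volume result
    exactly.

The per-face overlap is sized from the beta range ``R`` and voxel size ``v``
as the even integer closest to ``OV_min = ceil(2R / v)`` (ties upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ROLE_DOSE, PaddingRecord, VoxelGrid, crop_back, zero_pad

CL1, CL2, CL3 = "CL1", "CL2", "CL3"
_LAYOUTS = (CL1, CL2, CL3)


def min_overlap_voxels(range_mm: float, voxel_mm: float) -> int:
    """Even per-face overlap from the particle range: the even integer
    closest to ``OV_min = ceil(2R/v)``, ties and sub-minimum cases resolved
    upward (never below ``OV_min - 1``, never odd)."""
    if range_mm <= 0 or voxel_mm <= 0:
        raise ValueError("range and voxel size must be positive")
    ov_min = int(np.ceil(2.0 * range_mm / voxel_mm))
    return ov_min if ov_min % 2 == 0 else ov_min + 1


@dataclass(frozen=True)
class LayoutSpec:
    """A cropping layout: id, source-patch edge (the tiling stride, voxels)
    and per-face overlap ``OV``.  The geometry-patch edge is derived:
    ``source_edge`` for CL1, ``source_edge + 2 OV`` for CL2/CL3."""

    layout: str
    source_edge: int
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.layout not in _LAYOUTS:
            raise ValueError(f"layout must be one of {_LAYOUTS}")
        if self.source_edge < 1:
            raise ValueError("source_edge must be >= 1")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        if self.layout == CL1 and self.overlap != 0:
            raise ValueError("CL1 has no overlap")
        if self.layout in (CL2, CL3):
            if self.overlap == 0 or self.overlap % 2:
                raise ValueError(f"{self.layout} requires a positive even overlap")

    @property
    def geometry_edge(self) -> int:
        return self.source_edge + (2 * self.overlap if self.layout != CL1 else 0)

    def validate_overlap(self, range_mm: float, voxel_mm: float) -> None:
        """Check OV against the range-based minimum for the isotope in use."""
        if self.layout != CL1 and self.overlap < min_overlap_voxels(range_mm, voxel_mm) - 1:
            raise ValueError("overlap below the range-based minimum")


@dataclass
class PatchSet:
    """Ordered (source patch, geometry patch, origin) triples plus the
    padding needed to invert the crop.

    ``origins`` are the stride-cell origins in padded-canvas voxel indices
    (the geometry patch of CL2/CL3 starts ``OV`` voxels before the cell).
    Traversal order is C-order over the cell lattice and is what "same
    order" reassembly in CL1 refers to.
    """

    layout: LayoutSpec
    padding: PaddingRecord
    canvas_shape: tuple[int, int, int]
    origins: list[tuple[int, int, int]]
    source_patches: list[VoxelGrid]
    geometry_patches: list[VoxelGrid]
    tia_sums: list[float]
    spacing: tuple[float, float, float]
    canvas_origin: tuple[float, float, float]
    primaries: list[int] = field(default_factory=list)

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    def geometry_origin_index(self, i: int) -> tuple[int, int, int]:
        ov = self.layout.overlap
        return tuple(o - ov for o in self.origins[i])


def crop(tia: VoxelGrid, geometry: VoxelGrid, layout: LayoutSpec) -> PatchSet:
    """Crop an aligned (TIA, geometry) pair into patches under a layout.

    Both volumes are zero-padded so an integer number of stride cells fits
    (stride padding on the high side, plus a symmetric ``OV`` halo for
    CL2/CL3).  The geometry volume may be a CT or a density map; the halo is
    filled with zeros either way.
    """
    tia.require_aligned(geometry)
    stride = layout.source_edge
    ov = layout.overlap
    tia_pad, record = zero_pad(tia, stride, extra_per_face=ov)
    geo_pad, _ = zero_pad(geometry, stride, extra_per_face=ov)
    canvas_shape = tia_pad.shape
    cells = [int((canvas_shape[a] - 2 * ov) // stride) for a in range(3)]

    origins: list[tuple[int, int, int]] = []
    sources: list[VoxelGrid] = []
    geos: list[VoxelGrid] = []
    tia_sums: list[float] = []
    gedge = layout.geometry_edge
    for ci in np.ndindex(*cells):
        cell0 = tuple(ov + ci[a] * stride for a in range(3))
        origins.append(cell0)
        cell_sl = tuple(slice(c, c + stride) for c in cell0)
        geo_sl = tuple(slice(c - ov, c - ov + gedge) for c in cell0)
        geo_origin = tuple(geo_pad.origin[a] + (cell0[a] - ov) * geo_pad.spacing[a]
                           for a in range(3))
        geos.append(VoxelGrid(geo_pad.values[geo_sl].copy(), geo_pad.spacing,
                              geo_origin, geometry.role))
        cell_tia = tia_pad.values[cell_sl]
        if layout.layout == CL2:
            src = tia_pad.values[geo_sl].copy()
        elif layout.layout == CL3:
            src = np.zeros((gedge,) * 3)
            src[ov:ov + stride, ov:ov + stride, ov:ov + stride] = cell_tia
        else:
            src = cell_tia.copy()
        src_origin = geo_origin if layout.layout != CL1 else tuple(
            tia_pad.origin[a] + cell0[a] * tia_pad.spacing[a] for a in range(3))
        sources.append(VoxelGrid(src, tia_pad.spacing, src_origin, tia.role))
        tia_sums.append(float(src.sum()))
    return PatchSet(layout=layout, padding=record, canvas_shape=canvas_shape,
                    origins=origins, source_patches=sources,
                    geometry_patches=geos, tia_sums=tia_sums,
                    spacing=tia.spacing, canvas_origin=tia_pad.origin)


def allocate_primaries(total_primaries: int, patch_count: int) -> list[int]:
    """Homogeneous split of the primary budget; the remainder goes to the
    first ``total mod count`` patches, the sum is preserved exactly."""
    if total_primaries < 1 or patch_count < 1:
        raise ValueError("both arguments must be >= 1")
    base, rem = divmod(int(total_primaries), int(patch_count))
    return [base + (1 if i < rem else 0) for i in range(patch_count)]


def scale_patch(patch_dose_per_primary: VoxelGrid, patch_tia_sum: float,
                patch_primaries: int) -> VoxelGrid:
    """Absolute patch dose: per-primary patch dose times the patch's own
    total TIA (the patch-local analogue of the whole-volume scaling)."""
    from .mc import scale_to_absolute

    if patch_primaries <= 0:
        raise ValueError("patch primaries must be positive")
    return scale_to_absolute(patch_dose_per_primary, patch_tia_sum)


def _coverage(patchset: PatchSet) -> np.ndarray:
    cov = np.zeros(patchset.canvas_shape, dtype=np.int32)
    g = patchset.layout.geometry_edge
    for i in range(patchset.n_patches):
        o = patchset.geometry_origin_index(i)
        cov[o[0]:o[0] + g, o[1]:o[1] + g, o[2]:o[2] + g] += 1
    return cov


def mosaic(patch_doses: list[VoxelGrid] | list[np.ndarray],
           patchset: PatchSet) -> VoxelGrid:
    """Reassemble absolute patch doses into the whole-volume dose map.

    CL1 places the disjoint patches side by side; CL2 averages each canvas
    voxel over the geometry patches covering it (multiplicity 1 in patch
    interiors, 2/4/8 in the overlap bands); CL3 sums the overlapping
    patches.  The canvas is finally cropped back to the original dimensions.
    Dose a patch simulation deposited outside its geometry patch has no
    canvas address and is discarded by construction.
    """
    if len(patch_doses) != patchset.n_patches:
        raise ValueError("patch dose count does not match the patch set")
    vals = [p.values if isinstance(p, VoxelGrid) else np.asarray(p, dtype=float)
            for p in patch_doses]
    g = patchset.layout.geometry_edge
    acc = np.zeros(patchset.canvas_shape)
    for i, v in enumerate(vals):
        if v.shape != (g, g, g):
            raise ValueError(f"patch {i} has shape {v.shape}, expected {(g,) * 3}")
        o = patchset.geometry_origin_index(i)
        acc[o[0]:o[0] + g, o[1]:o[1] + g, o[2]:o[2] + g] += v
    if patchset.layout.layout == CL2:
        cov = _coverage(patchset)
        bad = np.unique(cov[cov > 0])
        if not set(bad.tolist()) <= {1, 2, 4, 8}:
            raise ValueError(f"unexpected coverage multiplicities {bad}")
        acc[cov > 0] /= cov[cov > 0]
    canvas = VoxelGrid(acc, patchset.spacing, patchset.canvas_origin, ROLE_DOSE)
    return crop_back(canvas, patchset.padding)


def mosaic_uncertainty(patch_doses: list[VoxelGrid],
                       patch_uncertainties: list[VoxelGrid],
                       patchset: PatchSet) -> VoxelGrid:
    """Percent-uncertainty map of a mosaicked dose.

    Per-patch percent uncertainties are converted to absolute standard
    errors, combined in quadrature across independent patches (divided by
    the coverage count for CL2's average), and re-expressed as a percentage
    of the mosaicked dose.
    """
    g = patchset.layout.geometry_edge
    var = np.zeros(patchset.canvas_shape)
    for i in range(patchset.n_patches):
        se = patch_uncertainties[i].values * patch_doses[i].values / 100.0
        o = patchset.geometry_origin_index(i)
        var[o[0]:o[0] + g, o[1]:o[1] + g, o[2]:o[2] + g] += se ** 2
    if patchset.layout.layout == CL2:
        cov = _coverage(patchset)
        var[cov > 0] /= cov[cov > 0] ** 2
    dose = mosaic(patch_doses, patchset)
    canvas = VoxelGrid(np.sqrt(var), patchset.spacing, patchset.canvas_origin)
    se_grid = crop_back(canvas, patchset.padding)
    unc = np.zeros_like(dose.values)
    pos = dose.values > 0
    unc[pos] = 100.0 * se_grid.values[pos] / dose.values[pos]
    return dose.with_values(unc, "uncertainty")


def overlap_region_mask(layout: LayoutSpec, original_dims: tuple[int, int, int],
                        reference_overlap: int | None = None) -> np.ndarray:
    """Boolean mask of voxels covered by >= 2 geometry patches, in original
    (unpadded) dimensions.

    For CL1 (no overlap of its own) a ``reference_overlap`` must be given;
    the bands of the matching-stride CL2 layout are returned, which is the
    common evaluation region across layouts.
    """
    ov = layout.overlap if layout.layout != CL1 else (reference_overlap or 0)
    if ov <= 0:
        raise ValueError("overlap region undefined: OV = 0 and no reference overlap")
    stride = layout.source_edge
    cov1d = []
    for a in range(3):
        n_cells = int(np.ceil(original_dims[a] / stride))
        padded = n_cells * stride + 2 * ov
        c = np.zeros(padded, dtype=np.int32)
        for i in range(n_cells):
            c[i * stride:i * stride + stride + 2 * ov] += 1
        cov1d.append(c[ov:ov + original_dims[a]])
    cx, cy, cz = np.meshgrid(*cov1d, indexing="ij")
    return (cx * cy * cz) >= 2
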