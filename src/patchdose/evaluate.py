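"""Comparison metrics for dose maps.

Dose estimates are compared against a reference Monte Carlo map through the
percentage difference ``PD = |D_ref - D| / D_ref * 100``, reported as mean
VOI doses, voxel-wise PD maps restricted to soft tissue, and region
statistics over the patch-overlap band versus the rest of the body.  The
figure of merit trading computation time against statistical noise is the
efficiency factor ``EF = 1 / (T * U^2)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .grid import VoxelGrid


@dataclass
class VOISet:
    """Integer label grid plus a name -> label map (0 = outside the body)."""

    labels: np.ndarray
    names: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or np.any(self.labels < 0):
            raise ValueError("labels must be a 3-D non-negative integer grid")
        present = set(np.unique(self.labels).tolist())
        missing = {n for n, l in self.names.items() if l not in present}
        if missing:
            raise ValueError(f"named labels absent from the map: {sorted(missing)}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.names[name]


def evaluation_mask(density: VoxelGrid, rho0: float = 0.05) -> np.ndarray:
    """Soft-tissue evaluation mask: voxels denser than ``rho0`` (g/cm^3).

    The default 0.05 keeps lung parenchyma (~0.26) and drops air around and
    inside the patient."""
    return density.values > rho0


def voi_mean_dose(dose: VoxelGrid, mask: np.ndarray) -> float:
    """Arithmetic mean dose (Gy) over the mask voxels."""
    if mask.shape != dose.shape:
        raise ValueError("mask is not aligned with the dose grid")
    if not mask.any():
        raise ValueError("empty mask")
    return float(dose.values[mask].mean())


def percentage_difference(d_ref: float, d: float) -> float:
    """Scalar PD = |d_ref - d| / d_ref * 100."""
    if d_ref <= 0:
        raise ValueError("reference dose must be positive")
    return abs(d_ref - d) / d_ref * 100.0


def pd_map(reference: VoxelGrid, test: VoxelGrid,
           mask: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Voxel-wise PD map (NaN where undefined) and the count of mask voxels
    excluded because the reference dose is zero there."""
    reference.require_aligned(test)
    if mask is None:
        mask = np.ones(reference.shape, dtype=bool)
    out = np.full(reference.shape, np.nan)
    ok = mask & (reference.values > 0)
    out[ok] = np.abs(reference.values[ok] - test.values[ok]) / reference.values[ok] * 100.0
    n_excluded = int(mask.sum() - ok.sum())
    return out, n_excluded


def region_statistics(pd_values: np.ndarray, eval_mask: np.ndarray,
                      overlap_mask: np.ndarray) -> dict[str, dict[str, float]]:
    """Mean and SD of the voxel PD in the whole body, the overlap region and
    the non-overlap region (all intersected with the evaluation mask; NaN
    PD voxels are ignored)."""
    regions = {
        "wb": eval_mask,
        "overlap": eval_mask & overlap_mask,
        "non_overlap": eval_mask & ~overlap_mask,
    }
    out: dict[str, dict[str, float]] = {}
    for name, m in regions.items():
        vals = pd_values[m]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"region {name!r} is empty")
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0)),
                     "n": int(vals.size)}
    return out


def line_profile(volume: VoxelGrid, axis: int, fixed_indices: tuple[int, int]) -> np.ndarray:
    """1-D profile along ``axis`` at the two fixed transverse indices."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    other = [a for a in range(3) if a != axis]
    for a, i in zip(other, fixed_indices):
        if not 0 <= i < volume.shape[a]:
            raise IndexError("fixed index out of range")
    sl: list = [slice(None)] * 3
    sl[other[0]], sl[other[1]] = fixed_indices
    return volume.values[tuple(sl)].copy()


def pd_histogram(pd_values: np.ndarray, mask: np.ndarray | None = None,
                 bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of a PD map (default 1 PD-percent bins) for tabular
    export; returns (bin_edges, counts).  NaN voxels are ignored."""
    vals = pd_values if mask is None else pd_values[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined PD values to histogram")
    hi = max(bin_width, float(np.ceil(vals.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts


def efficiency_factor(time_h: float, uncertainty_pct: float) -> float:
    """EF = 1 / (T * U^2) with T in hours and U in percent."""
    if time_h <= 0 or uncertainty_pct <= 0:
        raise ValueError("time and uncertainty must be positive")
    return 1.0 / (time_h * uncertainty_pct**2)


def mean_uncertainty(uncertainty: VoxelGrid, dose: VoxelGrid,
                     eval_mask: np.ndarray) -> float:
    """Mean voxel percent uncertainty over evaluation-mask voxels with dose."""
    m = eval_mask & (dose.values > 0)
    if not m.any():
        raise ValueError("no dosed voxels in the evaluation mask")
    return float(uncertainty.values[m].mean())


@dataclass
class DoseReport:
    """Aggregated comparison results for one study.

    ``voi_mean_dose_gy[method][voi]``, ``pd_voi_pct[method][voi]`` versus the
    reference method, ``region_stats_pct[method]`` from the voxel PD map,
    per-method mean percent uncertainty and efficiency factor, plus free-form
    metadata (problem sizes, seeds, timings)."""

    reference: str
    voi_mean_dose_gy: dict[str, dict[str, float]]
    pd_voi_pct: dict[str, dict[str, float]] = field(default_factory=dict)
    region_stats_pct: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    mean_uncertainty_pct: dict[str, float] = field(default_factory=dict)
    efficiency_factor: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DoseReport":
        return cls(**json.loads(text))

    def to_rows(self) -> list[dict]:
        """Flat (method, VOI) rows for tabular export."""
        rows = []
        for method, vois in self.voi_mean_dose_gy.items():
            for voi, dose in vois.items():
                rows.append({
                    "method": method, "voi": voi, "mean_dose_gy": dose,
                    "pd_vs_reference_pct": self.pd_voi_pct.get(method, {}).get(voi),
                })
        return rows
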