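"""Numba inner loops of the condensed-history electron transport engine.

Everything here operates on plain float64/int64 arrays; the public surface
lives in :mod:`patchdose.mc`.  One history is transported by
:func:`_one_history`; :func:`run_histories` drives a whole batch, seeding
numba's RNG once so a batch is a pure function of its seed.

Units inside the kernels: positions and spacings in mm, energies in MeV,
stopping power in MeV cm^2/g, CSDA range in g/cm^2, density in g/cm^3.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# maximum recorded deposits per history; a 2.28 MeV electron needs a few
# hundred steps at the default step rule, 8192 is a safe ceiling
MAX_DEPOSITS = 8192


@njit(cache=False)
def _one_history(
    x, y, z, ux, uy, uz, e0,
    density,                # (nx, ny, nz) g/cm^3
    ox, oy, oz, sx, sy, sz,  # grid origin (voxel-0 centre) and spacing, mm
    e_knots, sp_knots, range_knots,   # stopping-power / CSDA tables
    cutoff_mev, step_voxel_frac, step_range_frac, min_step_mm, ms_on,
    dep_idx, dep_e,          # output buffers (flat voxel index, MeV)
):
    """Transport one electron; returns (number of deposits, escaped MeV).

    Energy book-keeping is exact by construction: every step's loss is either
    written to ``dep_idx/dep_e`` or added to the escaped tally, and the
    history ends by depositing or escaping the full residual energy.
    """
    nx, ny, nz = density.shape
    e = e0
    n_dep = 0
    escaped = 0.0
    min_spacing = min(sx, min(sy, sz))
    while True:
        ix = int(np.floor((x - ox) / sx + 0.5))
        iy = int(np.floor((y - oy) / sy + 0.5))
        iz = int(np.floor((z - oz) / sz + 0.5))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            escaped += e
            break
        if e <= cutoff_mev:
            # residual energy deposited locally
            dep_idx[n_dep] = (ix * ny + iy) * nz + iz
            dep_e[n_dep] = e
            n_dep += 1
            break
        rho = density[ix, iy, iz]
        ds = step_voxel_frac * min_spacing
        if rho > 1e-9:
            r_local_mm = np.interp(e, e_knots, range_knots) / rho * 10.0
            ds_range = step_range_frac * r_local_mm
            if ds_range < ds:
                ds = ds_range
            if ds < min_step_mm:
                ds = min_step_mm
        # midpoint voxel receives the continuous energy loss of the step
        mx = x + 0.5 * ds * ux
        my = y + 0.5 * ds * uy
        mz = z + 0.5 * ds * uz
        jx = int(np.floor((mx - ox) / sx + 0.5))
        jy = int(np.floor((my - oy) / sy + 0.5))
        jz = int(np.floor((mz - oz) / sz + 0.5))
        mid_inside = 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz
        rho_mid = density[jx, jy, jz] if mid_inside else rho
        de = 0.0
        if rho_mid > 1e-9:
            de = np.interp(e, e_knots, sp_knots) * rho_mid * (ds / 10.0)
            if de > e:
                de = e
            if mid_inside:
                dep_idx[n_dep] = (jx * ny + jy) * nz + jz
                dep_e[n_dep] = de
                n_dep += 1
                if n_dep >= dep_idx.shape[0] - 1:
                    # buffer safety valve: dump the rest locally
                    dep_e[n_dep - 1] += e - de
                    return n_dep, escaped
            else:
                escaped += de
            e -= de
        if e <= 0.0:
            break
        x += ds * ux
        y += ds * uy
        z += ds * uz
        # Highland-style Gaussian multiple-scattering kick
        if ms_on and rho_mid > 1e-9:
            t = ds * rho_mid / 10.0 / 36.08  # step in radiation lengths
            if t > 0.0:
                etot = e + 0.51099895
                p = np.sqrt(e * (e + 2.0 * 0.51099895))
                beta = p / etot
                fac = 1.0 + 0.038 * np.log(t)
                if fac < 0.25:
                    fac = 0.25
                theta0 = 13.6e-3 / (beta * p) * np.sqrt(t) * fac * 1000.0
                gx = np.random.normal() * theta0
                gy = np.random.normal() * theta0
                theta = np.sqrt(gx * gx + gy * gy)
                if theta > 1.5:
                    theta = 1.5
                phi = 2.0 * np.pi * np.random.random()
                # orthonormal frame around (ux, uy, uz)
                if abs(uz) < 0.99:
                    e1x, e1y, e1z = uy, -ux, 0.0
                else:
                    e1x, e1y, e1z = 1.0, 0.0, 0.0
                n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x /= n1; e1y /= n1; e1z /= n1
                e2x = uy * e1z - uz * e1y
                e2y = uz * e1x - ux * e1z
                e2z = ux * e1y - uy * e1x
                st = np.sin(theta); ct = np.cos(theta)
                cp = np.cos(phi); sp = np.sin(phi)
                ux = ct * ux + st * (cp * e1x + sp * e2x)
                uy = ct * uy + st * (cp * e1y + sp * e2y)
                uz = ct * uz + st * (cp * e1z + sp * e2z)
                nu = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= nu; uy /= nu; uz /= nu
    return n_dep, escaped


@njit(cache=False)
def run_histories(
    n_histories, seed,
    tia_cdf, src_flat,       # CDF over source voxels, their flat indices
    density,
    ox, oy, oz, sx, sy, sz,
    inv_cdf_energy,          # spectrum inverse-CDF lookup table
    e_knots, sp_knots, range_knots,
    cutoff_mev, step_voxel_frac, step_range_frac, min_step_mm, ms_on,
    edep_flat,               # (nx*ny*nz,) accumulated MeV, modified in place
):
    """Run a batch of histories; returns (sum of initial energies, escaped MeV)."""
    np.random.seed(seed)
    nx, ny, nz = density.shape
    m = inv_cdf_energy.shape[0]
    dep_idx = np.empty(MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(MAX_DEPOSITS, dtype=np.float64)
    sum_e0 = 0.0
    escaped = 0.0
    for _ in range(n_histories):
        # decay position: voxel by TIA-weighted CDF, uniform inside the voxel
        u = np.random.random()
        k = np.searchsorted(tia_cdf, u)
        if k >= src_flat.shape[0]:
            k = src_flat.shape[0] - 1
        flat = src_flat[k]
        ix = flat // (ny * nz)
        iy = (flat // nz) % ny
        iz = flat % nz
        x = ox + (ix - 0.5 + np.random.random()) * sx
        y = oy + (iy - 0.5 + np.random.random()) * sy
        z = oz + (iz - 0.5 + np.random.random()) * sz
        # energy from the spectrum inverse CDF
        t = np.random.random() * (m - 1)
        i = int(t)
        if i >= m - 1:
            i = m - 2
        frac = t - i
        e0 = inv_cdf_energy[i] * (1.0 - frac) + inv_cdf_energy[i + 1] * frac
        # isotropic direction
        ct = 2.0 * np.random.random() - 1.0
        st = np.sqrt(1.0 - ct * ct)
        phi = 2.0 * np.pi * np.random.random()
        ux = st * np.cos(phi)
        uy = st * np.sin(phi)
        uz = ct
        n_dep, esc = _one_history(
            x, y, z, ux, uy, uz, e0, density,
            ox, oy, oz, sx, sy, sz,
            e_knots, sp_knots, range_knots,
            cutoff_mev, step_voxel_frac, step_range_frac, min_step_mm, ms_on,
            dep_idx, dep_e)
        for j in range(n_dep):
            edep_flat[dep_idx[j]] += dep_e[j]
        escaped += esc
        sum_e0 += e0
    return sum_e0, escaped


@njit(cache=False)
def single_history(
    seed,
    x, y, z, ux, uy, uz, e0,
    density, ox, oy, oz, sx, sy, sz,
    e_knots, sp_knots, range_knots,
    cutoff_mev, step_voxel_frac, step_range_frac, min_step_mm, ms_on,
):
    """Transport one history with a private RNG stream; returns the deposit
    list (flat indices, MeV) and the escaped energy."""
    np.random.seed(seed)
    dep_idx = np.empty(MAX_DEPOSITS, dtype=np.int64)
    dep_e = np.empty(MAX_DEPOSITS, dtype=np.float64)
    n_dep, escaped = _one_history(
        x, y, z, ux, uy, uz, e0, density,
        ox, oy, oz, sx, sy, sz,
        e_knots, sp_knots, range_knots,
        cutoff_mev, step_voxel_frac, step_range_frac, min_step_mm, ms_on,
        dep_idx, dep_e)
    return dep_idx[:n_dep].copy(), dep_e[:n_dep].copy(), escaped
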