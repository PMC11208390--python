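# Methods

This note documents the models behind `patchdose`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
package's known limitations.

## Dose model and units

All volumes are axis-aligned voxel lattices (`VoxelGrid`) with per-axis
spacing in mm and the physical origin at the centre of voxel (0,0,0); voxel
index `(i,j,k)` maps to `origin + index·spacing`. Cross-grid operations
require exact alignment. Dose is absorbed dose in Gy; a simulation tallies
energy deposits in MeV per voxel and converts with
`D = E_dep · 1.602·10⁻¹³ J/MeV / (ρ · V_voxel)`.

The time-integrated activity (TIA) map assumes permanently trapped
microspheres, so only physical decay contributes:
`TIA = A(T)·e^{λT}/λ` per voxel, with `λ = ln2/t½` and `t½ = 64.2 h` for
⁹⁰Y (other isotopes: swap `DecayParams`). Counts images are converted to Bq
by self-calibration: the administered activity, decay-corrected to the
acquisition start, divided by the total image counts. One shared interval
`T` is used for both the decay correction and the TIA integration.

## Transport engine

A desk-scale condensed-history β⁻ engine, deliberately simple and fully
specified:

* **Spectrum.** The ⁹⁰Y β⁻ spectrum is built analytically at import from
  the allowed-transition Fermi shape `N(E) ∝ F(Z,E)·p·E_tot·(Q−E)²` with
  the relativistic point-Coulomb Fermi function (daughter Z = 40,
  `E_max = 2.28 MeV`), tabulated on 101 knots. Its mean energy is
  0.928 MeV, within 0.7% of the evaluated value (0.934 MeV). Energies are
  drawn by inverse-CDF lookup.
* **Stopping power.** Collision mass stopping power of water from the
  Berger–Seltzer formula (I = 75 eV, Z/A = 0.55509) with the Sternheimer
  density-effect correction; agrees with evaluated electron data to ≲2%
  over 10 keV–2.3 MeV. The CSDA range is its quadrature integral; the
  2.28 MeV endpoint range is 11.2 mm in unit-density tissue, consistent
  with the 11.3 mm range constant used to size patch overlaps. All tissues
  use water stopping power scaled by local mass density — at ~10 mm SPECT
  voxels density is the dominant material effect; this is a declared
  fidelity limit, not a GEANT4 replica.
* **Stepping.** Step length = min(¼ of the smallest voxel edge, 1/20 of
  the residual CSDA range in the local medium), floored at 0.05 mm. The
  continuous loss `ΔE = S(E)·ρ·Δs` is deposited in the voxel containing
  the step midpoint. Histories end below the energy cutoff (residual
  deposited locally) or on leaving the grid (residual counted escaped), so
  deposited + escaped equals the initial energy exactly, per history, by
  construction. The default 15 keV cutoff corresponds to the usual 0.01 mm
  soft-tissue range cut; kernel generation uses the finer 5 keV cutoff
  (≈0.001 mm).
* **Multiple scattering.** A Highland-style Gaussian angular kick per step
  (`θ₀ = 13.6 MeV/(βcp)·√(Δs/X₀)·[1+0.038·ln(Δs/X₀)]`, X₀ = 36.08 g/cm²),
  switchable off for straight-track oracle tests. Voxels with ρ ≤ 10⁻⁹
  g/cm³ are vacuum: no deposition, no scattering.
* **Not modelled.** Bremsstrahlung, δ rays, positrons, material-specific
  collision data. For ⁹⁰Y in soft tissue these shift local dose at the
  percent level; the 60 g sphere S-value lands within 0.3% of the MIRD
  reference despite them (see below).
* **Randomness.** One master seed; batch streams are derived by splitmix
  integer mixing as (seed, batch), patch streams as (seed, patch, batch),
  so any scheduling order or concurrency gives identical results, and all
  derived seeds stay below 2³¹.

Batches are merged by a weighted mean (weights ∝ batch primaries) and the
voxel percent uncertainty is the batch estimator
`U = 100·SE/mean`, `SE = √[Σwᵢ(dᵢ−d̄)²/((B−1)Σwᵢ)]`, which for equal
batches reduces to the familiar `√[(⟨d²⟩−⟨d⟩²)/(B−1)]`. A single batch has
undefined uncertainty and returns `None`. Absolute dose = per-primary dose
× total TIA of the simulated source (per patch: the patch's own TIA sum).

## Patch layouts

The stride (source-patch edge) tiles the zero-padded volume exactly;
stride padding goes on the high-index side, the overlap halo is symmetric,
and a `PaddingRecord` makes cropping exactly invertible. "Overlap of OV
voxels per face" means each geometry patch extends `OV` voxels beyond its
stride cell on every face, so adjacent patches share a `2·OV`-wide band and
coverage multiplicities are {2,4,8} at band/edge/corner intersections —
the only interpretation consistent with 40-voxel patches on a 64-voxel
axis. CL2 averages by the actual coverage count; CL3 sums. Patch traversal
is C-order over the cell lattice and recorded in the manifest, which is
what "reassembly in the same order" means for CL1. Dose deposited outside
a patch's geometry has no canvas address and is discarded — exactly the
loss CL3's enlarged geometry patch prevents.

The halo of the cropped *geometry* volume is filled with zeros. The
pipeline crops the density map, so the halo is vacuum and a patch-boundary
escape behaves exactly like the whole-volume grid boundary; cropping the
CT in HU instead (halo HU 0 ≈ water) is supported but makes the outermost
canvas faces backscatter slightly differently from the whole-volume run.

The evaluation band shared by all layouts is CL2's overlap region (voxels
covered by ≥2 CL2 geometry patches); for CL1 it is generated from a
reference overlap of matching stride.

## Kernel dosimetry

The voxel S-value kernel is generated by the same engine: all decays in
the central voxel of a homogeneous ICRP soft-tissue cube (ρ = 1.03 g/cm³,
default 25³ voxels at 9.59 mm, 10⁶ primaries, 5 keV cutoff); the
per-primary dose grid is Gy/decay. Convolution with the TIA map uses exact
spatial convolution for small kernels and FFT for large ones (zero
boundary either way). Density correction defaults to
`D′ = D·ρ_ref/ρ_voxel` — the energy-per-mass argument: the same energy
imparted into lighter tissue gives more dose — with voxels below
0.05 g/cm³ zeroed; the opposite orientation is selectable and every report
records which was used, since the correction's direction is a genuine
modelling choice discussed in the literature.

## Synthetic data

`make_synthetic_patient` emulates a post-therapy ⁹⁰Y SIRT study on the
bremsstrahlung SPECT grid (64×64×42 at 9.59 mm): body/liver/lungs as
ellipsoids (HU 0/60/−740, air −1000, optional spine at 400 exercising the
bone bin), activity uniform over the treated (default right) hepatic lobe
with a 3× hot 28 mm lesion, a configurable lung-shunt fraction (default
5%), multiplicative log-normal voxel texture (σ = 0.4 — voxel-level PD
metrics are uninformative on perfectly uniform sources), and a 10 mm FWHM
Gaussian blur for SPECT resolution. The activity integrates exactly to the
administered activity (default 1.2 GBq, mid-range for lobar treatments)
before the blur; organs sit fully inside the grid so the blur conserves it
to better than 10⁻⁶. What it does **not** emulate: reconstruction
artefacts, attenuation/scatter residuals, registration error, realistic
anatomy — so green tests demonstrate the *algorithmic* properties
(layout equivalence, scaling, uncertainty behaviour), not clinical
accuracy.

`make_benchmark_sphere` voxelises the 60 g water sphere
(r = (3m/4πρ)^⅓ ≈ 24.3 mm) in an air box at 2 mm voxels (≈25 voxels across;
voxelised mass within 2%). The engine's mean absorbed dose per decay is
2.26·10⁻¹² Gy/decay at 2·10⁵ histories, −0.3% from the published MIRD-style
reference for this benchmark.

`make_toy_kernel` provides compact, exactly symmetric analytic kernels
(tent/uniform, half-width h, edge 2h+1) used as a *deterministic linear
dose engine* in tests: cropping with CL3 and summing the per-patch
convolutions reproduces the whole-volume convolution to machine precision
whenever the kernel half-width does not exceed `OV`, while CL1/CL2
provably under-dose band voxels — the layout mechanisms isolated from
Monte Carlo noise.

## Numerical choices and edge cases

* `OV_min = ⌈2R/v⌉` rounds to the closest even integer with ties upward
  (OV_min = 3 → 4), matching the ⁹⁰Y working point (R = 11.3, v = 9.59 →
  OV = 4 = 38.36 mm per face).
* Primary budgets split evenly; remainders go to the first patches and the
  sum is preserved exactly.
* Voxels with zero reference dose are excluded from PD maps and counted;
  region means ignore them. The soft-tissue evaluation mask keeps
  ρ > 0.05 g/cm³ (lung at 0.26 stays, air goes). Mean uncertainty for
  reports averages voxel U over evaluation-mask voxels with nonzero dose.
* Energy deposited in massless (ρ = 0) voxels cannot be scored as dose and
  is accounted with the escaped energy.
* HU→density uses a compact piecewise-linear anchor table
  (−1000→0.00121, −740→0.26, −98→0.93, 0→1.0, 60→1.06, 400→1.25,
  1500→1.90 g/cm³) with four material bins (air < −950 < lung < −200 <
  soft tissue < 200 < bone); resampling fills out-of-support voxels with
  −1000 HU (air outside the scanned field of view).
* Wall-clock times are recorded per stage for the efficiency factor but
  never asserted in tests (hardware-dependent).

## Problem sizes used in the shipped checks

The package's own validation runs at desk scale: 2·10⁵ histories for the
sphere S-value (statistical error well below the 3% check band), 10⁶ total
primaries for the full patient comparison (10 whole-volume batches, 4 per
patch), 10⁵–4·10⁵ for kernel cross-checks. The clinical-scale working
point the design targets — 5·10⁸ primaries split as 10 jobs of 5·10⁷ or
8 patches of 6.25·10⁷ (18 patches of ≈2.78·10⁷ for the finer tiling) — is
configuration, not code: only `total_primaries` changes.

At desk scale the voxel statistical noise dominates voxel-wise |PD|
statistics: with ~24% mean voxel uncertainty in the overlap band, the mean
|PD| between two matched 10⁶-primary maps is ≈1.6× the voxel uncertainty
regardless of layout, and the few-percent border bias separating the
layouts is visible in the *band mean dose* (CL1 < CL2 < CL3 ≈ reference,
tested) but not reliably in the heavy-tailed mean |PD|. Distinguishing the
layouts by mean |PD| the way a full-scale study can requires the voxel
uncertainty to be small against the border bias, i.e. ≳10⁸ primaries.

## Known limitations

Electron-only transport (no bremsstrahlung dose redistribution), water
stopping power for all materials, Gaussian small-angle multiple scattering,
no variance reduction, axis-aligned grids only, cubic patches only, and
organ-S-value (phantom-based) dosimetry is out of scope. The engine is a
transparent stand-in for a production MC code: its value is that every
physics ingredient is analytic, testable and fast, not that it reproduces
a condensed-history general-purpose code in detail.
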