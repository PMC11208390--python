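"""Monte Carlo engine: sampling, transport, tallies, merging, scaling."""

import numpy as np
import pytest
from scipy import stats

import patchdose as pdx
from patchdose.physics import MEV_TO_J

from conftest import point_source, uniform_water


def total_deposited_mev(tally, density):
    mass_kg = density.values * density.voxel_volume_cm3 * 1e-3
    return [
        float((tally.batches[i] * mass_kg).sum()) * tally.primaries[i] / MEV_TO_J
        for i in range(tally.n_batches)
    ]


class TestSampling:
    def test_single_voxel_source(self, rng):
        tia = point_source((8, 8, 8), 4.0, at=(2, 5, 3))
        pos = pdx.sample_decay_position(tia, rng, 500)
        idx = np.round(pos / 4.0).astype(int)
        assert np.all(idx == [2, 5, 3])

    def test_two_voxel_ratio_binomial(self, rng):
        v = np.zeros((4, 4, 4))
        v[0, 0, 0], v[3, 3, 3] = 1.0, 3.0
        tia = pdx.VoxelGrid(v, (4.0,) * 3, role="TIA")
        n = 10_000
        pos = pdx.sample_decay_position(tia, rng, n)
        frac = (pos[:, 0] < 2.0).mean()
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 4 * sigma

    def test_uniform_tia_chi_square(self, rng):
        tia = pdx.VoxelGrid(np.ones((4, 4, 4)), (4.0,) * 3, role="TIA")
        pos = pdx.sample_decay_position(tia, rng, 12_800)
        idx = np.round(pos / 4.0).astype(int)
        flat = np.ravel_multi_index(idx.T, (4, 4, 4))
        counts = np.bincount(flat, minlength=64)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_zero_tia_rejected(self, rng):
        with pytest.raises(ValueError):
            pdx.sample_decay_position(point_source().with_values(
                np.zeros((16, 16, 16))), rng)


class TestTransportHistory:
    def test_below_cutoff_deposits_at_birth(self):
        density = uniform_water()
        deposits, escaped = pdx.transport_history(
            (32.0, 32.0, 32.0), 0.010, (0, 0, 1), density,
            pdx.TransportConfig(cutoff_kev=15.0, seed=3))
        assert escaped == 0.0
        assert len(deposits) == 1
        assert deposits[0] == ((8, 8, 8), 0.010)

    @pytest.mark.parametrize("energy,direction", [
        (2.28, (0, 0, 1)), (0.5, (1, 1, 1)), (1.2, (-1, 0.3, 0.2))])
    def test_energy_conservation_exact(self, energy, direction):
        density = uniform_water((12, 12, 12), 3.0)
        deposits, escaped = pdx.transport_history(
            (18.0, 18.0, 18.0), energy, direction, density,
            pdx.TransportConfig(seed=7))
        total = sum(de for _, de in deposits) + escaped
        assert total == pytest.approx(energy, rel=1e-9)

    def test_straight_track_within_csda_range(self, water_table):
        # multiple scattering off -> straight track; deposits can reach at
        # most one CSDA range (plus a voxel diagonal) from the start
        density = uniform_water((24, 24, 24), 1.0)
        start = np.array([2.0, 12.0, 12.0])
        e0 = 2.0
        deposits, _ = pdx.transport_history(
            start, e0, (1, 0, 0), density,
            pdx.TransportConfig(multiple_scattering=False, seed=5))
        r_max_mm = water_table.csda_range(e0) * 10.0
        for (i, j, k), _ in deposits:
            d = np.linalg.norm(np.array([i, j, k]) * 1.0 - start)
            assert d <= r_max_mm + np.sqrt(3)

    def test_start_outside_grid_escapes_everything(self):
        density = uniform_water()
        deposits, escaped = pdx.transport_history(
            (-100.0, 0.0, 0.0), 1.0, (0, 0, 1), density, pdx.TransportConfig(seed=1))
        assert deposits == [] and escaped == 1.0


class TestRunSimulation:
    def test_same_seed_bit_identical(self):
        density = uniform_water()
        tia = point_source()
        cfg = pdx.TransportConfig(seed=42)
        t1 = pdx.run_simulation(tia, density, 2000, 2, cfg)
        t2 = pdx.run_simulation(tia, density, 2000, 2, cfg)
        for a, b in zip(t1.batches, t2.batches):
            np.testing.assert_array_equal(a, b)
        assert t1.escaped_mev == t2.escaped_mev

    def test_global_energy_conservation(self):
        density = uniform_water((10, 10, 10), 5.0)
        tia = point_source((10, 10, 10), 5.0)
        tally = pdx.run_simulation(tia, density, 5000, 2, pdx.TransportConfig(seed=9))
        dep = total_deposited_mev(tally, density)
        for i in range(tally.n_batches):
            assert dep[i] + tally.escaped_mev[i] == pytest.approx(
                tally.initial_energy_mev[i], rel=1e-9)

    def test_point_source_peaks_at_source_voxel(self):
        density = uniform_water((16, 16, 16), 4.0)
        tia = point_source((16, 16, 16), 4.0)
        tally = pdx.run_simulation(tia, density, 30_000, 1, pdx.TransportConfig(seed=4))
        dose, _ = pdx.merge_batches(tally)
        assert np.unravel_index(dose.values.argmax(), dose.shape) == (8, 8, 8)

    def test_translation_equivariance_in_uniform_medium(self):
        # shifting a compact source by one voxel shifts the sampled tracks
        # exactly (same RNG stream), hence the dose map shifts exactly too
        density = uniform_water((20, 20, 20), 4.0)
        blob = np.zeros((20, 20, 20))
        blob[9:11, 9:11, 9:11] = 1.0
        tia_a = pdx.VoxelGrid(blob, (4.0,) * 3, role="TIA")
        tia_b = pdx.VoxelGrid(np.roll(blob, 1, axis=2), (4.0,) * 3, role="TIA")
        cfg = pdx.TransportConfig(seed=10)
        da, _ = pdx.merge_batches(pdx.run_simulation(tia_a, density, 4000, 1, cfg))
        db, _ = pdx.merge_batches(pdx.run_simulation(tia_b, density, 4000, 1, cfg))
        np.testing.assert_allclose(np.roll(da.values, 1, axis=2), db.values,
                                   rtol=1e-12)

    def test_misaligned_and_empty_inputs_rejected(self):
        density = uniform_water()
        with pytest.raises(ValueError):
            pdx.run_simulation(point_source((8, 8, 8), 4.0), density, 100, 1)
        with pytest.raises(ValueError):
            pdx.run_simulation(point_source().with_values(np.zeros((16, 16, 16))),
                               density, 100, 1)


class TestMergeBatches:
    def _tally(self, batch_values):
        grids = [np.full((2, 2, 2), float(v)) for v in batch_values]
        return pdx.TallyResult(grids, [10] * len(grids), [0.0] * len(grids),
                               [1.0] * len(grids), (1, 1, 1), (0, 0, 0))

    def test_identical_batches_have_zero_uncertainty(self):
        dose, unc = pdx.merge_batches(self._tally([2.0, 2.0, 2.0]))
        assert np.all(dose.values == 2.0)
        assert np.all(unc.values == 0.0)

    def test_two_batch_arithmetic(self):
        # batches {1, 3}: mean 2, SE 1, uncertainty 50%
        dose, unc = pdx.merge_batches(self._tally([1.0, 3.0]))
        assert np.all(dose.values == 2.0)
        assert np.all(unc.values == pytest.approx(50.0))

    def test_single_batch_flags_undefined_uncertainty(self):
        dose, unc = pdx.merge_batches(self._tally([4.0]))
        assert unc is None
        assert np.all(dose.values == 4.0)

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            pdx.TallyResult([], [], [], [], (1, 1, 1), (0, 0, 0))


class TestScaleToAbsolute:
    def test_identity_when_tia_equals_primaries(self):
        d = pdx.VoxelGrid(np.full((2, 2, 2), 5.0), (1,) * 3, role="dose_per_primary")
        out = pdx.scale_to_absolute(d, 1000.0, 1000)
        np.testing.assert_allclose(out.values, 5.0)

    def test_per_primary_times_total_tia(self):
        d = pdx.VoxelGrid(np.full((1, 1, 1), 1e-14), (1,) * 3, role="dose_per_primary")
        assert pdx.scale_to_absolute(d, 2e8).values[0, 0, 0] == pytest.approx(2e-6)

    def test_zero_tia_zero_dose(self):
        d = pdx.VoxelGrid(np.ones((2, 2, 2)), (1,) * 3, role="dose_per_primary")
        assert np.all(pdx.scale_to_absolute(d, 0.0).values == 0.0)

    def test_negative_tia_rejected(self):
        d = pdx.VoxelGrid(np.ones((1, 1, 1)), (1,) * 3)
        with pytest.raises(ValueError):
            pdx.scale_to_absolute(d, -1.0)
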