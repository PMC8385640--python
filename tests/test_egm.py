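"""Unipolar EGM forward model: kernel, footprint, normalization, filters, noise."""

import numpy as np
import pytest

from achmap.egm import (
    ElectrodeGrid, compute_dimensional_egm, compute_egm_grid, compute_pegm,
    add_noise, filter_egm, normalize,
)
from achmap.phantom import synth_noise
from achmap.solver import VmField

from conftest import make_translating_wave


def brute_force_pegm(field, x_mm, y_mm, z_mm):
    """Naive double-loop evaluation of the dipole-kernel summation."""
    nt, ny, nx = field.vm.shape
    dx = field.dx
    out = np.zeros(nt)
    xp, yp, zp = x_mm / 10.0, y_mm / 10.0, z_mm / 10.0
    gx = np.gradient(field.vm, dx, axis=2)
    gy = np.gradient(field.vm, dx, axis=1)
    for j in range(ny):
        for i in range(nx):
            d3 = ((i * dx - xp) ** 2 + (j * dx - yp) ** 2 + zp ** 2) ** 1.5
            out += (gx[:, j, i] * (i * dx - xp)
                    + gy[:, j, i] * (j * dx - yp)) / d3 * dx * dx
    return out


def _random_movie(seed, ny=30, nx=30, nt=12):
    rng = np.random.default_rng(seed)
    vm = rng.standard_normal((nt, ny, nx)).cumsum(axis=0)
    return VmField(vm=vm, sample_dt=1.0, dx=0.02)


class TestKernel:
    def test_uniform_vm_gives_zero(self):
        vm = np.full((10, 20, 20), -60.0)
        f = VmField(vm=vm, sample_dt=1.0, dx=0.02)
        phi = compute_pegm(f, (2.0, 2.0, 1.0))
        assert np.allclose(phi, 0.0, atol=1e-12)

    def test_amplitude_decays_with_height(self):
        # stationary half-plane step: |phi| strictly decreases as z doubles
        vm = np.zeros((1, 40, 40))
        vm[:, 20:, :] = 100.0
        f = VmField(vm=vm, sample_dt=1.0, dx=0.02)
        mags = [abs(compute_pegm(f, (3.9, 3.9, z))[0]) for z in (0.5, 1.0, 2.0)]
        assert mags[0] > mags[1] > mags[2] > 0

    def test_zero_height_raises(self):
        f = _random_movie(0)
        with pytest.raises(ValueError):
            compute_pegm(f, (2.0, 2.0, 0.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        f = _random_movie(seed)
        phi = compute_pegm(f, (2.3, 3.1, 1.0))
        ref = brute_force_pegm(f, 2.3, 3.1, 1.0)
        assert np.allclose(phi, ref, rtol=1e-10, atol=1e-12)

    def test_linearity(self):
        fa, fb = _random_movie(1), _random_movie(2)
        fsum = VmField(vm=fa.vm + fb.vm, sample_dt=1.0, dx=0.02)
        r = (2.9, 2.1, 1.0)
        lhs = compute_pegm(fsum, r)
        rhs = compute_pegm(fa, r) + compute_pegm(fb, r)
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    def test_mirror_symmetry(self):
        """A wave symmetric about the electrode's x stays invariant under
        mirroring the tissue about that axis."""
        f = make_translating_wave(ny=31, nx=31)
        mid_mm = 15 * 0.02 * 10.0
        phi = compute_pegm(f, (mid_mm, 2.0, 1.0))
        fm = VmField(vm=f.vm[:, :, ::-1].copy(), sample_dt=1.0, dx=0.02)
        phim = compute_pegm(fm, (mid_mm, 2.0, 1.0))
        assert np.allclose(phi, phim, rtol=1e-9, atol=1e-12)


class TestDimensionalElectrode:
    def test_mean_of_25_pegms(self):
        f = _random_movie(4)
        dx_mm = f.dx * 10.0
        center = (3.0, 3.0)
        got = compute_dimensional_egm(f, center, z_mm=1.0)
        offs = np.arange(-2, 3) * dx_mm
        acc = np.zeros(f.vm.shape[0])
        for oy in offs:
            for ox in offs:
                acc += compute_pegm(f, (center[0] + ox, center[1] + oy, 1.0))
        assert np.allclose(got, acc / 25.0, rtol=1e-12)

    def test_footprint_outside_raises(self):
        f = _random_movie(4)
        with pytest.raises(ValueError):
            compute_dimensional_egm(f, (0.1, 3.0), z_mm=1.0)

    def test_grid_matches_per_electrode(self):
        f = _random_movie(5)
        grid = ElectrodeGrid(n_rows=2, n_cols=2, pitch_mm=2.0, z_mm=1.0,
                             footprint="square")
        out = compute_egm_grid(f, grid)
        for r in range(2):
            for c in range(2):
                x, y = out.positions_mm[r, c]
                ref = compute_dimensional_egm(f, (x, y), z_mm=1.0)
                assert np.allclose(out.phi[r, c], ref, rtol=1e-9)

    def test_punctual_grid_matches_pegm(self):
        f = _random_movie(6)
        grid = ElectrodeGrid(n_rows=2, n_cols=2, z_mm=1.0, footprint="punctual")
        out = compute_egm_grid(f, grid)
        x, y = out.positions_mm[1, 0]
        assert np.allclose(out.phi[1, 0], compute_pegm(f, (x, y, 1.0)),
                           rtol=1e-9)

    def test_mesh_must_fit(self):
        f = _random_movie(7)
        grid = ElectrodeGrid(n_rows=16, n_cols=16, z_mm=1.0)
        with pytest.raises(ValueError):
            compute_egm_grid(f, grid)


class TestNormalizeAndFilter:
    def _grid(self, phi, sample_dt=1.0):
        nr, nc, _ = phi.shape
        g = ElectrodeGrid(n_rows=nr, n_cols=nc, z_mm=1.0)
        from achmap.egm import EgmGrid
        return EgmGrid(phi=phi, sample_dt=sample_dt, grid=g,
                       positions_mm=np.zeros((nr, nc, 2)))

    @pytest.mark.parametrize("z,factor", [(0.5, 350.0), (1.0, 250.0), (2.0, 150.0)])
    def test_published_factors(self, z, factor):
        e = self._grid(np.ones((1, 1, 100)))
        out = normalize(e, z_mm=z)
        assert np.allclose(out.phi, 1.0 / factor)

    def test_unknown_height_needs_factor(self):
        e = self._grid(np.ones((1, 1, 100)))
        with pytest.raises(ValueError):
            normalize(e, z_mm=1.5)
        out = normalize(e, z_mm=1.5, factor=100.0)
        assert np.allclose(out.phi, 0.01)

    def test_zero_signal_stays_zero(self):
        e = self._grid(np.zeros((1, 1, 100)))
        assert not normalize(e, z_mm=1.0).phi.any()

    def test_dc_rejection(self):
        e = self._grid(np.full((1, 1, 1000), 3.0))
        out = filter_egm(e, "hp2")
        assert np.abs(out.phi).max() < 1e-6

    def test_bandpass_frequency_response(self):
        t = np.arange(4000) / 1000.0
        for f_hz, passed in ((1.0, False), (10.0, True)):
            sig = np.sin(2 * np.pi * f_hz * t)[None, None, :]
            out = filter_egm(self._grid(sig), "bp2_30")
            # compare steady-state amplitude away from the edges
            amp = np.abs(out.phi[0, 0, 1000:3000]).max()
            if passed:
                assert amp > 10 ** (-1 / 20)          # within 1 dB
            else:
                assert amp < 10 ** (-3 / 20)          # at least 3 dB down

    def test_wideband_preserves_depol_peak_to_peak(self):
        t = np.arange(1000)
        sig = np.gradient(5.0 * np.exp(-0.5 * ((t - 300) / 4.0) ** 2))
        out = filter_egm(self._grid(sig[None, None, :]), "bp2_250")
        p2p_in = sig.max() - sig.min()
        p2p_out = out.phi[0, 0].max() - out.phi[0, 0].min()
        assert abs(p2p_out - p2p_in) / p2p_in < 0.05

    def test_nyquist_guard(self):
        e = self._grid(np.zeros((1, 1, 1000)), sample_dt=4.0)   # fs = 250 Hz
        with pytest.raises(ValueError):
            filter_egm(e, "bp2_250")

    def test_short_signal_raises(self):
        e = self._grid(np.zeros((1, 1, 20)))
        with pytest.raises(ValueError):
            filter_egm(e, "hp2")


class TestNoise:
    def _signal_grid(self):
        t = np.arange(800)
        sig = np.gradient(np.exp(-0.5 * ((t - 200) / 5.0) ** 2)) * 100
        phi = np.tile(sig, (2, 2, 1))
        from achmap.egm import EgmGrid
        return EgmGrid(phi=phi, sample_dt=1.0,
                       grid=ElectrodeGrid(n_rows=2, n_cols=2, z_mm=1.0),
                       positions_mm=np.zeros((2, 2, 2)))

    @pytest.mark.parametrize("snr", [0, 5, 10, 15, 20])
    def test_realized_snr_within_one_percent(self, snr):
        e = self._signal_grid()
        out = add_noise(e, snr, synth_noise, seed=3)
        for r in range(2):
            for c in range(2):
                p_sig = np.mean(e.phi[r, c] ** 2)
                p_noise = np.mean((out.phi[r, c] - e.phi[r, c]) ** 2)
                snr_real = 10 * np.log10(p_sig / p_noise)
                # the noise segment has exactly unit power, so the realized
                # power ratio matches to numerical precision
                assert 10 ** (abs(snr_real - snr) / 10) < 1.01

    def test_none_means_clean(self):
        e = self._signal_grid()
        assert add_noise(e, None, synth_noise, seed=0) is e

    def test_reproducible(self):
        e = self._signal_grid()
        a = add_noise(e, 10, synth_noise, seed=5)
        b = add_noise(e, 10, synth_noise, seed=5)
        assert np.array_equal(a.phi, b.phi)

    def test_zero_power_signal_raises(self):
        from achmap.egm import EgmGrid
        e = EgmGrid(phi=np.zeros((1, 1, 100)), sample_dt=1.0,
                    grid=ElectrodeGrid(n_rows=1, n_cols=1, z_mm=1.0),
                    positions_mm=np.zeros((1, 1, 2)))
        with pytest.raises(ValueError):
            add_noise(e, 10, synth_noise, seed=0)
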