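import numpy as np
import pytest

from kdentropy.bandwidth import (
    fixed_point_residual,
    periodic_pseudo_coefficients,
    select_bandwidth,
    select_bandwidth_periodic,
)
from kdentropy.errors import DataError
from kdentropy.gridding import BinnedData, Grid, Sample1D, bin_samples, make_grid


def _binned(values, resolution=256, weights=None):
    sample = Sample1D(np.asarray(values, float), weights=weights)
    grid = make_grid(sample, resolution)
    return bin_samples(sample, grid)


class TestSelectBandwidth:
    def test_gaussian_close_to_normal_reference(self):
        """On Gaussian data the plug-in bandwidth should land near the
        AMISE-optimal 1.06 sigma n^(-1/5)."""
        x = np.random.default_rng(0).normal(0.0, 1.0, 10_000)
        bw = select_bandwidth(_binned(x, 2048))
        reference = 1.06 * x.std() * 10_000 ** (-0.2)
        assert bw.converged
        assert bw.sigma_data == pytest.approx(reference, rel=0.15)

    def test_root_matches_dense_scan(self):
        """Brute-force oracle: the root returned must agree with a dense
        log-grid scan of the residual's sign change."""
        x = np.random.default_rng(3).normal(2.0, 0.7, 50)
        binned = _binned(x, 64)
        bw = select_bandwidth(binned)

        from scipy import fft as sfft
        coeffs = sfft.dct(binned.frequencies, type=2)
        ts = np.logspace(-12, -1, 100_000)
        res = np.array([fixed_point_residual(t, binned.n_effective, coeffs) for t in ts])
        idx = np.flatnonzero(np.sign(res[:-1]) * np.sign(res[1:]) < 0)[0]
        # linear interpolation of the crossing on the scan grid
        t_lo, t_hi = ts[idx], ts[idx + 1]
        t_scan = t_lo - res[idx] * (t_hi - t_lo) / (res[idx + 1] - res[idx])
        assert bw.t_unit == pytest.approx(t_scan, rel=1e-6)

    def test_residual_is_zero_at_root(self):
        x = np.random.default_rng(1).normal(size=500)
        bw = select_bandwidth(_binned(x))
        assert abs(bw.residual) < 1e-10

    def test_t_data_scaling_is_exact(self):
        x = np.random.default_rng(1).normal(size=500)
        binned = _binned(x)
        bw = select_bandwidth(binned)
        assert bw.t_data == bw.t_unit * binned.grid.span**2

    def test_scale_equivariance(self):
        """x -> a*x + b must multiply the squared data-space bandwidth by a^2."""
        x = np.random.default_rng(5).normal(size=20_000)
        t1 = select_bandwidth(_binned(x, 1024)).t_data
        t2 = select_bandwidth(_binned(5.0 * x + 3.0, 1024)).t_data
        assert t2 / t1 == pytest.approx(25.0, rel=0.01)

    def test_bandwidth_shrinks_with_n(self):
        rng = np.random.default_rng(7)
        hs = []
        for n in (10**3, 10**4, 10**5):
            hs.append(select_bandwidth(_binned(rng.normal(size=n), 1024)).sigma_data)
        assert hs[0] > hs[1] > hs[2]

    def test_consistency_rate(self):
        """sqrt(t) * n^(1/5) stabilises near 1.06 sigma for Gaussian data."""
        rng = np.random.default_rng(11)
        scaled = [
            select_bandwidth(_binned(rng.normal(size=n), 1024)).sigma_data * n**0.2
            for n in (10**3, 10**4, 10**5)
        ]
        assert all(abs(s - 1.06) / 1.06 < 0.15 for s in scaled)

    def test_degenerate_inputs_rejected(self):
        grid = Grid(0.0, 1.0, 8)
        one_bin = BinnedData(grid, np.array([0, 0, 5.0, 0, 0, 0, 0, 0]), 5, 5.0, 5.0)
        with pytest.raises(DataError, match="occupied"):
            select_bandwidth(one_bin)
        tiny = BinnedData(grid, np.array([1.0, 0, 1.0, 0, 0, 0, 0, 0]), 2, 2.0, 1.5)
        with pytest.raises(DataError, match="effective"):
            select_bandwidth(tiny)


class TestFixedPointResidual:
    def test_continuity(self):
        coeffs = np.array([2.0, 0.8, -0.3, 0.1, 0.05, -0.02, 0.01, 0.005])
        t = 0.01
        base = fixed_point_residual(t, 100, coeffs)
        for delta in (1e-4, 1e-6, 1e-8):
            assert abs(fixed_point_residual(t + delta, 100, coeffs) - base) < 100 * delta + 1e-9

    def test_empty_coefficients_rejected(self):
        with pytest.raises(DataError):
            fixed_point_residual(0.01, 100, np.array([]))

    def test_matches_high_precision_rederivation(self):
        """Re-derive the seven-stage functional recursion in 50-digit
        arithmetic and compare the float implementation against it."""
        import mpmath as mp

        coeffs = np.array([2.0, 0.8, -0.3, 0.1, 0.05, -0.02, 0.01, 0.005])
        t, n = 0.01, 100
        value = fixed_point_residual(t, n, coeffs)

        with mp.workdps(50):
            pi = mp.pi
            a2 = [(mp.mpf(c) / 2) ** 2 for c in coeffs[1:]]
            i_sq = [mp.mpf(k) ** 2 for k in range(1, len(coeffs))]
            ell = 7
            f = 2 * pi ** (2 * ell) * mp.fsum(
                i**ell * a * mp.e ** (-i * pi**2 * mp.mpf(t)) for i, a in zip(i_sq, a2)
            )
            for s in range(ell - 1, 1, -1):
                odd = mp.mpf(1)
                for v in range(1, 2 * s, 2):
                    odd *= v
                k0 = odd / mp.sqrt(2 * pi)
                const = (1 + mp.mpf(2) ** -(s + mp.mpf("0.5"))) / 3
                time_s = (2 * const * k0 / (n * f)) ** (mp.mpf(2) / (3 + 2 * s))
                f = 2 * pi ** (2 * s) * mp.fsum(
                    i**s * a * mp.e ** (-i * pi**2 * time_s) for i, a in zip(i_sq, a2)
                )
            expected = mp.mpf(t) - (2 * n * mp.sqrt(pi) * f) ** (mp.mpf(-2) / 5)
        assert value == pytest.approx(float(expected), rel=1e-12)


class TestPeriodicSelector:
    def test_shift_invariance_is_exact(self):
        """Rolling the circular histogram by whole bins must not change the
        selected bandwidth at all — the spectrum is phase-blind."""
        rng = np.random.default_rng(4)
        angles = np.degrees(rng.vonmises(0.5, 3.0, 5000))
        grid = Grid(-180.0, 180.0, 512)
        b1 = bin_samples(Sample1D(angles), grid)
        rolled = BinnedData(grid, np.roll(b1.bin_mass, 97), b1.n_samples,
                            b1.total_weight, b1.n_effective)
        t1 = select_bandwidth_periodic(b1).t_unit
        t2 = select_bandwidth_periodic(rolled).t_unit
        # identical up to FFT round-off in the rolled spectrum
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_pseudo_coefficients_layout(self):
        freqs = np.array([0.5, 0.25, 0.125, 0.125])
        coeffs = periodic_pseudo_coefficients(freqs)
        c = np.fft.rfft(freqs)
        assert coeffs.size == 2 * (c.size - 1) + 1
        assert np.all(coeffs[1::2] == 0)
        assert np.allclose(coeffs[2::2], 2 * np.abs(c[1:]))

    def test_converges_on_peaked_circular_data(self):
        angles = np.degrees(np.random.default_rng(8).vonmises(1.0, 20.0, 10_000))
        binned = bin_samples(Sample1D(angles), Grid(-180.0, 180.0, 1024))
        bw = select_bandwidth_periodic(binned)
        assert bw.converged
        # kernel width should resolve the ~13 deg-wide von Mises peak
        assert 1.0 < bw.sigma_data < 15.0
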