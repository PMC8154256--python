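import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kdentropy.dihedral import (
    DihedralSeries,
    dihedral_entropy,
    residuewise_entropy,
)
from kdentropy.entropy import GAS_CONSTANT as R
from kdentropy.errors import DataError
from kdentropy.gridding import wrap_degrees


def _periodic_direct_sum_entropy(angles_deg, t_data_rad, r=1024):
    """Independent oracle: explicit periodic Gaussian-kernel sum on the
    circle (images at theta, theta +- 2 pi), integrated by Riemann sum."""
    theta = np.radians(angles_deg)
    grid = np.linspace(-np.pi, np.pi, r, endpoint=False) + np.pi / r
    pdf = np.zeros(r)
    norm = 1.0 / np.sqrt(2.0 * np.pi * t_data_rad)
    for shift in (-2 * np.pi, 0.0, 2 * np.pi):
        for start in range(0, theta.size, 512):
            block = theta[start:start + 512, None] + shift
            pdf += np.exp(-((grid[None, :] - block) ** 2) / (2 * t_data_rad)).sum(axis=0)
    pdf *= norm / theta.size
    dx = 2 * np.pi / r
    pdf /= pdf.sum() * dx
    mask = pdf > 0
    return float(-R * np.sum(pdf[mask] * np.log(pdf[mask])) * dx)


class TestDihedralEntropy:
    def test_uniform_circle_value(self):
        """Angles uniform on the circle have entropy R ln(2 pi) in the
        radian convention."""
        angles = np.random.default_rng(1).uniform(-180.0, 180.0, 50_000)
        s = dihedral_entropy(angles).value
        assert s == pytest.approx(R * np.log(2 * np.pi), rel=0.02)

    def test_quarter_turn_invariance(self):
        vm = np.degrees(np.random.default_rng(2).vonmises(0.1, 2.8, 20_000))
        s1 = dihedral_entropy(vm).value
        s2 = dihedral_entropy(wrap_degrees(vm + 90.0)).value
        assert abs(s1 - s2) < 1e-3

    @given(st.integers(min_value=1, max_value=4095))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_shift_by_whole_bins_is_exact(self, k):
        vm = np.degrees(np.random.default_rng(3).vonmises(0.5, 4.0, 4000))
        r = 1024
        shift = k * (360.0 / r)
        s1 = dihedral_entropy(vm, resolution=r).value
        s2 = dihedral_entropy(wrap_degrees(vm + shift), resolution=r).value
        assert abs(s1 - s2) < 1e-6

    def test_matches_periodic_direct_sum(self):
        """A concentrated von Mises sample: the binned spectral pipeline and
        a literal periodic kernel sum at the same bandwidth must agree."""
        angles = np.degrees(np.random.default_rng(4).vonmises(0.3, 20.0, 10_000))
        result = dihedral_entropy(angles)
        t_rad = result.density.bandwidth.t_data  # already rad^2
        oracle = _periodic_direct_sum_entropy(angles, t_rad, r=2048)
        assert result.value == pytest.approx(oracle, abs=0.005 * abs(oracle) + 1e-12)

    def test_window_mass_is_one(self):
        angles = np.degrees(np.random.default_rng(5).vonmises(1.0, 5.0, 5000))
        result = dihedral_entropy(angles)
        assert result.density.riemann_sum == pytest.approx(1.0, abs=1e-9)

    def test_entropy_converges_with_frames(self):
        """On stationary synthetic data the estimate flattens as the
        trajectory grows."""
        rng = np.random.default_rng(6)
        full = np.degrees(rng.vonmises(0.0, 5.0, 40_000))
        s = {n: dihedral_entropy(full[:n]).value for n in (10_000, 20_000, 40_000)}
        assert abs(s[40_000] - s[20_000]) < abs(s[20_000] - s[10_000]) + 0.02

    def test_input_validation(self):
        with pytest.raises(DataError):
            dihedral_entropy(np.array([]))
        with pytest.raises(DataError, match="weights length"):
            dihedral_entropy(np.array([0.0, 10.0, 20.0]), weights=np.array([1.0]))

    def test_wrapping_on_construction(self):
        series = DihedralSeries(np.array([180.0, 190.0, -540.0]), name="chi")
        assert np.all(series.angles >= -180.0) and np.all(series.angles < 180.0)
        assert series.angles[0] == -180.0


class TestResiduewise:
    def _series(self, rng, name, residue, n=1500, kappa=3.0):
        return DihedralSeries(np.degrees(rng.vonmises(0.0, kappa, n)),
                              name=name, residue_index=residue, residue_name="ALA")

    def test_grouping_and_ordering(self):
        rng = np.random.default_rng(7)
        series = [self._series(rng, f"psi_{i}", i) for i in (3, 1, 2)]
        series += [self._series(rng, f"phi_{i}", i) for i in (1, 2, 3)]
        results = residuewise_entropy(series, resolution=128)
        assert [r.residue_index for r in results] == [1, 2, 3]
        assert all(set(r.entropy_values) == {f"phi_{r.residue_index}",
                                             f"psi_{r.residue_index}"} for r in results)
        for r in results:
            assert r.combined == pytest.approx(sum(r.entropy_values.values()), abs=1e-12)

    def test_singleton_sum(self):
        rng = np.random.default_rng(8)
        s = self._series(rng, "phi_5", 5)
        [res] = residuewise_entropy([s], resolution=128)
        assert res.combined == dihedral_entropy(s, resolution=128).value

    def test_identical_series_add(self):
        rng = np.random.default_rng(9)
        a = self._series(rng, "phi_1", 1)
        b = DihedralSeries(a.angles, name="psi_1", residue_index=1, residue_name="ALA")
        [res] = residuewise_entropy([a, b], resolution=128)
        assert res.combined == pytest.approx(2 * res.entropy_values["phi_1"], abs=1e-12)

    def test_duplicate_name_rejected(self):
        rng = np.random.default_rng(10)
        a = self._series(rng, "phi_1", 1)
        b = self._series(rng, "phi_1", 1)
        with pytest.raises(DataError, match="duplicate"):
            residuewise_entropy([a, b], resolution=128)

    def test_missing_residue_metadata_rejected(self):
        s = DihedralSeries(np.array([0.0, 10.0, 20.0]), name="phi")
        with pytest.raises(DataError, match="residue_index"):
            residuewise_entropy([s])

    def test_many_series_grouping(self):
        """114 backbone series (57 residues x phi/psi) group into 57
        records, mirroring a full-protein analysis."""
        rng = np.random.default_rng(11)
        series = []
        for i in range(1, 58):
            series.append(self._series(rng, f"phi_{i}", i, n=400))
            series.append(self._series(rng, f"psi_{i}", i, n=400))
        results = residuewise_entropy(series, resolution=128)
        assert len(results) == 57
        assert sum(len(r.entropy_values) for r in results) == 114
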