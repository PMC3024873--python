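"""3D Zernike moments, invariants, reconstruction, and descriptor I/O."""

import io
import warnings
from math import pi

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from zernsurf.structures import select_representation
from zernsurf.surface import surface_unit_grid
from zernsurf.zernike import (
    Descriptor,
    ZernikeMoments,
    _basis_table,
    _nlm_triplets,
    compute_moments,
    count_invariants,
    describe_grid,
    descriptor_correlation,
    invariants,
    nl_pairs,
    normalize_descriptor,
    read_descriptor,
    reconstruct,
    write_descriptor,
)

from conftest import unit_ball_grid
from zernike_oracle import brute_force_moments


def random_unit_grid(dim=16, density=0.3, seed=0):
    """Random occupancy restricted to the unit ball."""
    rng = np.random.default_rng(seed)
    vals = (rng.random((dim, dim, dim)) < density).astype(float)
    ax = (np.arange(dim) + 0.5 - dim / 2) * (2.0 / dim)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals[x**2 + y**2 + z**2 > 1.0] = 0.0
    return vals


class TestCountInvariants:
    @pytest.mark.parametrize("order, expected", [(20, 121), (0, 1), (5, 12)])
    def test_known_values(self, order, expected):
        assert count_invariants(order) == expected

    @given(st.integers(min_value=0, max_value=30))
    @settings(derandomize=True, max_examples=31)
    def test_even_order_closed_form(self, order):
        brute = sum(
            1 for n in range(order + 1) for l in range(n + 1) if (n - l) % 2 == 0
        )
        assert count_invariants(order) == brute
        if order % 2 == 0:
            assert count_invariants(order) == (order // 2 + 1) ** 2

    def test_negative_order_raises(self):
        with pytest.raises(ValueError):
            count_invariants(-1)


class TestComputeMoments:
    def test_matches_brute_force_oracle(self):
        """Fast monomial path equals direct basis integration per voxel."""
        vals = random_unit_grid(dim=16, seed=0)
        moments = compute_moments(vals, order=6)
        oracle = brute_force_moments(vals, order=6)
        scale = max(abs(v) for v in oracle.values())
        for (n, l, m), expected in oracle.items():
            if m < 0:
                continue
            assert abs(moments.value(n, l, m) - expected) <= 1e-9 * scale

    def test_conjugation_symmetry_against_oracle(self):
        """Negative-m moments equal (-1)^m conj of positive-m for real input."""
        vals = random_unit_grid(dim=12, seed=4)
        moments = compute_moments(vals, order=4)
        oracle = brute_force_moments(vals, order=4)
        scale = max(abs(v) for v in oracle.values())
        for (n, l, m), expected in oracle.items():
            if m >= 0:
                continue
            assert abs(moments.value(n, l, m) - expected) <= 1e-9 * scale

    def test_ball_kills_nonzero_degree(self):
        moments = compute_moments(unit_ball_grid(radius=0.6, dim=96), order=8)
        mags = {t: abs(moments.value(*t)) for t in _nlm_triplets(8)}
        peak = max(mags.values())
        for (n, l, m), mag in mags.items():
            if (l, m) != (0, 0):
                assert mag < 1e-3 * peak

    def test_outside_sphere_raises(self):
        vals = np.zeros((16, 16, 16))
        vals[0, 0, 0] = 1.0  # corner voxel: radius sqrt(3) > 1
        with pytest.raises(ValueError, match="unit sphere"):
            compute_moments(vals, order=4)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="occupied"):
            compute_moments(np.zeros((16, 16, 16)), order=4)

    def test_high_order_warns(self):
        with pytest.warns(UserWarning, match="precision"):
            compute_moments(unit_ball_grid(radius=0.5, dim=16), order=22)

    def test_deterministic(self):
        vals = random_unit_grid(dim=16, seed=7)
        m1 = compute_moments(vals, order=8).values
        m2 = compute_moments(vals, order=8).values
        np.testing.assert_array_equal(m1, m2)


class TestInvariants:
    def test_zero_moments_zero_descriptor(self):
        moments = ZernikeMoments(order=4, values=np.zeros(len(_nlm_triplets(4)), complex))
        assert np.all(invariants(moments).values == 0)

    def test_single_moment_norm(self):
        """F_22 is the plain modulus when only Omega_220 is set."""
        vals = np.zeros(len(_nlm_triplets(4)), dtype=complex)
        idx = _nlm_triplets(4).index((2, 2, 0))
        vals[idx] = 3 + 4j
        d = invariants(ZernikeMoments(order=4, values=vals))
        assert d.values[nl_pairs(4).index((2, 2))] == pytest.approx(5.0)

    def test_exact_lattice_rotation_invariance(self):
        """A 90-degree rotation about z is exact on the lattice."""
        vals = random_unit_grid(dim=16, seed=2)
        d1 = invariants(compute_moments(vals, order=8)).values
        d2 = invariants(compute_moments(np.rot90(vals, axes=(0, 1)), order=8)).values
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestNormalize:
    def test_three_four_example(self):
        values = np.zeros(count_invariants(4))
        values[0], values[1] = 3.0, 4.0
        d = normalize_descriptor(Descriptor(order=4, values=values))
        assert d.values[0] == pytest.approx(0.6)
        assert d.values[1] == pytest.approx(0.8)
        assert np.linalg.norm(d.values) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        d = Descriptor(order=4, values=rng.random(count_invariants(4)))
        once = normalize_descriptor(d)
        twice = normalize_descriptor(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)

    def test_zero_raises(self):
        d = Descriptor(order=2, values=np.zeros(count_invariants(2)))
        with pytest.raises(ValueError):
            normalize_descriptor(d)

    def test_resolution_robustness(self, chain100_cacno):
        """Descriptors of the same surface at dim 48 and 64 agree closely."""
        d48 = describe_grid(surface_unit_grid(chain100_cacno, dim=48)).values
        d64 = describe_grid(surface_unit_grid(chain100_cacno, dim=64)).values
        assert np.corrcoef(d48, d64)[0, 1] > 0.99


class TestReconstruct:
    def test_ball_reconstruction_spherical(self):
        moments = compute_moments(unit_ball_grid(radius=0.55), order=12)
        rec = reconstruct(moments, dim=48)
        rng = np.random.default_rng(1)
        directions = rng.normal(size=(200, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        coords = (0.35 * directions + 1.0) / (2.0 / 48) - 0.5
        samples = ndimage.map_coordinates(rec.values, coords.T, order=1)
        assert samples.std() / abs(samples.mean()) < 0.05

    @pytest.mark.parametrize("radius", [0.5, 0.65])
    def test_truncation_monotonicity(self, radius):
        """Higher-order reconstruction never fits the input worse."""
        grid = unit_ball_grid(radius=radius, dim=48, filled=False)
        moments = compute_moments(grid, order=20)
        ax = (np.arange(48) + 0.5 - 24) * (2.0 / 48)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = x**2 + y**2 + z**2 <= 1.0
        f = grid.values.astype(float)
        errs = []
        for cap in (10, 20):
            rec = reconstruct(moments, dim=48, order_cap=cap)
            errs.append(np.sqrt(np.mean((rec.values[mask] - f[mask]) ** 2)))
        assert errs[1] <= errs[0]

    def test_order_cap_zero_is_angularly_constant(self):
        moments = compute_moments(unit_ball_grid(radius=0.5, dim=32), order=8)
        rec = reconstruct(moments, dim=32, order_cap=0)
        ax = (np.arange(32) + 0.5 - 16) * (2.0 / 32)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(x**2 + y**2 + z**2)
        ring = (r > 0.4) & (r < 0.45)
        vals = rec.values[ring]
        assert vals.std() <= 1e-6 * max(abs(vals.mean()), 1e-30) + 1e-9

    def test_cap_above_order_raises(self):
        moments = compute_moments(unit_ball_grid(radius=0.5, dim=16), order=4)
        with pytest.raises(ValueError):
            reconstruct(moments, dim=16, order_cap=6)


class TestBasisOrthonormality:
    def test_gram_matrix_identity(self):
        """Numerically integrated Gram matrix is close to identity."""
        dim = 64
        ax = (np.arange(dim) + 0.5 - dim / 2) * (2.0 / dim)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = (x**2 + y**2 + z**2 <= 1.0).ravel()
        nlms, monos, chi = _basis_table(6)
        mono_vals = np.stack(
            [
                (x**a * y**b * z**c).ravel()[inside]
                for (a, b, c) in monos
            ]
        )
        basis = chi @ mono_vals  # each row: Z_nlm at the inside voxels
        gram = (3.0 / (4.0 * pi)) * (basis @ basis.conj().T) * (2.0 / dim) ** 3
        assert np.abs(gram - np.eye(len(nlms))).max() < 0.02


class TestCorrelation:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        d = Descriptor(order=20, values=rng.random(121))
        assert descriptor_correlation(d, d) == pytest.approx(1.0)

    def test_anticorrelation(self):
        base = np.linspace(0.0, 1.0, 121)
        a = Descriptor(order=20, values=base)
        b = Descriptor(order=20, values=base.max() - base)
        assert descriptor_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        av, bv = rng.random(121), rng.random(121)
        a = Descriptor(order=20, values=av)
        b = Descriptor(order=20, values=bv)
        # independent covariance-formula computation
        expected = (
            np.mean((av - av.mean()) * (bv - bv.mean())) / (av.std() * bv.std())
        )
        assert descriptor_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        a = Descriptor(order=20, values=np.full(121, 0.5))
        b = Descriptor(order=20, values=np.random.default_rng(0).random(121))
        with pytest.raises(ValueError):
            descriptor_correlation(a, b)

    def test_length_mismatch_raises(self):
        a = Descriptor(order=20, values=np.ones(121))
        b = Descriptor(order=10, values=np.ones(36))
        with pytest.raises(ValueError):
            descriptor_correlation(a, b)


class TestDescriptorIO:
    def test_round_trip_bit_stable(self):
        rng = np.random.default_rng(9)
        d = normalize_descriptor(Descriptor(order=20, values=rng.random(121)))
        d.meta.update({"id": "fix1", "rep": "cacno", "len": 87})
        buf = io.StringIO()
        write_descriptor(d, buf)
        buf.seek(0)
        back = read_descriptor(buf)
        np.testing.assert_array_equal(back.values, d.values)
        assert back.order == 20
        assert back.meta["id"] == "fix1"
        assert back.meta["rep"] == "cacno"
        assert back.meta["len"] == 87
        assert back.normalized

    def test_bad_header_raises(self):
        with pytest.raises(ValueError, match="descriptor file"):
            read_descriptor(io.StringIO("not a header\n1 2 3\n"))
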