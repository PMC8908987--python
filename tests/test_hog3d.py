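import numpy as np
import pytest

from lungcad.volume import VoxelVolume
from lungcad.descriptors.hog3d import (
    IntegralGradientVolume,
    SOLID_VERTICES,
    hog3d_descriptor,
    integral_gradient_volume,
    mean_gradient,
    partial_derivative_volumes,
    platonic_directions,
    vote,
)


def brute_integral(vd):
    out = np.zeros_like(vd)
    for x in range(vd.shape[0]):
        for y in range(vd.shape[1]):
            for z in range(vd.shape[2]):
                out[x, y, z] = vd[: x + 1, : y + 1, : z + 1].sum()
    return out


class TestDerivatives:
    def test_linear_ramp(self):
        ax = np.arange(8, dtype=float)
        x, _, _ = np.meshgrid(ax, ax, ax, indexing="ij")
        vdx, vdy, vdz = partial_derivative_volumes(VoxelVolume(x))
        np.testing.assert_allclose(vdx, 1.0)
        np.testing.assert_allclose(vdy, 0.0)
        np.testing.assert_allclose(vdz, 0.0)

    def test_constant_volume(self):
        for v in partial_derivative_volumes(np.full((5, 5, 5), 9.0)):
            np.testing.assert_allclose(v, 0.0)

    def test_analytic_gradient(self, ramp_volume):
        vdx, vdy, vdz = partial_derivative_volumes(ramp_volume)
        np.testing.assert_allclose(vdx, 1.0)
        np.testing.assert_allclose(vdy, 2.0)
        np.testing.assert_allclose(vdz, 3.0)


class TestIntegralVolume:
    def test_single_voxel(self):
        np.testing.assert_array_equal(
            integral_gradient_volume(np.array([[[4.0]]])), [[[4.0]]]
        )

    def test_all_ones_closed_form(self):
        iv = integral_gradient_volume(np.ones((3, 3, 3)))
        x, y, z = np.meshgrid(*[np.arange(3)] * 3, indexing="ij")
        np.testing.assert_allclose(iv, (x + 1) * (y + 1) * (z + 1))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            vd = rng.normal(size=(5, 5, 5))
            np.testing.assert_allclose(
                integral_gradient_volume(vd), brute_integral(vd), rtol=1e-9, atol=1e-9
            )

    def test_exhaustive_small_volumes(self):
        rng = np.random.default_rng(1)
        for shape in [(1, 1, 1), (2, 3, 4), (8, 8, 8)]:
            vd = rng.normal(size=shape)
            np.testing.assert_allclose(
                integral_gradient_volume(vd), brute_integral(vd), rtol=1e-9, atol=1e-9
            )


class TestMeanGradient:
    def test_whole_volume_ramp(self, ramp_volume):
        igv = IntegralGradientVolume.from_volume(VoxelVolume(ramp_volume))
        n = mean_gradient(igv, (0, 0, 0), 16, 16, 16)
        np.testing.assert_allclose(n, [1.0, 2.0, 3.0], rtol=1e-9)

    def test_constant_volume_zero(self):
        igv = IntegralGradientVolume.from_volume(VoxelVolume(np.full((6, 6, 6), 2.0)))
        np.testing.assert_allclose(mean_gradient(igv, (1, 1, 1), 3, 3, 3), 0.0, atol=1e-12)

    def test_random_queries_match_brute_force(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(32, 32, 32))
        vol = VoxelVolume(data)
        grads = np.stack(partial_derivative_volumes(vol), axis=-1)
        igv = IntegralGradientVolume.from_volume(vol)
        for _ in range(100):
            base = rng.integers(0, 28, size=3)
            size = rng.integers(1, 5, size=3)
            got = mean_gradient(igv, base, *size)
            sub = grads[base[0]:base[0] + size[0], base[1]:base[1] + size[1],
                        base[2]:base[2] + size[2]]
            np.testing.assert_allclose(got, sub.mean(axis=(0, 1, 2)), rtol=1e-9, atol=1e-9)

    def test_out_of_bounds_raises(self):
        igv = IntegralGradientVolume.from_volume(VoxelVolume(np.zeros((4, 4, 4))))
        with pytest.raises(ValueError):
            mean_gradient(igv, (2, 2, 2), 3, 3, 3)


class TestPlatonicDirections:
    @pytest.mark.parametrize("solid,count", [
        ("tetrahedron", 4), ("octahedron", 6), ("cube", 8),
        ("icosahedron", 12), ("dodecahedron", 20),
    ])
    def test_full_binning_counts(self, solid, count):
        bins = platonic_directions(solid, "full")
        assert bins.n_bins == count
        np.testing.assert_allclose(np.linalg.norm(bins.directions, axis=1), 1.0)

    @pytest.mark.parametrize("solid,count", [
        ("octahedron", 3), ("cube", 4), ("icosahedron", 6), ("dodecahedron", 10),
    ])
    def test_half_binning_folds_antipodes(self, solid, count):
        assert platonic_directions(solid, "half").n_bins == count

    def test_tetrahedron_threshold(self):
        bins = platonic_directions("tetrahedron", "full")
        assert bins.threshold == pytest.approx(-1.0 / 3.0)

    def test_threshold_is_max_pairwise_dot(self):
        bins = platonic_directions("dodecahedron", "full")
        d = bins.directions @ bins.directions.T
        np.fill_diagonal(d, -2)
        assert bins.threshold == pytest.approx(d.max())

    def test_unknown_solid_raises(self):
        with pytest.raises(ValueError):
            platonic_directions("prism", "full")


class TestVote:
    def test_gradient_along_bin_hits_one_bin_only(self):
        bins = platonic_directions("dodecahedron", "full")
        for i in range(bins.n_bins):
            w = vote(3.0 * bins.directions[i], bins)
            assert np.count_nonzero(w) == 1
            assert w[i] == pytest.approx(3.0)  # carries the magnitude

    def test_zero_gradient_votes_nothing(self):
        bins = platonic_directions("dodecahedron", "full")
        np.testing.assert_array_equal(vote(np.zeros(3), bins), np.zeros(20))

    def test_at_most_three_nonzero_components(self):
        bins = platonic_directions("dodecahedron", "full")
        rng = np.random.default_rng(3)
        for g in rng.normal(size=(1000, 3)):
            assert np.count_nonzero(vote(g, bins)) <= 3

    def test_vote_magnitude_preserved(self):
        bins = platonic_directions("icosahedron", "full")
        rng = np.random.default_rng(4)
        for g in rng.normal(size=(50, 3)):
            w = vote(g, bins)
            if np.any(w):
                assert np.linalg.norm(w) == pytest.approx(np.linalg.norm(g))


class TestDescriptor:
    def test_default_length(self, malignant_record):
        d = hog3d_descriptor(malignant_record.voi)
        assert len(d) == 125 * 20 and d.tag == "hog3d"

    def test_block_histograms_unit_or_zero(self, malignant_record):
        d = hog3d_descriptor(malignant_record.voi)
        blocks = d.values.reshape(125, 20)
        norms = np.linalg.norm(blocks, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))

    def test_shift_invariance(self, malignant_record):
        """Gradients ignore a constant offset; the nearest-3-bin selection has
        tie points where float round-off can swap a bin, so invariance is
        asserted on the aggregate rather than per element."""
        a = hog3d_descriptor(malignant_record.voi).values
        shifted = VoxelVolume(malignant_record.voi.data + 500.0)
        b = hog3d_descriptor(shifted).values
        assert np.abs(a - b).sum() / np.abs(a).sum() < 0.005

    def test_axis_permutation_equivariance_cube(self):
        """Swapping two volume axes permutes the cube-bin descriptor consistently."""
        rng = np.random.default_rng(5)
        data = rng.normal(size=(27, 27, 27))
        d0 = hog3d_descriptor(VoxelVolume(data), n_blocks=3, cell_size=3,
                              solid="cube", binning_style="full")
        d1 = hog3d_descriptor(VoxelVolume(data.transpose(1, 0, 2)), n_blocks=3,
                              cell_size=3, solid="cube", binning_style="full")
        v0 = d0.values.reshape(3, 3, 3, 8)
        v1 = d1.values.reshape(3, 3, 3, 8)
        # cube vertices enumerated (sx, sy, sz) with x fastest over sign pairs:
        # swapping x and y axes maps vertex (sx, sy, sz) -> (sy, sx, sz)
        verts = np.asarray(SOLID_VERTICES["cube"], dtype=float)
        perm = [int(np.argmax((verts == v[[1, 0, 2]]).all(axis=1))) for v in verts]
        np.testing.assert_allclose(v1.transpose(1, 0, 2, 3)[..., perm], v0, atol=1e-9)
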