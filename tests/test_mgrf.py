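import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import wilcoxon

from lungcad.volume import NoduleMask, VoxelVolume
from lungcad.phantoms import PhantomParams, make_benign_phantom, make_malignant_phantom
from lungcad.descriptors.mgrf import (
    DEFAULT_OFFSETS,
    MGRFEnergyExtractor,
    energy_histogram,
    gibbs_energy_image,
    train_mgrf,
)


def _toy_pair(seed, smooth):
    """12^3 volume with mask; smooth=True gives spatially correlated texture."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(12, 12, 12))
    if smooth:
        data = ndimage.gaussian_filter(data, 1.5)
    mask = np.zeros((12, 12, 12), bool)
    mask[2:-2, 2:-2, 2:-2] = True
    return VoxelVolume(100 * data), NoduleMask(mask)


class TestTraining:
    def test_offsets_cover_26_neighbourhood(self):
        full = set()
        for o in DEFAULT_OFFSETS:
            full.add(o)
            full.add(tuple(-c for c in o))
        assert len(full) == 26

    def test_deterministic(self):
        pairs = [_toy_pair(s, True) for s in range(3)]
        m1 = train_mgrf(pairs, q_levels=8)
        m2 = train_mgrf(pairs, q_levels=8)
        for o in m1.offsets:
            np.testing.assert_array_equal(m1.pair_potentials[o], m2.pair_potentials[o])
        np.testing.assert_array_equal(m1.star_potential, m2.star_potential)

    def test_single_level_quantisation_gives_zero_potentials(self):
        pairs = [_toy_pair(0, False)]
        model = train_mgrf(pairs, q_levels=1)
        for pot in model.pair_potentials.values():
            np.testing.assert_allclose(pot, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.star_potential, 0.0, atol=1e-12)

    def test_constant_training_concentrates_cooccurrence(self):
        """On a constant cube every pair realises one configuration; its potential
        is positive-centred, all others are -1/Q^2."""
        vol = VoxelVolume(np.zeros((5, 5, 5)))
        mask = NoduleMask(np.ones((5, 5, 5), bool))
        model = train_mgrf([(vol, mask)], q_levels=4, include_star=False)
        for pot in model.pair_potentials.values():
            hot = np.unravel_index(np.argmax(pot), pot.shape)
            assert hot[0] == hot[1]
            assert pot[hot] == pytest.approx(1.0 - 1.0 / 16.0)
            cold = pot[pot != pot[hot]]
            np.testing.assert_allclose(cold, -1.0 / 16.0, atol=1e-12)

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            train_mgrf([])


class TestEnergyImage:
    def test_outside_mask_is_zero_and_finite(self):
        pairs = [_toy_pair(s, True) for s in range(2)]
        model = train_mgrf(pairs, q_levels=8)
        vol, mask = _toy_pair(7, True)
        e = gibbs_energy_image(vol, mask, model)
        assert np.all(np.isfinite(e))
        assert np.all(e[~mask.data] == 0)

    def test_shape_mismatch_raises(self):
        pairs = [_toy_pair(0, True)]
        model = train_mgrf(pairs)
        vol, _ = _toy_pair(1, True)
        with pytest.raises(ValueError):
            gibbs_energy_image(vol, NoduleMask(np.ones((5, 5, 5), bool)), model)

    def test_training_texture_has_lower_energy_than_shuffled_null(self):
        """The model learns spatial structure: shuffling voxels raises energy."""
        pairs = [_toy_pair(s, True) for s in range(5)]
        model = train_mgrf(pairs, q_levels=8)
        rng = np.random.default_rng(0)
        reals, nulls = [], []
        for s in range(5):
            vol, mask = _toy_pair(100 + s, True)
            reals.append(gibbs_energy_image(vol, mask, model)[mask.data].mean())
            shuffled = vol.data.copy()
            vals = shuffled[mask.data]
            rng.shuffle(vals)
            shuffled[mask.data] = vals
            nulls.append(
                gibbs_energy_image(VoxelVolume(shuffled), mask, model)[mask.data].mean()
            )
        assert np.mean(reals) < np.mean(nulls)

    def test_homogeneous_vs_heterogeneous_contrast(self):
        """Benign-trained model separates homogeneous from heterogeneous interiors."""
        train = [make_benign_phantom(PhantomParams(seed=s)) for s in range(8)]
        model = train_mgrf(train)
        diffs = []
        for s in range(15):
            b = make_benign_phantom(PhantomParams(seed=500 + s))
            m = make_malignant_phantom(seed=600 + s)
            eb = gibbs_energy_image(b.voi, b.mask, model)[b.mask.data].mean()
            em = gibbs_energy_image(m.voi, m.mask, model)[m.mask.data].mean()
            diffs.append(em - eb)
        assert wilcoxon(diffs, alternative="greater").pvalue < 0.01


class TestHistogram:
    @pytest.mark.parametrize("n_bins", [400, 600, 800, 1000])
    def test_bin_grid_supported_and_normalised(self, n_bins):
        vol, mask = _toy_pair(3, True)
        model = train_mgrf([(vol, mask)], q_levels=8)
        e = gibbs_energy_image(vol, mask, model)
        h = energy_histogram(e, mask, n_bins=n_bins, energy_range=model.energy_range)
        assert len(h) == n_bins
        assert h.values.sum() == pytest.approx(1.0)

    def test_too_few_bins_raises(self):
        vol, mask = _toy_pair(3, True)
        with pytest.raises(ValueError):
            energy_histogram(np.zeros(vol.shape), mask, n_bins=1)


class TestExtractor:
    def test_fit_uses_benign_records_only(self):
        recs = [make_benign_phantom(PhantomParams(seed=s)) for s in range(3)]
        recs += [make_malignant_phantom(seed=10)]
        ext = MGRFEnergyExtractor(n_bins=400).fit(recs)
        X = ext.transform(recs)
        assert X.shape == (4, 400)
        np.testing.assert_allclose(X.sum(axis=1), 1.0)

    def test_transform_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            MGRFEnergyExtractor().describe(make_malignant_phantom(seed=1))
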