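"""Synthetic lung phantom generator."""

import numpy as np
import pytest
from scipy import stats

from strainpet import PhantomParams, generate_phantom, read_phantom, write_phantom
from strainpet.profiles import layer_profile


def _small(**kw):
    base = dict(grid_shape=(8, 64, 16), seed=0)
    base.update(kw)
    return PhantomParams(**base)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(aeration_top=1.2),
            dict(atelectasis_depth_fraction=-0.1),
            dict(coupling_kappa=1.5),
            dict(inflation_factor=0.9),
            dict(pet_noise_sd=-1.0),
            dict(ct_noise_sd=-0.1),
            dict(voxel_volume=0.0),
            dict(aeration_gradient=-0.2),
            dict(reopened_gas_fraction=2.0),
            dict(gravity_axis=3),
            dict(blood_pool_activity=0.0),
        ],
    )
    def test_nonphysical_params_rejected(self, kw):
        with pytest.raises(ValueError):
            _small(**kw)

    def test_dict_roundtrip(self):
        p = _small(coupling_kappa=0.7)
        assert PhantomParams.from_dict(p.to_dict()) == p


class TestGeneration:
    def test_determinism_under_fixed_seed(self):
        a = generate_phantom(_small(seed=7))
        b = generate_phantom(_small(seed=7))
        np.testing.assert_array_equal(a.ct_ref.hu, b.ct_ref.hu)
        np.testing.assert_array_equal(a.ct_inflated.hu, b.ct_inflated.hu)
        np.testing.assert_array_equal(a.pet, b.pet)
        np.testing.assert_array_equal(a.truth_strain, b.truth_strain)
        c = generate_phantom(_small(seed=8))
        assert not np.array_equal(a.pet, c.pet)

    def test_masks_disjoint_and_shapes_consistent(self):
        ph = generate_phantom(_small())
        assert not (ph.lung_mask & ph.ref_roi_mask).any()
        for vol in (ph.ct_ref.hu, ph.ct_inflated.hu, ph.pet, ph.truth_strain):
            assert vol.shape == ph.lung_mask.shape

    def test_coupling_off_gives_constant_lung_activity(self):
        ph = generate_phantom(
            _small(coupling_kappa=0.0, pet_noise_sd=0.0, ct_noise_sd=0.0)
        )
        lung_pet = ph.pet[ph.lung_mask]
        np.testing.assert_allclose(lung_pet, ph.params.activation_baseline)

    def test_homogeneous_phantom_uniform_hu(self):
        ph = generate_phantom(
            _small(
                atelectasis_depth_fraction=0.0,
                aeration_gradient=0.0,
                pet_noise_sd=0.0,
                ct_noise_sd=0.0,
            )
        )
        hu = ph.ct_ref.hu[ph.lung_mask]
        np.testing.assert_allclose(hu, hu[0])

    def test_aeration_decreases_with_depth(self):
        """Reference gas fraction is monotonically non-increasing layer by
        layer on a noise-free phantom."""
        ph = generate_phantom(
            _small(atelectasis_depth_fraction=0.25, pet_noise_sd=0.0, ct_noise_sd=0.0)
        )
        frac = -ph.ct_ref.hu / 1000.0
        prof = layer_profile(frac, ph.lung_mask, ph.ct_ref.gravity_axis, n_layers=50)
        means = prof.layer_mean[~np.isnan(prof.layer_mean)]
        assert np.all(np.diff(means) <= 1e-12)
        # dependent zone fully degassed
        assert means[-1] == pytest.approx(0.0, abs=1e-12)

    def test_inflation_rule(self):
        """Ventilated voxels multiply gas by the inflation factor (no cap
        reached here); reopened atelectatic voxels get the reopening gas."""
        p = _small(
            aeration_top=0.45,
            aeration_gradient=0.2,
            atelectasis_depth_fraction=0.2,
            inflation_factor=1.8,
            pet_noise_sd=0.0,
            ct_noise_sd=0.0,
        )
        ph = generate_phantom(p)
        f_ref = -ph.ct_ref.hu / 1000.0
        f_inf = -ph.ct_inflated.hu / 1000.0
        vent = ph.lung_mask & (f_ref > 0)
        closed = ph.lung_mask & (f_ref == 0)
        np.testing.assert_allclose(f_inf[vent], f_ref[vent] * 1.8, rtol=1e-12)
        np.testing.assert_allclose(f_inf[closed], p.reopened_gas_fraction, rtol=1e-12)

    def test_truth_strain_nonnegative_inside_lung(self):
        for kw in (dict(), dict(atelectasis_depth_fraction=0.3, inflation_factor=4.0),
                   dict(reopen_atelectasis=False, atelectasis_depth_fraction=0.3)):
            ph = generate_phantom(_small(**kw))
            assert (ph.truth_strain[ph.lung_mask] >= 0).all()

    def test_gas_conservation_noise_free(self):
        """Gas fraction reconstructed from generated HU equals the
        generator's gas field to machine precision."""
        ph = generate_phantom(
            _small(atelectasis_depth_fraction=0.3, pet_noise_sd=0.0, ct_noise_sd=0.0)
        )
        f = -ph.ct_ref.hu[ph.lung_mask] / 1000.0
        assert f.min() >= 0.0 and f.max() <= 1.0
        # the HU transform is exactly linear, so reconstruction is exact
        hu_again = -1000.0 * f
        np.testing.assert_array_equal(hu_again, ph.ct_ref.hu[ph.lung_mask])

    def test_monotone_coupling_rank_correlation(self):
        ph = generate_phantom(
            _small(
                atelectasis_depth_fraction=0.2,
                inflation_factor=4.0,
                coupling_kappa=0.8,
                pet_noise_sd=0.0,
                ct_noise_sd=0.0,
            )
        )
        s = ph.truth_strain[ph.lung_mask]
        a = ph.truth_activation[ph.lung_mask]
        rho = stats.spearmanr(s, a).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_blood_pool_mean_activity(self):
        ph = generate_phantom(_small(blood_pool_activity=2.5, pet_noise_sd=0.0))
        assert ph.pet[ph.ref_roi_mask].mean() == pytest.approx(2.5)


class TestSerialization:
    def test_write_read_roundtrip(self, tmp_path, small_phantom):
        paths = write_phantom(small_phantom, tmp_path)
        assert len(paths) == 7
        back = read_phantom(tmp_path)
        np.testing.assert_allclose(back.ct_ref.hu, small_phantom.ct_ref.hu)
        np.testing.assert_allclose(back.pet, small_phantom.pet)
        np.testing.assert_array_equal(back.lung_mask, small_phantom.lung_mask)
        np.testing.assert_allclose(back.truth_strain, small_phantom.truth_strain)
        assert back.params == small_phantom.params

    def test_consistent_affines(self, tmp_path, small_phantom):
        import nibabel as nib

        paths = write_phantom(small_phantom, tmp_path)
        affines = [nib.load(p).affine for p in paths.values()]
        for a in affines[1:]:
            np.testing.assert_array_equal(a, affines[0])

    def test_missing_directory_rejected(self, tmp_path, small_phantom):
        with pytest.raises(FileNotFoundError):
            write_phantom(small_phantom, tmp_path / "nope")
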