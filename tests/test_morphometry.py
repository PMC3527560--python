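"""TBM/VBM maps, weight images and the weighted ROI feature."""
import numpy as np
import pytest
from scipy import stats

from ftdmorph import synthetic as syn
from ftdmorph.imgio import Geometry, Volume, make_roi_mask
from ftdmorph.morphometry import (
    FWHM_TO_SIGMA,
    GMDensityMap,
    gm_density_map,
    mean_log_jacobian,
    modulate,
    roi_weighted_feature,
    weight_image,
)
from ftdmorph.registration import DeformationField


def _vol(data, spacing=(1, 1, 1)):
    return Volume(np.asarray(data, dtype=float), spacing)


class TestMeanLogJacobian:
    def test_identity_fields_give_zero(self):
        geom = Geometry((6, 6, 6), (2, 2, 2))
        m = mean_log_jacobian(fields=[DeformationField.identity(geom)] * 3)
        np.testing.assert_allclose(m.values.data, 0.0, atol=1e-12)
        assert m.n_templates == 3

    def test_reciprocal_jacobians_cancel(self):
        j1 = _vol(np.full((4, 4, 4), 2.0))
        j2 = _vol(np.full((4, 4, 4), 0.5))
        m = mean_log_jacobian(jacobians=[j1, j2])
        np.testing.assert_allclose(m.values.data, 0.0, atol=1e-14)

    def test_matches_log_geometric_mean_oracle(self, rng):
        jacobians = [_vol(rng.uniform(0.3, 3.0, (5, 5, 5))) for _ in range(30)]
        m = mean_log_jacobian(jacobians=jacobians)
        # direct product oracle
        prod = np.ones((5, 5, 5))
        for j in jacobians:
            prod *= j.data
        np.testing.assert_allclose(m.values.data, np.log(prod ** (1 / 30)), atol=1e-10)

    def test_nonpositive_jacobian_names_template_and_voxel(self):
        good = _vol(np.ones((3, 3, 3)))
        bad = _vol(np.ones((3, 3, 3)))
        bad.data[1, 2, 0] = -0.2
        with pytest.raises(ValueError, match=r"template 1.*\(1, 2, 0\)"):
            mean_log_jacobian(jacobians=[good, bad])


class TestWeightImage:
    def test_identical_groups_give_zero_weights(self, rng):
        maps = [_vol(rng.standard_normal((4, 4, 4))) for _ in range(3)]
        w = weight_image(maps, [m.with_data(m.data.copy()) for m in maps])
        np.testing.assert_allclose(w.t_map.data, 0.0)
        np.testing.assert_allclose(w.w_map.data, 0.0)

    def test_t_matches_pooled_variance_oracle(self):
        # two small printed samples at a single voxel
        a_vals = [1.0, 2.0, 3.0, 4.0]
        b_vals = [2.5, 3.5, 4.5]
        A = [_vol(np.full((1, 1, 1), v)) for v in a_vals]
        B = [_vol(np.full((1, 1, 1), v)) for v in b_vals]
        w = weight_image(A, B, p_threshold=1.0)
        na, nb = len(a_vals), len(b_vals)
        sa = np.var(a_vals, ddof=1)
        sb = np.var(b_vals, ddof=1)
        sp2 = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
        t_hand = (np.mean(a_vals) - np.mean(b_vals)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert w.t_map.data[0, 0, 0] == pytest.approx(t_hand, abs=1e-12)
        p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
        assert w.p_map.data[0, 0, 0] == pytest.approx(p_hand, abs=1e-12)
        assert w.w_map.data[0, 0, 0] == pytest.approx(np.sign(t_hand) * (1 - p_hand))

    def test_support_shrinks_with_threshold(self, rng):
        A = [_vol(rng.standard_normal((6, 6, 6)) + 0.8) for _ in range(8)]
        B = [_vol(rng.standard_normal((6, 6, 6))) for _ in range(8)]
        supports = [
            (weight_image(A, B, p_threshold=thr).w_map.data != 0) for thr in (0.2, 0.05, 0.01)
        ]
        assert supports[0].sum() >= supports[1].sum() >= supports[2].sum()
        assert not (supports[1] & ~supports[0]).any()  # nested

    def test_sign_convention_follows_t(self, rng):
        A = [_vol(rng.standard_normal((4, 4, 4)) + 2.0) for _ in range(6)]
        B = [_vol(rng.standard_normal((4, 4, 4))) for _ in range(6)]
        w = weight_image(A, B, p_threshold=0.5)
        nz = w.w_map.data != 0
        assert (np.sign(w.w_map.data[nz]) == np.sign(w.t_map.data[nz])).all()


class TestROIWeightedFeature:
    def _weights_from(self, t_data, w_data, spacing=(1, 1, 1)):
        from ftdmorph.morphometry import WeightImage

        return WeightImage(
            _vol(t_data, spacing), _vol(1.0 - np.abs(w_data), spacing),
            _vol(w_data, spacing), p_threshold=0.05,
        )

    def test_empty_weights_flagged_zero(self):
        w = self._weights_from(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))
        val, empty = roi_weighted_feature(_vol(np.ones((3, 3, 3))), w, _vol(np.ones((3, 3, 3))))
        assert val == 0.0 and empty

    def test_single_atrophic_voxel_reduces_to_value(self):
        t = np.zeros((3, 3, 3)); t[1, 1, 1] = 3.0
        wmap = np.zeros((3, 3, 3)); wmap[1, 1, 1] = 0.9
        v = np.zeros((3, 3, 3)); v[1, 1, 1] = 2.0
        val, empty = roi_weighted_feature(
            _vol(v), self._weights_from(t, wmap), _vol(np.ones((3, 3, 3)))
        )
        assert not empty
        assert val == pytest.approx(2.0)

    def test_matches_voxel_loop_oracle(self, rng):
        shape = (6, 6, 6)
        t = rng.standard_normal(shape)
        wmap = np.sign(t) * rng.uniform(0, 1, shape) * (rng.random(shape) < 0.7)
        v = rng.standard_normal(shape)
        mask = (rng.random(shape) < 0.5).astype(float)
        val, _ = roi_weighted_feature(_vol(v), self._weights_from(t, wmap), _vol(mask))
        num = 0.0
        den = 0.0
        for idx in np.ndindex(shape):
            if mask[idx] == 0:
                continue
            den += abs(wmap[idx])
            if wmap[idx] == 0:
                continue
            if t[idx] > 0:  # atrophic partition under the fixed convention
                num += abs(wmap[idx]) * v[idx]
            elif t[idx] < 0:
                num -= abs(wmap[idx]) * v[idx]
        assert val == pytest.approx(num / den, abs=1e-12)

    def test_linear_in_value_map(self, rng):
        shape = (5, 5, 5)
        t = rng.standard_normal(shape)
        wmap = np.sign(t) * rng.uniform(0, 1, shape)
        w = self._weights_from(t, wmap)
        mask = _vol(np.ones(shape))
        v1, v2 = rng.standard_normal(shape), rng.standard_normal(shape)
        f1, _ = roi_weighted_feature(_vol(v1), w, mask)
        f2, _ = roi_weighted_feature(_vol(v2), w, mask)
        f12, _ = roi_weighted_feature(_vol(2.0 * v1 + 3.0 * v2), w, mask)
        assert f12 == pytest.approx(2 * f1 + 3 * f2, abs=1e-10)

    def test_geometry_mismatch_rejected(self):
        w = self._weights_from(np.ones((3, 3, 3)), np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="grid"):
            roi_weighted_feature(_vol(np.ones((4, 4, 4))), w, _vol(np.ones((3, 3, 3))))


class TestGMDensity:
    def test_default_fwhm(self):
        import inspect

        assert inspect.signature(gm_density_map).parameters["fwhm_mm"].default == 4.7

    def test_constant_map_identity_field_unchanged(self):
        # away from the zero-padded boundary the constant is preserved
        geom = Geometry((16, 16, 16), (2, 2, 2))
        gm = Volume(np.full(geom.shape, 0.6), geom.spacing)
        out = gm_density_map(gm, DeformationField.identity(geom), fwhm_mm=4.7)
        np.testing.assert_allclose(out.values.data[6:-6, 6:-6, 6:-6], 0.6, atol=1e-9)

    def test_delta_spike_matches_gaussian_kernel(self):
        geom = Geometry((25, 25, 25), (1, 1, 1))
        gm = np.zeros(geom.shape)
        gm[12, 12, 12] = 1.0
        out = gm_density_map(Volume(gm, geom.spacing), DeformationField.identity(geom), 4.7)
        sigma = 4.7 * FWHM_TO_SIGMA
        assert sigma == pytest.approx(1.996, abs=0.01)
        x = np.arange(25) - 12.0
        gauss = np.exp(-(x**2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        kernel3 = gauss[:, None, None] * gauss[None, :, None] * gauss[None, None, :]
        np.testing.assert_allclose(out.values.data, kernel3, atol=5e-5)
        assert out.values.data.sum() == pytest.approx(1.0, abs=1e-6)  # interior mass

    def test_nonpositive_fwhm_rejected(self):
        geom = Geometry((4, 4, 4), (1, 1, 1))
        gm = Volume(np.zeros(geom.shape), geom.spacing)
        with pytest.raises(ValueError, match="fwhm"):
            gm_density_map(gm, DeformationField.identity(geom), fwhm_mm=0.0)


class TestModulation:
    def test_unit_jacobian_is_identity(self, rng):
        d = GMDensityMap(_vol(rng.uniform(0, 1, (5, 5, 5))))
        out = modulate(d, _vol(np.ones((5, 5, 5))))
        np.testing.assert_array_equal(out.values.data, d.values.data)
        assert out.modulated

    def test_double_modulation_rejected(self, rng):
        d = GMDensityMap(_vol(rng.uniform(0, 1, (4, 4, 4))))
        jac = _vol(np.full((4, 4, 4), 1.1))
        with pytest.raises(ValueError, match="modulated"):
            modulate(modulate(d, jac), jac)

    def test_mass_conserved_under_uniform_scaling(self, phantom):
        # subject = globally scaled template; modulated GM in template space
        # must equal the subject's native GM volume
        from ftdmorph.registration import apply_deformation, jacobian_determinant

        img, lab, truth = syn.synthesize_subject(phantom, {}, icv_factor=1.1, noise_sd=0.0)
        gm_subj = Volume(
            np.isin(lab.labels, sorted(syn.TISSUE_GM)).astype(float), lab.spacing
        )
        field = truth.warp.displacement_field(phantom.labels.geometry)
        propagated = apply_deformation(gm_subj, field, mode="linear")
        jac = jacobian_determinant(field)
        modulated = propagated.data * jac.data
        vox = phantom.labels.geometry.voxel_volume_mm3
        native = gm_subj.data.sum() * vox
        assert modulated.sum() * vox == pytest.approx(native, rel=0.02)

    def test_modulation_commutes_with_masking(self, rng):
        d = GMDensityMap(_vol(rng.uniform(0, 1, (5, 5, 5))))
        jac = _vol(rng.uniform(0.5, 1.5, (5, 5, 5)))
        mask = rng.random((5, 5, 5)) < 0.5
        a = modulate(d, jac).values.data[mask].sum()
        b = (d.values.data * jac.data)[mask].sum()
        assert a == pytest.approx(b, abs=1e-12)


class TestTBMProperties:
    def test_identity_subject_has_zero_feature_everywhere(self, phantom, rng):
        geom = phantom.labels.geometry
        m = mean_log_jacobian(fields=[DeformationField.identity(geom)] * 5)
        t = rng.standard_normal(geom.shape)
        wmap = np.sign(t) * rng.uniform(0, 1, geom.shape)
        from ftdmorph.morphometry import WeightImage

        w = WeightImage(
            Volume(t, geom.spacing), Volume(1 - np.abs(wmap), geom.spacing),
            Volume(wmap, geom.spacing), 0.05,
        )
        for roi in syn.ROI_DEFINITIONS:
            val, _ = roi_weighted_feature(m.values, w, make_roi_mask(phantom.labels, roi))
            assert val == 0.0

    def test_stronger_atrophy_gives_larger_group_difference(self, phantom_coarse):
        # rank agreement between simulated atrophy strength and the TBM
        # group-mean feature difference
        factors = {
            "hippocampus_amygdala": 0.75,
            "posterior_temporal": 0.90,
            "superior_frontal": 0.97,
        }
        geom = phantom_coarse.labels.geometry
        diffs = {}
        n = 6
        rng = np.random.default_rng(0)
        disease_maps, control_maps = [], []
        for i in range(n):
            _im, _lab, tr = syn.synthesize_subject(phantom_coarse, factors, 1.0, rng=rng)
            fld = syn.make_field_set(phantom_coarse, [tr], 0.4, seed=i)[0]
            disease_maps.append(mean_log_jacobian(fields=[fld]).values)
            _im, _lab, tr0 = syn.synthesize_subject(phantom_coarse, {}, 1.0, rng=rng)
            fld0 = syn.make_field_set(phantom_coarse, [tr0], 0.4, seed=100 + i)[0]
            control_maps.append(mean_log_jacobian(fields=[fld0]).values)
        w = weight_image(control_maps, disease_maps, p_threshold=0.05)
        for roi_name in factors:
            roi = next(r for r in syn.ROI_DEFINITIONS if r.name == roi_name)
            mask = make_roi_mask(phantom_coarse.labels, roi)
            d = np.mean([roi_weighted_feature(m, w, mask)[0] for m in disease_maps])
            c = np.mean([roi_weighted_feature(m, w, mask)[0] for m in control_maps])
            diffs[roi_name] = abs(d - c)
        assert (
            diffs["hippocampus_amygdala"] > diffs["posterior_temporal"] > diffs["superior_frontal"]
        )
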