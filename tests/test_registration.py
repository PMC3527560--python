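"""Deformation fields, Jacobians and the bundled registration backend."""
import numpy as np
import pytest

from ftdmorph import synthetic as syn
from ftdmorph.imgio import Geometry, LabelVolume, Volume
from ftdmorph.registration import (
    DeformationField,
    RegistrationConfig,
    apply_deformation,
    bending_energy,
    correlation_ratio,
    jacobian_determinant,
    nmi,
    register_nonrigid,
)


def _scaling_field(geom: Geometry, s: float, center: np.ndarray | None = None) -> DeformationField:
    """phi(x) = c + s (x - c)."""
    world = geom.index_grid_world()
    c = center if center is not None else world.reshape(-1, 3).mean(axis=0)
    u = (s - 1.0) * (world - c)
    return DeformationField(u, geom.spacing, geom.origin)


class TestJacobian:
    def test_identity_field_gives_unity(self):
        geom = Geometry((8, 8, 8), (1.5, 1.5, 1.5))
        J = jacobian_determinant(DeformationField.identity(geom))
        np.testing.assert_allclose(J.data, 1.0)

    def test_uniform_half_scaling_gives_eighth(self):
        geom = Geometry((10, 10, 10), (2.0, 2.0, 2.0))
        J = jacobian_determinant(_scaling_field(geom, 0.5))
        np.testing.assert_allclose(J.data[1:-1, 1:-1, 1:-1], 0.125, atol=1e-12)

    def test_polynomial_field_matches_hand_derivative(self):
        # u = (a x^2, b x y, c z^2) -> F = I + [[2ax, by, 0], [0, bx, 0], [0, 0, 2cz]]
        # det = (1 + 2ax)(1 + bx)(1 + 2cz), exact for the quadratic since
        # central differences are exact on polynomials of degree <= 2
        geom = Geometry((16, 16, 16), (1.0, 1.0, 1.0))
        a, b, c = 0.004, 0.006, 0.003
        w = geom.index_grid_world()
        x, y, z = w[..., 0], w[..., 1], w[..., 2]
        u = np.stack([a * x**2, b * x * y, c * z**2], axis=-1)
        J = jacobian_determinant(DeformationField(u, geom.spacing)).data
        expected = (1 + 2 * a * x) * (1 + b * x) * (1 + 2 * c * z)
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(J[interior], expected[interior], atol=1e-3)

    def test_composed_scalings_multiply(self):
        geom = Geometry((12, 12, 12), (1.0, 1.0, 1.0))
        c = geom.index_grid_world().reshape(-1, 3).mean(axis=0)
        s1, s2 = 0.9, 1.1
        J1 = jacobian_determinant(_scaling_field(geom, s1, c)).data
        J2 = jacobian_determinant(_scaling_field(geom, s2, c)).data
        J12 = jacobian_determinant(_scaling_field(geom, s1 * s2, c)).data
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(J12[interior], (J1 * J2)[interior], atol=1e-6)

    def test_degenerate_determinant_reported_with_voxel(self):
        geom = Geometry((8, 8, 8), (1.0, 1.0, 1.0))
        J_neg = _scaling_field(geom, -0.5)
        with pytest.raises(ValueError, match=r"\["):
            jacobian_determinant(J_neg, check_positive=True)


class TestApplyDeformation:
    def test_identity_returns_input(self, rng):
        geom = Geometry((6, 7, 8), (1, 2, 3))
        vol = Volume(rng.standard_normal(geom.shape), geom.spacing)
        out = apply_deformation(vol, DeformationField.identity(geom))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_constant_shift_on_ramp_matches_closed_form(self):
        geom = Geometry((12, 6, 6), (1.0, 1.0, 1.0))
        x = geom.index_grid_world()[..., 0]
        ramp = Volume(3.0 * x, geom.spacing)
        u = np.zeros(geom.shape + (3,))
        u[..., 0] = 2.0
        out = apply_deformation(ramp, DeformationField(u, geom.spacing))
        np.testing.assert_allclose(out.data[:-2], 3.0 * (x[:-2] + 2.0), atol=1e-10)

    def test_label_propagation_preserves_label_set(self, rng):
        geom = Geometry((8, 8, 8), (2.0, 2.0, 2.0))
        lab = LabelVolume(
            rng.integers(0, 3, geom.shape).astype(np.int32), geom.spacing,
            table={1: "a", 2: "b"},
        )
        u = rng.normal(0, 1.0, geom.shape + (3,))
        out = apply_deformation(lab, DeformationField(u, geom.spacing), mode="nearest")
        assert set(np.unique(out.labels)) <= set(np.unique(lab.labels))

    def test_true_warp_aligns_subject_labels_with_template(self, phantom, rng):
        # pulling subject labels back through the true field reproduces the
        # template hippocampus with high overlap
        _img, lab, truth = syn.synthesize_subject(
            phantom, {"hippocampus_amygdala": 0.8}, 1.02, rng=rng
        )
        field = truth.warp.displacement_field(phantom.labels.geometry)
        pulled = apply_deformation(lab, field, mode="nearest")
        a = np.isin(pulled.labels, [10, 11])
        b = np.isin(phantom.labels.labels, [10, 11])
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.9

    def test_nonfinite_field_rejected(self):
        geom = Geometry((4, 4, 4), (1, 1, 1))
        u = np.zeros(geom.shape + (3,))
        u[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            DeformationField(u, geom.spacing)


class TestSimilarityMeasures:
    def test_nmi_matches_brute_force_histogram(self):
        a = np.array([[[0.0], [1.0], [2.0], [3.0]],
                      [[1.0], [1.0], [2.0], [0.0]],
                      [[3.0], [2.0], [2.0], [1.0]],
                      [[0.0], [0.0], [1.0], [3.0]]])
        b = (a * 2 + 1) % 4
        n_bins = 32

        def brute_nmi(x, y):
            hist = np.zeros((n_bins, n_bins))
            xb = np.clip(((x - x.min()) / (np.ptp(x)) * n_bins).astype(int), 0, n_bins - 1)
            yb = np.clip(((y - y.min()) / (np.ptp(y)) * n_bins).astype(int), 0, n_bins - 1)
            for xi, yi in zip(xb.ravel(), yb.ravel()):
                hist[xi, yi] += 1
            p = hist / hist.sum()
            px, py = p.sum(1), p.sum(0)
            h = lambda q: -(q[q > 0] * np.log(q[q > 0])).sum()
            return (h(px) + h(py)) / h(p.ravel())

        assert nmi(a, b, n_bins) == pytest.approx(brute_nmi(a, b), abs=1e-12)

    def test_self_similarity_is_maximal(self, rng):
        img = rng.standard_normal((6, 6, 6))
        other = rng.standard_normal((6, 6, 6))
        assert nmi(img, img) > nmi(img, other)
        assert correlation_ratio(img, img) > correlation_ratio(img, other)


class TestRegisterNonrigid:
    def test_identity_registration_is_near_zero(self, phantom):
        fld = register_nonrigid(phantom.intensity, phantom.intensity,
                                RegistrationConfig(max_iter=15))
        mean_disp_vox = np.linalg.norm(fld.displacement, axis=-1).mean() / min(phantom.spec.spacing)
        assert mean_disp_vox < 0.1
        assert fld.quality_flag == "ok"

    def test_two_voxel_translation_recovered(self, phantom):
        shift_vox = 2
        moving = Volume(np.roll(phantom.intensity.data, -shift_vox, axis=0),
                        phantom.intensity.spacing)
        fld = register_nonrigid(phantom.intensity, moving, RegistrationConfig(max_iter=40))
        brain = phantom.labels.labels > 0
        ux = fld.displacement[..., 0][brain].mean()
        true_ux = -shift_vox * phantom.spec.spacing[0]
        assert abs(ux - true_ux) <= 0.5 * phantom.spec.spacing[0]

    def test_more_regularization_reduces_bending_energy(self, phantom, rng):
        img, _lab, _truth = syn.synthesize_subject(
            phantom, {"hippocampus_amygdala": 0.8}, 1.0, rng=rng
        )
        energies = []
        for w in (0.5, 2.0, 6.0):
            fld = register_nonrigid(
                phantom.intensity, img, RegistrationConfig(max_iter=20, regularization_weight=w)
            )
            energies.append(bending_energy(fld))
        assert energies[0] >= energies[1] >= energies[2]

    @pytest.mark.parametrize("similarity", ["nmi", "correlation_ratio"])
    def test_histogram_similarities_align_rescaled_images(self, phantom, similarity):
        # a 2-voxel shift plus an affine intensity change: only the
        # histogram-based similarities can drive this registration
        shift_vox = 2
        moving = Volume(
            np.roll(phantom.intensity.data, -shift_vox, axis=0) * 1.7 + 40.0,
            phantom.intensity.spacing,
        )
        cfg = RegistrationConfig(similarity=similarity, max_iter=40)
        fld = register_nonrigid(phantom.intensity, moving, cfg)
        assert fld.quality_flag == "ok"
        brain = phantom.labels.labels > 0
        ux = fld.displacement[..., 0][brain].mean()
        true_ux = -shift_vox * phantom.spec.spacing[0]
        assert abs(ux - true_ux) <= 0.75 * phantom.spec.spacing[0]

    def test_unknown_similarity_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(similarity="ssd")
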