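"""Atlas selection, probabilistic fusion, EM classification and volumetry."""
import numpy as np
import pytest

from ftdmorph import synthetic as syn
from ftdmorph.imgio import LabelVolume, Volume
from ftdmorph.registration import DeformationField
from ftdmorph.segmentation import (
    Atlas,
    MultiAtlasConfig,
    ProbabilisticAtlas,
    TissueModel,
    build_probabilistic_atlas,
    em_classify,
    hippocampus_area_mask,
    register_library_to_template,
    segment_multiatlas,
    select_atlases,
    structure_volume,
)


def _toy_atlas(labels: np.ndarray, name: str, table=None) -> Atlas:
    table = table or {int(i): f"s{int(i)}" for i in np.unique(labels) if i != 0}
    intensity = Volume(labels.astype(float) * 10.0, (1, 1, 1))
    return Atlas(intensity, LabelVolume(labels.astype(np.int32), (1, 1, 1), table=table), name)


class TestSelectAtlases:
    def test_identical_atlas_ranked_first(self, rng):
        patient = Volume(rng.standard_normal((8, 8, 8)), (1, 1, 1))
        twin = Atlas(Volume(patient.data.copy(), (1, 1, 1)),
                     LabelVolume(np.zeros((8, 8, 8), np.int32), (1, 1, 1)), "twin")
        others = [
            Atlas(Volume(rng.standard_normal((8, 8, 8)), (1, 1, 1)),
                  LabelVolume(np.zeros((8, 8, 8), np.int32), (1, 1, 1)), f"o{i}")
            for i in range(4)
        ]
        mask = Volume(np.ones((8, 8, 8), np.uint8), (1, 1, 1))
        chosen = select_atlases(patient, others + [twin], mask, k=2)
        assert chosen[0].name == "twin"

    def test_default_selection_count_is_five(self):
        assert MultiAtlasConfig().k_select == 5

    def test_empty_mask_rejected(self, rng):
        patient = Volume(rng.standard_normal((4, 4, 4)), (1, 1, 1))
        atlas = _toy_atlas(np.zeros((4, 4, 4)), "a")
        mask = Volume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.raises(ValueError, match="mask"):
            select_atlases(patient, [atlas], mask, k=1)


class TestProbabilisticAtlas:
    def _identity_fields(self, shape, n):
        from ftdmorph.imgio import Geometry

        return [DeformationField.identity(Geometry(shape, (1, 1, 1))) for _ in range(n)]

    def test_unanimous_votes_give_indicators(self, rng):
        labels = rng.integers(0, 3, (5, 5, 5))
        atlases = [_toy_atlas(labels, f"a{i}", {1: "x", 2: "y"}) for i in range(4)]
        patient = atlases[0].intensity
        prob, _ = build_probabilistic_atlas(
            patient, atlases, fields=self._identity_fields((5, 5, 5), 4)
        )
        assert set(np.unique(prob.probabilities)) <= {0.0, 1.0}

    def test_three_of_five_votes_give_point_six(self):
        base = np.zeros((3, 3, 3))
        voted = base.copy()
        voted[1, 1, 1] = 2
        table = {2: "gm"}
        atlases = [_toy_atlas(voted if i < 3 else base, f"a{i}", table) for i in range(5)]
        patient = atlases[0].intensity
        prob, _ = build_probabilistic_atlas(
            patient, atlases, fields=self._identity_fields((3, 3, 3), 5)
        )
        ci = prob.classes.index(2)
        assert prob.probabilities[1, 1, 1, ci] == pytest.approx(0.6)

    def test_probabilities_sum_to_one_for_random_votes(self, rng):
        table = {1: "a", 2: "b", 3: "c"}
        atlases = [
            _toy_atlas(rng.integers(0, 4, (4, 4, 4)), f"a{i}", table) for i in range(5)
        ]
        prob, _ = build_probabilistic_atlas(
            atlases[0].intensity, atlases, fields=self._identity_fields((4, 4, 4), 5)
        )
        np.testing.assert_allclose(prob.probabilities.sum(axis=-1), 1.0, atol=1e-12)

    def test_improper_distribution_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProbabilisticAtlas((0, 1), np.full((2, 2, 2, 2), 0.4), (1, 1, 1))


class TestEMClassify:
    def test_zero_prior_class_never_assigned(self, rng):
        img = Volume(rng.normal(5.0, 1.0, (6, 6, 6)), (1, 1, 1))
        p = np.zeros((6, 6, 6, 2))
        p[..., 0] = 1.0  # class 1 has zero prior mass at every voxel
        with pytest.warns(UserWarning, match="zero prior"):
            lab, _m, _a = em_classify(img, ProbabilisticAtlas((0, 1), p, (1, 1, 1)))
        assert not (lab.labels == 1).any()

    def test_separable_mixture_recovered(self, rng):
        truth = rng.integers(0, 2, (10, 10, 10))
        img = Volume(np.where(truth == 1, 10.0, -10.0) + rng.normal(0, 1.0, truth.shape), (1, 1, 1))
        prior = ProbabilisticAtlas((0, 1), np.full((10, 10, 10, 2), 0.5), (1, 1, 1))
        init = TissueModel((0, 1), np.array([-5.0, 5.0]), np.array([4.0, 4.0]))
        lab, model, audit = em_classify(img, prior, init=init)
        np.testing.assert_array_equal(lab.labels, (img.data > 0).astype(int))
        assert model.means[0] == pytest.approx(-10.0, abs=0.1)
        assert model.means[1] == pytest.approx(10.0, abs=0.1)
        # log-likelihood monotone non-decreasing
        ll = np.array(audit.em_log_likelihoods)
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()

    def test_single_class_degenerates_to_image_mean(self, rng):
        img = Volume(rng.normal(3.0, 1.0, (5, 5, 5)), (1, 1, 1))
        prior = ProbabilisticAtlas((7,), np.ones((5, 5, 5, 1)), (1, 1, 1))
        lab, model, _a = em_classify(img, prior)
        assert (lab.labels == 7).all()
        assert model.means[0] == pytest.approx(img.data.mean())


class TestStructureVolume:
    def test_arithmetic_in_ml(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels.ravel()[:1000] = 4
        lab = LabelVolume(labels, (1.2, 1.2, 1.2), table={4: "hippo"})
        assert structure_volume(lab, 4) == pytest.approx(1000 * 1.728 / 1000.0)

    def test_empty_structure_is_zero(self):
        lab = LabelVolume(np.zeros((4, 4, 4), np.int32), (1, 1, 1), table={4: "x"})
        assert structure_volume(lab, 4) == 0.0

    def test_left_right_additivity(self, rng):
        labels = rng.integers(0, 3, (8, 8, 8)).astype(np.int32)
        lab = LabelVolume(labels, (2, 2, 2), table={1: "left", 2: "right"})
        total = structure_volume(lab, [1, 2])
        assert total == pytest.approx(structure_volume(lab, 1) + structure_volume(lab, 2))


@pytest.fixture(scope="module")
def atlas_setup(phantom):
    from ftdmorph.pipeline import make_atlas_library

    template, library = make_atlas_library(phantom, n_atlases=6, seed=42)
    cfg = MultiAtlasConfig()
    cached = register_library_to_template(library, template, cfg)
    return phantom, template, library, cfg, cached


class TestMultiAtlasPipeline:
    def test_fixed_point_reproduces_template_hippocampus(self, atlas_setup):
        phantom, template, library, cfg, cached = atlas_setup
        lab, audit = segment_multiatlas(
            phantom.intensity, library, template, cfg, template_space_atlases=cached
        )
        truth = syn.collapse_to_segmentation_labels(phantom.labels)
        np.testing.assert_array_equal(lab.labels == 10, truth.labels == 10)
        np.testing.assert_array_equal(lab.labels == 11, truth.labels == 11)
        assert len(audit.selected_atlases) == 5
        assert audit.selected_atlases[0] == "template"

    def test_synthetic_subject_dice(self, atlas_setup, rng):
        phantom, template, library, cfg, cached = atlas_setup
        img, slab, _truth = syn.synthesize_subject(
            phantom, {"hippocampus_amygdala": 0.85}, 1.02, rng=rng
        )
        lab, _audit = segment_multiatlas(
            img, library, template, cfg, template_space_atlases=cached
        )
        a = np.isin(lab.labels, [10, 11])
        b = np.isin(slab.labels, [10, 11])
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.85

    def test_noisier_subject_does_not_improve_dice(self, atlas_setup):
        phantom, template, library, cfg, cached = atlas_setup

        def dice_at_noise(noise_sd, seed):
            img, slab, _t = syn.synthesize_subject(
                phantom, {"hippocampus_amygdala": 0.85}, 1.0,
                noise_sd=noise_sd, rng=np.random.default_rng(seed),
            )
            lab, _ = segment_multiatlas(
                img, library, template, cfg, template_space_atlases=cached
            )
            a = np.isin(lab.labels, [10, 11])
            b = np.isin(slab.labels, [10, 11])
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        assert dice_at_noise(40.0, 7) <= dice_at_noise(4.0, 7) + 1e-9

    def test_selection_mask_covers_hippocampus(self, phantom):
        mask = hippocampus_area_mask(phantom.labels, (10, 11), 3)
        hippo = np.isin(phantom.labels.labels, [10, 11])
        assert (mask.data.astype(bool) & hippo).sum() == hippo.sum()
        assert mask.data.sum() > hippo.sum()

    def test_empty_library_aborts_with_stage_name(self, phantom):
        with pytest.raises(RuntimeError, match="atlas_library"):
            segment_multiatlas(phantom.intensity, [], None)
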