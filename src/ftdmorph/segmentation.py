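"""Multi-atlas segmentation with EM tissue classification, and volumetry.

Pipeline (per patient image):

1. register all atlases and the patient to a designated template image;
2. select the k atlases with the highest normalized mutual information with
   the patient over the hippocampus area, computed in template space;
3. register the patient to each selected atlas (patient grid fixed);
4. propagate each atlas's class labels to the patient grid and fuse the
   votes into a per-class probabilistic atlas;
5. refine with expectation-maximization tissue classification (per-class
   intensity Gaussians, the probabilistic atlas as a fixed spatial prior).

Volumes are voxel counts times the voxel volume, reported in ml.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imgio import LabelVolume, Volume
from .registration import (
    DeformationField,
    RegistrationConfig,
    apply_deformation,
    nmi,
    register_nonrigid,
)


@dataclass
class Atlas:
    """Paired intensity image and label map in the same space."""

    intensity: Volume
    labels: LabelVolume
    name: str = ""

    def __post_init__(self) -> None:
        if self.intensity.geometry != self.labels.geometry:
            raise ValueError(f"atlas {self.name!r}: intensity and labels disagree in geometry")


@dataclass
class ProbabilisticAtlas:
    """Per-class probability volumes on the patient grid."""

    classes: tuple[int, ...]
    probabilities: np.ndarray  # shape grid + (n_classes,)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 4 or p.shape[3] != len(self.classes):
            raise ValueError("probabilities must have shape grid + (n_classes,)")
        if p.min() < -1e-9:
            raise ValueError("negative class probability")
        s = p.sum(axis=-1)
        if np.abs(s - 1.0).max() > 1e-6:
            raise ValueError("per-voxel class probabilities must sum to 1")
        self.probabilities = p


@dataclass
class TissueModel:
    """Per-class Gaussian intensity model."""

    classes: tuple[int, ...]
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances <= 0):
            raise ValueError("class variances must be > 0")


@dataclass
class MultiAtlasConfig:
    k_select: int = 5  # number of atlases fused
    hippocampus_labels: tuple[int, ...] = (10, 11)
    selection_dilation_vox: int = 3  # "hippocampus area" = dilated template hippocampus
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    em_max_iter: int = 100
    em_tol: float = 1e-6


@dataclass
class SegmentationAudit:
    """Intermediate artifacts emitted for audit."""

    selected_atlases: list[str] = field(default_factory=list)
    nmi_scores: dict[str, float] = field(default_factory=dict)
    probabilistic_atlas: ProbabilisticAtlas | None = None
    em_iterations: int = 0
    em_log_likelihoods: list[float] = field(default_factory=list)
    posteriors: np.ndarray | None = None  # grid + (n_classes,), EM responsibilities


# ---------------------------------------------------------------------------


def hippocampus_area_mask(template_labels: LabelVolume, hippo_labels: Sequence[int],
                          dilation_vox: int = 3) -> Volume:
    """Selection mask: template hippocampus labels dilated by a voxel radius."""
    core = np.isin(template_labels.labels, list(hippo_labels))
    if dilation_vox > 0:
        core = ndimage.binary_dilation(core, iterations=dilation_vox)
    return Volume(core.astype(np.uint8), template_labels.spacing, template_labels.origin)


def select_atlases(
    patient: Volume,
    atlases: Sequence[Atlas],
    region_mask: Volume,
    k: int = 5,
) -> list[Atlas]:
    """The k atlases with the highest NMI to the patient within the mask.

    All inputs must already live in the common (template) space.  Ties break
    toward the earlier atlas in the input order; the result is deterministic.
    """
    if k > len(atlases):
        raise ValueError(f"cannot select {k} atlases from a library of {len(atlases)}")
    mask = np.asarray(region_mask.data).astype(bool)
    if not mask.any():
        raise ValueError("empty atlas-selection mask")
    scores = [
        nmi(patient.data, atlas.intensity.data, mask=mask) for atlas in atlases
    ]
    order = sorted(range(len(atlases)), key=lambda i: (-scores[i], i))
    return [atlases[i] for i in order[:k]]


def build_probabilistic_atlas(
    patient: Volume,
    selected: Sequence[Atlas],
    cfg: MultiAtlasConfig | None = None,
    fields: Sequence[DeformationField] | None = None,
) -> tuple[ProbabilisticAtlas, list[LabelVolume]]:
    """Register the patient to each selected atlas (unless precomputed
    ``fields`` are given, one per atlas, patient grid fixed), propagate the
    atlas labels onto the patient grid, and fuse the votes into per-class
    probabilities."""
    cfg = cfg or MultiAtlasConfig()
    if not selected:
        raise ValueError("need at least one atlas")
    propagated: list[LabelVolume] = []
    for i, atlas in enumerate(selected):
        if fields is not None:
            fld = fields[i]
        else:
            fld = register_nonrigid(patient, atlas.intensity, cfg.registration)
        propagated.append(apply_deformation(atlas.labels, fld, mode="nearest"))
    classes = sorted(
        set().union(*(set(np.unique(p.labels).tolist()) for p in propagated))
    )
    allowed = set().union(*(set(a.labels.table) | {0} for a in selected))
    stray = set(classes) - allowed
    if stray:
        raise ValueError(f"propagated label(s) {sorted(stray)} outside the atlas class set")
    votes = np.zeros(patient.geometry.shape + (len(classes),))
    for p in propagated:
        for ci, c in enumerate(classes):
            votes[..., ci] += p.labels == c
    votes /= len(propagated)
    atlas_prob = ProbabilisticAtlas(
        tuple(int(c) for c in classes), votes, patient.spacing, patient.origin
    )
    return atlas_prob, propagated


def init_tissue_model(patient: Volume, prior: ProbabilisticAtlas) -> TissueModel:
    """Prior-weighted image statistics as the EM starting point."""
    I = np.asarray(patient.data, dtype=float)
    means, variances = [], []
    floor = max(1e-8, 1e-6 * float(I.var()))
    for ci in range(len(prior.classes)):
        w = prior.probabilities[..., ci]
        wsum = w.sum()
        if wsum == 0:
            means.append(float(I.mean()))
            variances.append(float(I.var()) + floor)
            continue
        mu = float((w * I).sum() / wsum)
        var = float((w * (I - mu) ** 2).sum() / wsum)
        means.append(mu)
        variances.append(max(var, floor))
    return TissueModel(prior.classes, np.array(means), np.array(variances))


def em_classify(
    patient: Volume,
    prior: ProbabilisticAtlas,
    init: TissueModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    label_table: dict[int, str] | None = None,
) -> tuple[LabelVolume, TissueModel, SegmentationAudit]:
    """EM tissue classification with the probabilistic atlas as spatial prior.

    Posterior(c | x) ∝ prior(x, c) · N(I(x); mu_c, sigma_c^2); hard labels
    are the argmax posterior.  The data log-likelihood is non-decreasing
    across iterations; stops at relative change < ``tol`` or ``max_iter``.
    Classes with zero prior mass everywhere are dropped with a warning.
    """
    I = np.asarray(patient.data, dtype=float)
    keep = [ci for ci in range(len(prior.classes)) if prior.probabilities[..., ci].sum() > 0]
    if len(keep) < len(prior.classes):
        dropped = [prior.classes[ci] for ci in range(len(prior.classes)) if ci not in keep]
        warnings.warn(f"dropping class(es) {dropped} with zero prior mass", stacklevel=2)
    classes = tuple(prior.classes[ci] for ci in keep)
    pri = prior.probabilities[..., keep]
    pri = pri / pri.sum(axis=-1, keepdims=True)
    model = init
    if model is None or tuple(model.classes) != classes:
        model = init_tissue_model(
            patient,
            ProbabilisticAtlas(classes, pri, prior.spacing, prior.origin),
        )
    means = model.means.copy()
    variances = model.variances.copy()
    floor = max(1e-8, 1e-6 * float(I.var()))

    audit = SegmentationAudit()
    prev_ll = -np.inf
    gamma = None
    for it in range(max_iter):
        # E-step
        log_lik = -0.5 * (
            np.log(2 * np.pi * variances)
            + (I[..., None] - means) ** 2 / variances
        )
        log_post = np.log(np.maximum(pri, 1e-300)) + log_lik
        m = log_post.max(axis=-1, keepdims=True)
        p = np.exp(log_post - m)
        norm = p.sum(axis=-1, keepdims=True)
        gamma = p / norm
        ll = float((m[..., 0] + np.log(norm[..., 0])).sum())
        audit.em_log_likelihoods.append(ll)
        if prev_ll != -np.inf and ll - prev_ll < tol * abs(prev_ll):
            break
        prev_ll = ll
        # M-step
        wsum = gamma.reshape(-1, len(classes)).sum(axis=0)
        means = (gamma * I[..., None]).reshape(-1, len(classes)).sum(axis=0) / np.maximum(wsum, 1e-12)
        variances = (gamma * (I[..., None] - means) ** 2).reshape(-1, len(classes)).sum(axis=0)
        variances = np.maximum(variances / np.maximum(wsum, 1e-12), floor)
    audit.em_iterations = len(audit.em_log_likelihoods)
    audit.posteriors = gamma

    hard = np.argmax(gamma, axis=-1)
    labels = np.asarray(classes, dtype=np.int32)[hard]
    table = dict(label_table or {})
    for c in classes:
        if c != 0:
            table.setdefault(int(c), f"class_{int(c)}")
    lab = LabelVolume(labels, patient.spacing, patient.origin, table)
    return lab, TissueModel(classes, means, variances), audit


def segment_multiatlas(
    patient: Volume,
    atlas_library: Sequence[Atlas],
    template: Atlas,
    cfg: MultiAtlasConfig | None = None,
    template_space_atlases: Sequence[Atlas] | None = None,
) -> tuple[LabelVolume, SegmentationAudit]:
    """Run the five-step multi-atlas pipeline end to end.

    ``template_space_atlases`` may carry the step-1 atlas-to-template
    registrations precomputed once per library (they do not depend on the
    patient); otherwise they are computed here.
    """
    cfg = cfg or MultiAtlasConfig()
    if not atlas_library:
        raise RuntimeError("stage atlas_library: empty library")

    try:
        # Step 1: everything to template space
        if template_space_atlases is None:
            template_space_atlases = register_library_to_template(
                atlas_library, template, cfg
            )
        fld_p = register_nonrigid(template.intensity, patient, cfg.registration)
        patient_in_template = apply_deformation(patient, fld_p, mode="linear")
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage template_alignment: {e}") from e

    try:
        # Step 2: NMI atlas selection in the hippocampus area
        mask = hippocampus_area_mask(
            template.labels, cfg.hippocampus_labels, cfg.selection_dilation_vox
        )
        scores = {
            a.name: nmi(patient_in_template.data, a.intensity.data,
                        mask=np.asarray(mask.data).astype(bool))
            for a in template_space_atlases
        }
        order = sorted(
            range(len(template_space_atlases)),
            key=lambda i: (-scores[template_space_atlases[i].name], i),
        )
        chosen = [atlas_library[i] for i in order[: cfg.k_select]]
    except Exception as e:
        raise RuntimeError(f"stage atlas_selection: {e}") from e

    try:
        # Steps 3-4: patient-to-atlas registrations, label propagation, fusion
        atlas_prob, _ = build_probabilistic_atlas(patient, chosen, cfg)
    except Exception as e:
        raise RuntimeError(f"stage probabilistic_atlas: {e}") from e

    try:
        # Step 5: EM refinement
        table = dict(chosen[0].labels.table)
        lab, _model, audit = em_classify(
            patient, atlas_prob, max_iter=cfg.em_max_iter, tol=cfg.em_tol,
            label_table=table,
        )
    except Exception as e:
        raise RuntimeError(f"stage em_classification: {e}") from e

    audit.selected_atlases = [a.name for a in chosen]
    audit.nmi_scores = {k: float(v) for k, v in scores.items()}
    audit.probabilistic_atlas = atlas_prob
    return lab, audit


def register_library_to_template(
    atlas_library: Sequence[Atlas], template: Atlas, cfg: MultiAtlasConfig | None = None
) -> list[Atlas]:
    """Step-1 helper: resample every atlas into template space (cacheable)."""
    cfg = cfg or MultiAtlasConfig()
    out = []
    for atlas in atlas_library:
        if np.shares_memory(atlas.intensity.data, template.intensity.data) or (
            atlas.intensity.geometry == template.intensity.geometry
            and np.array_equal(atlas.intensity.data, template.intensity.data)
        ):
            out.append(Atlas(atlas.intensity, atlas.labels, atlas.name))
            continue
        fld = register_nonrigid(template.intensity, atlas.intensity, cfg.registration)
        out.append(
            Atlas(
                apply_deformation(atlas.intensity, fld, mode="linear"),
                apply_deformation(atlas.labels, fld, mode="nearest"),
                atlas.name,
            )
        )
    return out


def structure_volume(
    labels: LabelVolume, structure_ids: Sequence[int] | int
) -> float:
    """Volume of the given label id(s): voxel count × voxel volume, in ml."""
    if np.isscalar(structure_ids):
        structure_ids = [int(structure_ids)]
    count = int(np.isin(labels.labels, list(structure_ids)).sum())
    return count * labels.geometry.voxel_volume_mm3 / 1000.0
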