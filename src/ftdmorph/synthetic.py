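"""Synthetic phantom anatomy and cohort generation.

A desk-scale stand-in for a T1-weighted dementia cohort: a spherical-head
template with grey matter, white matter, a CSF shell and ten named
sub-structures covering the seven classification ROIs (hippocampus and
amygdala left/right, posterior temporal lobe, lateral ventricle, temporal
horn, parahippocampal region, anterior cingulate, superior frontal gyrus).

Group-specific atrophy is realized as smooth radial warps, one per
structure: inside a core sphere the anatomy is scaled uniformly by
``s = f**(1/3)`` (volume factor ``f``; ``f > 1`` models ventricular
expansion), blending C2-smoothly to the identity over a finite shell.  The
warp is analytic and invertible with a closed-form Jacobian determinant, so
every tensor-based-morphometry stage has an exact oracle.  A per-subject
global scale ties regional volumes to intracranial volume, and a linear age
slope on the atrophy factors gives the covariate correction something real
to remove.

Everything is reproducible from (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .imgio import Geometry, LabelVolume, ROIDefinition, SubjectRecord, Volume
from .registration import DeformationField

# ---------------------------------------------------------------------------
# Label scheme and ROI table

LABELS = {
    1: "csf",
    2: "gm",
    3: "wm",
    10: "hippocampus_left",
    11: "hippocampus_right",
    12: "amygdala_left",
    13: "amygdala_right",
    14: "posterior_temporal",
    15: "ventricle_lateral",
    16: "ventricle_temporal_horn",
    17: "parahippocampal",
    18: "anterior_cingulate",
    19: "superior_frontal",
}

#: The seven composite classification ROIs.
ROI_DEFINITIONS: tuple[ROIDefinition, ...] = (
    ROIDefinition("hippocampus_amygdala", frozenset({10, 11, 12, 13})),
    ROIDefinition("posterior_temporal", frozenset({14})),
    ROIDefinition("ventricle_lateral", frozenset({15})),
    ROIDefinition("ventricle_temporal_horn", frozenset({16})),
    ROIDefinition("parahippocampal", frozenset({17})),
    ROIDefinition("anterior_cingulate", frozenset({18})),
    ROIDefinition("superior_frontal", frozenset({19})),
)
ROI_NAMES = tuple(r.name for r in ROI_DEFINITIONS)

HIPPO_LEFT = ROIDefinition("hippocampus_left", frozenset({10}), "left")
HIPPO_RIGHT = ROIDefinition("hippocampus_right", frozenset({11}), "right")

#: structure label -> ROI name whose atrophy factor drives its warp
STRUCTURE_ROI = {
    10: "hippocampus_amygdala",
    11: "hippocampus_amygdala",
    12: "hippocampus_amygdala",
    13: "hippocampus_amygdala",
    14: "posterior_temporal",
    15: "ventricle_lateral",
    16: "ventricle_temporal_horn",
    17: "parahippocampal",
    18: "anterior_cingulate",
    19: "superior_frontal",
}

TISSUE_CSF = frozenset({1, 15, 16})
TISSUE_GM = frozenset({2, 10, 11, 12, 13, 14, 17, 18, 19})
TISSUE_WM = frozenset({3})

SEGMENTATION_LABELS = {0: "background", 1: "csf", 2: "gm", 3: "wm",
                       10: "hippocampus_left", 11: "hippocampus_right"}


def collapse_to_segmentation_labels(lab: LabelVolume) -> LabelVolume:
    """Collapse the full structure scheme to the multi-atlas class set
    (background / CSF / GM / WM / hippocampus L/R)."""
    out = np.zeros_like(lab.labels)
    for lid in np.unique(lab.labels):
        lid = int(lid)
        if lid == 0:
            continue
        if lid in (10, 11):
            out[lab.labels == lid] = lid
        elif lid in TISSUE_CSF:
            out[lab.labels == lid] = 1
        elif lid in TISSUE_WM:
            out[lab.labels == lid] = 3
        else:
            out[lab.labels == lid] = 2
    return LabelVolume(out, lab.spacing, lab.origin, dict(SEGMENTATION_LABELS))


# ---------------------------------------------------------------------------
# Template specification

#: (center mm, radius mm, falloff width mm) of each warped structure
_STRUCTURES: dict[int, tuple[tuple[float, float, float], float, float]] = {
    10: ((28.0, 38.0, 36.0), 8.0, 5.6),
    11: ((68.0, 38.0, 36.0), 8.0, 5.6),
    12: ((28.0, 62.0, 44.0), 5.0, 4.0),
    13: ((68.0, 62.0, 44.0), 5.0, 4.0),
    14: ((48.0, 20.0, 40.0), 6.0, 4.2),
    15: ((48.0, 50.0, 58.0), 7.0, 4.0),
    16: ((48.0, 78.0, 32.0), 3.0, 4.0),
    17: ((20.0, 64.0, 62.0), 4.0, 4.0),
    18: ((48.0, 74.0, 72.0), 4.5, 4.0),
    19: ((48.0, 36.0, 76.0), 5.5, 4.0),
}

_CORE_MARGIN_MM = 0.5  # uniform-scale zone extends this far beyond the structure

DEFAULT_INTENSITY = {
    0: 0.0, 1: 30.0, 2: 100.0, 3: 140.0,
    10: 85.0, 11: 85.0, 12: 90.0, 13: 90.0,
    14: 105.0, 15: 32.0, 16: 34.0, 17: 95.0, 18: 102.0, 19: 98.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of the phantom head."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radius_mm: float = 40.0
    csf_shell_mm: float = 3.0
    wm_radius_mm: float = 30.0
    intensity_means: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    noise_sd: float = 4.0
    structures: Mapping[int, tuple[tuple[float, float, float], float, float]] = field(
        default_factory=lambda: dict(_STRUCTURES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.grid_shape, self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        # center of the physical domain, independent of grid parity
        g = self.geometry
        return np.array([n * s / 2.0 for n, s in zip(g.shape, g.spacing)])


@dataclass
class Phantom:
    """A built template: intensity + label volumes plus the generating spec."""

    intensity: Volume
    labels: LabelVolume
    spec: PhantomSpec

    @property
    def structure_volumes_ml(self) -> dict[str, float]:
        return structure_volumes_from_labels(self.labels)

    @property
    def icv_ml(self) -> float:
        vox = self.labels.geometry.voxel_volume_mm3
        return float(np.count_nonzero(self.labels.labels) * vox / 1000.0)


def structure_volumes_from_labels(lab: LabelVolume) -> dict[str, float]:
    vox_ml = lab.geometry.voxel_volume_mm3 / 1000.0
    out = {}
    for lid, name in lab.table.items():
        out[name] = float(np.count_nonzero(lab.labels == lid) * vox_ml)
    return out


def _validate_layout(spec: PhantomSpec) -> None:
    """Structures must be disjoint, inside the head, and their warp supports
    pairwise disjoint (so per-site Jacobians compose exactly)."""
    c0 = spec.center_mm
    items = sorted(spec.structures.items())
    extent = np.array(spec.geometry.shape) * np.array(spec.geometry.spacing)
    for lid, (c, r, w) in items:
        c = np.asarray(c)
        if np.linalg.norm(c - c0) + r > spec.brain_radius_mm + spec.csf_shell_mm:
            raise ValueError(f"structure {lid} does not fit inside the head")
        if (c - r < 0).any() or (c + r > extent).any():
            raise ValueError(f"structure {lid} does not fit the grid")
    for i, (lid_a, (ca, ra, wa)) in enumerate(items):
        sup_a = ra + _CORE_MARGIN_MM + wa
        for lid_b, (cb, rb, wb) in items[i + 1 :]:
            d = float(np.linalg.norm(np.asarray(ca) - np.asarray(cb)))
            if d < ra + rb:
                raise ValueError(f"structures {lid_a} and {lid_b} overlap")
            sup_b = rb + _CORE_MARGIN_MM + wb
            if d < sup_a + sup_b:
                raise ValueError(
                    f"warp supports of structures {lid_a} and {lid_b} overlap "
                    f"(distance {d:.1f} mm < {sup_a + sup_b:.1f} mm)"
                )


def _labels_at_points(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Analytic anatomy lookup: the label of each world point (..., 3).

    Used both to rasterize the template and to rasterize warped subjects at
    the pre-image of each voxel center, so subject label maps are exactly
    consistent with the generating warp."""
    c0 = spec.center_mm
    r_head = np.linalg.norm(points - c0, axis=-1)
    labels = np.zeros(points.shape[:-1], dtype=np.int32)
    labels[r_head <= spec.brain_radius_mm + spec.csf_shell_mm] = 1
    labels[r_head <= spec.brain_radius_mm] = 2
    labels[r_head <= spec.wm_radius_mm] = 3
    for lid, (c, radius, _w) in sorted(spec.structures.items()):
        d = np.linalg.norm(points - np.asarray(c), axis=-1)
        labels[d <= radius] = lid
    return labels


def make_template(spec: PhantomSpec | None = None) -> Phantom:
    """Build the template anatomy.

    With ``noise_sd == 0`` every structure's voxels take exactly the
    configured mean intensity.
    """
    spec = spec or PhantomSpec()
    _validate_layout(spec)
    geom = spec.geometry
    world = geom.index_grid_world()
    labels = _labels_at_points(spec, world)
    means = dict(spec.intensity_means)
    intensity = np.vectorize(means.__getitem__, otypes=[float])(labels)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, geom.shape)
    lab = LabelVolume(labels, geom.spacing, geom.origin, dict(LABELS))
    return Phantom(Volume(intensity, geom.spacing, geom.origin), lab, spec)


# ---------------------------------------------------------------------------
# Analytic radial warps


def _smoothstep(q: np.ndarray) -> np.ndarray:
    q = np.clip(q, 0.0, 1.0)
    return q * q * q * (q * (q * 6.0 - 15.0) + 10.0)


def _smoothstep_d(q: np.ndarray) -> np.ndarray:
    q = np.clip(q, 0.0, 1.0)
    return 30.0 * q * q * (q - 1.0) * (q - 1.0)


class RadialWarp:
    """Template -> subject radial map around ``center``: uniform linear scale
    ``s`` inside ``r_core``, identity beyond ``r_core + width``, quintic
    blend between.  Closed-form Jacobian; numerically exact inverse via a
    monotone radius table."""

    def __init__(self, center: Sequence[float], s: float, r_core: float, width: float):
        if s <= 0:
            raise ValueError("scale must be > 0")
        self.center = np.asarray(center, dtype=float)
        self.s = float(s)
        self.r_core = float(r_core)
        self.width = float(width)
        self.r_support = self.r_core + self.width
        rr = np.linspace(0.0, self.r_support, 4097)
        rho = rr * self._phi(rr)
        drho = np.diff(rho)
        if drho.min() <= 0:
            raise ValueError(
                f"radial warp with scale {s:.3f} over core {r_core:.1f} mm / "
                f"width {width:.1f} mm is not invertible"
            )
        self._rho_table = rho
        self._r_table = rr

    def _phi(self, r: np.ndarray) -> np.ndarray:
        q = (np.asarray(r, float) - self.r_core) / self.width
        return self.s + (1.0 - self.s) * _smoothstep(q)

    def _dphi(self, r: np.ndarray) -> np.ndarray:
        q = (np.asarray(r, float) - self.r_core) / self.width
        return (1.0 - self.s) * _smoothstep_d(q) / self.width

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """u(x) = T(x) - x for points of shape (..., 3)."""
        d = points - self.center
        r = np.linalg.norm(d, axis=-1)
        return (self._phi(r) - 1.0)[..., None] * d

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """det J of T at points (closed form: (rho/r)^2 * rho')."""
        r = np.linalg.norm(points - self.center, axis=-1)
        phi = self._phi(r)
        drho = phi + r * self._dphi(r)
        return phi * phi * drho

    def inverse(self, points: np.ndarray) -> np.ndarray:
        d = points - self.center
        r = np.linalg.norm(d, axis=-1)
        inside = r < self._rho_table[-1]
        if not inside.any():
            return points.copy()
        out = points.copy()
        r_in = r[inside]
        r_src = np.interp(r_in, self._rho_table, self._r_table)
        ratio = np.where(r_in > 0, r_src / np.maximum(r_in, 1e-12), 1.0)
        out[inside] = self.center + ratio[..., None] * d[inside]
        return out


class SubjectWarp:
    """Composition of disjoint-support radial warps with a global uniform
    scale about the head center (template -> subject)."""

    def __init__(self, sites: Sequence[RadialWarp], global_scale: float = 1.0,
                 center: Sequence[float] = (0.0, 0.0, 0.0)):
        self.sites = list(sites)
        self.g = float(global_scale)
        if self.g <= 0:
            raise ValueError("global scale must be > 0")
        self.center = np.asarray(center, dtype=float)

    def forward(self, points: np.ndarray) -> np.ndarray:
        y = points.astype(float).copy()
        for site in self.sites:
            y = y + site.displacement(points)
        return self.center + self.g * (y - self.center)

    def inverse(self, points: np.ndarray) -> np.ndarray:
        x = self.center + (points - self.center) / self.g
        for site in self.sites:
            x = site.inverse(x)
        return x

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        J = np.full(points.shape[:-1], self.g**3)
        for site in self.sites:
            J = J * site.jacobian(points)
        return J

    def displacement_field(self, geometry: Geometry) -> DeformationField:
        world = geometry.index_grid_world()
        u = self.forward(world) - world
        return DeformationField(u, geometry.spacing, geometry.origin)

    def jacobian_map(self, geometry: Geometry) -> Volume:
        world = geometry.index_grid_world()
        return Volume(self.jacobian(world), geometry.spacing, geometry.origin)


# ---------------------------------------------------------------------------
# Cohorts

#: per-group hippocampus+amygdala volume factors follow the study groups'
#: hippocampal volume ratios relative to controls; other ROIs are free,
#: documented defaults (frontal + ventricular emphasis in FTD, medial
#: temporal + ventricular emphasis in AD).
DEFAULT_ATROPHY: dict[str, dict[str, float]] = {
    "C": {},
    "FTD": {
        "hippocampus_amygdala": 0.87,
        "superior_frontal": 0.82,
        "anterior_cingulate": 0.90,
        "ventricle_lateral": 1.18,
        "ventricle_temporal_horn": 1.12,
        "posterior_temporal": 0.95,
        "parahippocampal": 0.93,
    },
    "AD": {
        "hippocampus_amygdala": 0.79,
        "parahippocampal": 0.88,
        "posterior_temporal": 0.90,
        "ventricle_lateral": 1.20,
        "ventricle_temporal_horn": 1.20,
        "anterior_cingulate": 0.96,
        "superior_frontal": 0.97,
    },
    "SMCI": {"hippocampus_amygdala": 0.96, "ventricle_lateral": 1.04},
    "PMCI": {
        "hippocampus_amygdala": 0.86,
        "parahippocampal": 0.94,
        "ventricle_lateral": 1.10,
        "ventricle_temporal_horn": 1.10,
    },
}

#: Table-1 group layout: sizes, age mean/sd, male fraction
DEFAULT_DEMOGRAPHICS = {
    "C": (26, 74.0, 4.0, 12 / 26),
    "FTD": (37, 66.0, 9.0, 20 / 37),
    "AD": (46, 74.0, 6.0, 14 / 46),
    "SMCI": (48, 73.0, 5.0, 18 / 48),
    "PMCI": (16, 72.0, 6.0, 7 / 16),
}


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes, atrophy model and covariate model of a simulated cohort."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: DEFAULT_DEMOGRAPHICS[g][0] for g in DEFAULT_DEMOGRAPHICS}
    )
    atrophy: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_ATROPHY.items()}
    )
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {g: (DEFAULT_DEMOGRAPHICS[g][1], DEFAULT_DEMOGRAPHICS[g][2])
                                 for g in DEFAULT_DEMOGRAPHICS}
    )
    male_fraction: Mapping[str, float] = field(
        default_factory=lambda: {g: DEFAULT_DEMOGRAPHICS[g][3] for g in DEFAULT_DEMOGRAPHICS}
    )
    icv_rel_sd: float = 0.05  # SD of ICV around its sex mean, relative
    icv_sex_gap: float = 0.06  # male/female relative ICV offset (+/- half)
    age_slope: float = 0.003  # extra fractional volume loss per year above age_ref
    age_ref: float = 72.0
    noise_sd: float | None = None  # None -> PhantomSpec.noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in DEFAULT_DEMOGRAPHICS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("n per group must be >= 0")
        for g, rois in self.atrophy.items():
            for roi, f in rois.items():
                if roi not in ROI_NAMES:
                    raise ValueError(f"unknown ROI {roi!r} in atrophy spec")
                if not f > 0:
                    raise ValueError("atrophy factors must be > 0")


@dataclass
class GroundTruth:
    """Per-subject oracle: the generating warp and the true volumes.

    ``structure_volumes_ml`` are exact continuous volumes (sphere volume ×
    atrophy factor × global scale); ``counted_volumes_ml`` are voxel counts
    × voxel volume from the rasterized subject labels.  The two agree to
    within one voxel-shell of the structure surface.
    """

    warp: SubjectWarp
    structure_volumes_ml: dict[str, float]
    counted_volumes_ml: dict[str, float]
    roi_factors: dict[str, float]
    icv_factor: float


@dataclass
class CohortSubject:
    record: SubjectRecord
    image: Volume
    labels: LabelVolume  # subject-space true labels
    truth: GroundTruth


@dataclass
class Cohort:
    phantom: Phantom
    spec: CohortSpec
    subjects: list[CohortSubject]

    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]

    def by_group(self, group: str) -> list[CohortSubject]:
        return [s for s in self.subjects if s.record.group == group]


def _subject_warp(
    phantom: Phantom, roi_factors: Mapping[str, float], icv_factor: float
) -> SubjectWarp:
    sites = []
    for lid, (c, radius, width) in sorted(phantom.spec.structures.items()):
        f = float(roi_factors.get(STRUCTURE_ROI[lid], 1.0))
        if abs(f - 1.0) < 1e-12:
            continue
        sites.append(RadialWarp(c, f ** (1.0 / 3.0), radius + _CORE_MARGIN_MM, width))
    return SubjectWarp(sites, global_scale=icv_factor ** (1.0 / 3.0),
                       center=phantom.spec.center_mm)


def synthesize_subject(
    phantom: Phantom,
    roi_factors: Mapping[str, float],
    icv_factor: float = 1.0,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, LabelVolume, GroundTruth]:
    """Warp the template by the prescribed per-ROI volume factors and global
    scale, then apply the intensity model plus noise."""
    rng = rng or np.random.default_rng(0)
    noise_sd = phantom.spec.noise_sd if noise_sd is None else noise_sd
    warp = _subject_warp(phantom, roi_factors, icv_factor)
    geom = phantom.labels.geometry
    world = geom.index_grid_world().reshape(-1, 3)
    src = warp.inverse(world)
    labels = _labels_at_points(phantom.spec, src).reshape(geom.shape)
    means = dict(phantom.spec.intensity_means)
    image = np.vectorize(means.__getitem__, otypes=[float])(labels)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, geom.shape)
    lab = LabelVolume(labels, geom.spacing, geom.origin, dict(LABELS))
    g3 = float(icv_factor)
    exact = {
        LABELS[lid]: (4.0 / 3.0) * np.pi * radius**3
        * float(roi_factors.get(STRUCTURE_ROI[lid], 1.0)) * g3 / 1000.0
        for lid, (_c, radius, _w) in phantom.spec.structures.items()
    }
    truth = GroundTruth(
        warp=warp,
        structure_volumes_ml=exact,
        counted_volumes_ml=structure_volumes_from_labels(lab),
        roi_factors=dict(roi_factors),
        icv_factor=float(icv_factor),
    )
    return Volume(image, geom.spacing, geom.origin), lab, truth


def make_cohort(phantom: Phantom, spec: CohortSpec | None = None) -> Cohort:
    """Simulate a full cohort with Table-1-style group layout."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    noise_sd = phantom.spec.noise_sd if spec.noise_sd is None else spec.noise_sd
    template_icv = phantom.icv_ml
    subjects: list[CohortSubject] = []
    for group in sorted(spec.n_per_group):
        n = spec.n_per_group[group]
        mean_age, sd_age = spec.age_mean_sd[group]
        p_male = spec.male_fraction[group]
        base = dict(spec.atrophy.get(group, {}))
        for i in range(n):
            age = float(np.clip(rng.normal(mean_age, sd_age), 41.0, 95.0))
            sex = "male" if rng.random() < p_male else "female"
            sex_off = spec.icv_sex_gap / 2.0 * (1 if sex == "male" else -1)
            icv_factor = float(
                np.clip(rng.normal(1.0 + sex_off, spec.icv_rel_sd), 0.8, 1.2)
            )
            age_scale = max(0.2, 1.0 - spec.age_slope * (age - spec.age_ref))
            factors = {roi: f * age_scale for roi, f in base.items()}
            for roi in ROI_NAMES:
                factors.setdefault(roi, age_scale)
            image, labels, truth = synthesize_subject(
                phantom, factors, icv_factor, noise_sd, rng
            )
            record = SubjectRecord(
                id=f"{group}{i:03d}",
                group=group,
                age=round(age, 1),
                sex=sex,
                icv=round(template_icv * icv_factor, 2),
            )
            subjects.append(CohortSubject(record, image, labels, truth))
    return Cohort(phantom, spec, subjects)


# ---------------------------------------------------------------------------
# Deformation-field sets (registration bypass for TBM)


def _smooth_noise_field(
    geometry: Geometry, rms_mm: float, rng: np.random.Generator, corr_mm: float = 6.0
) -> np.ndarray:
    from scipy import ndimage

    sigma_vox = [corr_mm / s for s in geometry.spacing]
    u = rng.standard_normal(geometry.shape + (3,))
    for k in range(3):
        u[..., k] = ndimage.gaussian_filter(u[..., k], sigma_vox)
    rms = np.sqrt((u**2).sum(axis=-1).mean())
    return u * (rms_mm / max(rms, 1e-12))


def make_field_set(
    phantom: Phantom,
    truths: Sequence[GroundTruth],
    perturb_rms_mm: float = 0.0,
    seed: int = 0,
) -> list[DeformationField]:
    """True template->subject displacement fields, optionally perturbed with
    smooth noise of the configured RMS amplitude (mm) to emulate
    registration error."""
    rng = np.random.default_rng(seed)
    geom = phantom.labels.geometry
    out = []
    for truth in truths:
        fld = truth.warp.displacement_field(geom)
        if perturb_rms_mm > 0:
            fld = DeformationField(
                fld.displacement + _smooth_noise_field(geom, perturb_rms_mm, rng),
                geom.spacing,
                geom.origin,
            )
        out.append(fld)
    return out


# ---------------------------------------------------------------------------
# Pure feature-table cohorts (direct classification harness)


def make_feature_cohort(
    n_per_group: int | tuple[int, int],
    effect_size: float | Sequence[float],
    n_features: int = 1,
    seed: int = 0,
    groups: tuple[str, str] = ("C", "AD"),
):
    """Two-group Gaussian feature cohort: unit-variance features whose group
    means differ by ``effect_size`` (scalar applies to the first feature,
    sequence gives per-feature separations; 0 -> pure noise feature)."""
    from .features import FeatureTable

    if isinstance(n_per_group, int):
        n_a = n_b = n_per_group
    else:
        n_a, n_b = n_per_group
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    d = np.zeros(n_features)
    if np.isscalar(effect_size):
        d[0] = float(effect_size)
    else:
        es = np.asarray(effect_size, dtype=float)
        d[: len(es)] = es
    if not np.all(np.isfinite(d)):
        raise ValueError("effect sizes must be finite")

    rng = np.random.default_rng(seed)
    import pandas as pd

    rows = []
    for gi, (group, n) in enumerate(zip(groups, (n_a, n_b))):
        X = rng.standard_normal((n, n_features))
        if gi == 1:
            X = X - d  # disease group shifted downward (atrophy-like)
        for i in range(n):
            row = {
                "id": f"{group}{i:03d}",
                "group": group,
                "age": float(np.clip(rng.normal(72, 5), 45, 95)),
                "sex": "male" if rng.random() < 0.5 else "female",
                "icv": float(rng.normal(1400, 100)),
            }
            row.update({f"feat{j}": X[i, j] for j in range(n_features)})
            rows.append(row)
    df = pd.DataFrame(rows)
    return FeatureTable(df, [f"feat{j}" for j in range(n_features)])


DEFAULT_COVARIATE_COEFFS = {
    # feature -> (intercept, per-year age, male offset, per-ml icv, noise sd)
    "HV_total": (2.5, -0.020, 0.10, 0.0060, 0.25),
    "TBM_hippocampus_amygdala": (0.1, -0.004, 0.01, 0.0004, 0.05),
    "VBM_hippocampus_amygdala": (0.6, -0.002, 0.00, 0.0002, 0.04),
}


def make_covariate_reference(
    n: int = 115,
    seed: int = 0,
    coeffs: Mapping[str, tuple[float, float, float, float, float]] | None = None,
):
    """Healthy reference cohort with known linear covariate structure, for
    covariate-model recovery and standardization tests."""
    from .features import FeatureTable
    import pandas as pd

    coeffs = dict(coeffs or DEFAULT_COVARIATE_COEFFS)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        age = float(np.clip(rng.normal(72, 6), 50, 92))
        sex = "male" if rng.random() < 0.5 else "female"
        icv = float(rng.normal(1500 if sex == "male" else 1350, 110))
        row = {"id": f"REF{i:03d}", "group": "C", "age": age, "sex": sex, "icv": icv}
        for name, (b0, b_age, b_sex, b_icv, sd) in coeffs.items():
            row[name] = (
                b0 + b_age * age + b_sex * (sex == "male") + b_icv * icv
                + rng.normal(0, sd)
            )
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows), list(coeffs))
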