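"""TBM and VBM voxelwise maps and the shared weighted ROI feature.

Tensor-based morphometry: for each subject the Jacobian determinants of the
registrations to T templates are averaged in logarithmic space voxel by
voxel (log makes the distribution more Gaussian and turns the geometric
mean into an arithmetic one).

Voxel-based morphometry: the subject grey-matter probability map is
propagated to template space, smoothed with a Gaussian kernel
(sigma = FWHM / (2 sqrt(2 ln 2)) per axis, spacing-aware), and optionally
modulated by the Jacobian so values measure absolute grey-matter volume
instead of concentration.

Both feature families reduce to the same ROI statistic: a voxelwise
group-level t-map on a held-out reference cohort defines signed weights
w(x) = sign(t)·(1 − p) where p < threshold (zero elsewhere); the feature is
the weight-averaged difference between the atrophic and the expanding
partition of the ROI.  The t-test is control minus disease, so t > 0 marks
disease atrophy for volume-like maps — that direction convention is fixed
here, in one place (``ATROPHIC_T_SIGN``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .imgio import Volume
from .registration import DeformationField, apply_deformation, jacobian_determinant

#: sign of t (control minus disease) that marks disease-atrophic voxels
ATROPHIC_T_SIGN = +1

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MeanLogJacobianMap:
    """Voxelwise (1/T)·Σ_t log J_t(x) over the template set."""

    values: Volume
    n_templates: int

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("need at least one template")


@dataclass
class WeightImage:
    """Group t/p maps and the derived signed weights on the common grid."""

    t_map: Volume
    p_map: Volume
    w_map: Volume
    p_threshold: float
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        w = self.w_map.data
        if np.abs(w).max() > 1.0 + 1e-12:
            raise ValueError("|w| must lie in [0, 1]")


@dataclass
class GMDensityMap:
    """Grey-matter concentration in template space, post-smoothing."""

    values: Volume
    modulated: bool = False

    def __post_init__(self) -> None:
        if self.values.data.min() < -1e-9:
            raise ValueError("grey-matter density must be >= 0")


# ---------------------------------------------------------------------------


def mean_log_jacobian(
    fields: Sequence[DeformationField] | None = None,
    jacobians: Sequence[Volume] | None = None,
) -> MeanLogJacobianMap:
    """Average the log Jacobian determinants of the template registrations.

    Accepts deformation fields (Jacobians computed here) or precomputed
    Jacobian maps; all must share the common template grid.  A non-positive
    Jacobian raises, naming the template and a voxel.
    """
    if jacobians is None:
        if not fields:
            raise ValueError("need at least one deformation field")
        jacobians = [jacobian_determinant(f) for f in fields]
    if not jacobians:
        raise ValueError("need at least one Jacobian map")
    geom = jacobians[0].geometry
    acc = np.zeros(geom.shape)
    for t, jac in enumerate(jacobians):
        if jac.geometry != geom:
            raise ValueError("Jacobian maps must share the template grid")
        data = np.asarray(jac.data)
        if data.min() <= 0:
            vox = tuple(int(i) for i in np.argwhere(data <= 0)[0])
            raise ValueError(
                f"non-positive Jacobian for template {t} at voxel {vox}"
            )
        acc += np.log(data)
    acc /= len(jacobians)
    return MeanLogJacobianMap(Volume(acc, geom.spacing, geom.origin), len(jacobians))


def weight_image(
    maps_group_a: Sequence[Volume],
    maps_group_b: Sequence[Volume],
    p_threshold: float = 0.05,
    mode: str = "one_minus_p",
) -> WeightImage:
    """Voxelwise two-sample equal-variance t-test (group A minus group B; by
    convention A = controls, B = disease) and the derived weights.

    ``one_minus_p``: w = sign(t)·(1 − p) where p < threshold, else 0.
    ``abs_t``: |t| rescaled to (0, 1] on the suprathreshold support, signed.
    Zero-pooled-variance voxels get w = 0 and are counted.
    """
    if len(maps_group_a) < 2 or len(maps_group_b) < 2:
        raise ValueError("need at least two maps per group")
    geom = maps_group_a[0].geometry
    A = np.stack([np.asarray(m.data) for m in maps_group_a])
    B = np.stack([np.asarray(m.data) for m in maps_group_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=True)
    bad = ~np.isfinite(t)
    n_zero = int(bad.sum())
    if n_zero:
        warnings.warn(f"{n_zero} voxel(s) with zero pooled variance get w = 0", stacklevel=2)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    sig = p < p_threshold
    if mode == "one_minus_p":
        w = np.where(sig, np.sign(t) * (1.0 - p), 0.0)
    elif mode == "abs_t":
        tmax = np.abs(t[sig]).max() if sig.any() else 1.0
        w = np.where(sig, t / max(tmax, 1e-12), 0.0)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return WeightImage(
        Volume(t, geom.spacing, geom.origin),
        Volume(p, geom.spacing, geom.origin),
        Volume(w, geom.spacing, geom.origin),
        p_threshold,
        n_zero,
    )


def roi_weighted_feature(
    value_map: Volume,
    weights: WeightImage,
    roi_mask: Volume,
    denominator: str = "both_partitions",
) -> tuple[float, bool]:
    """Weighted atrophic-minus-expanding ROI average.

    f = [Σ_{x∈R, atrophic} |w|·v − Σ_{x∈R, expanding} |w|·v] / Σ_{x∈R} |w|

    with atrophic = voxels whose t-sign equals ``ATROPHIC_T_SIGN``.  Returns
    ``(feature, empty_weight_flag)``; the flag is set (value 0) when the ROI
    carries no weight.  ``denominator`` may be ``both_partitions`` (default)
    or ``per_partition`` (each partition normalized separately before the
    difference) — the description "divided by the sum of the weights" admits
    both readings.
    """
    for other in (weights.w_map, roi_mask):
        if other.geometry != value_map.geometry:
            raise ValueError("value map, weights and ROI mask must share a grid")
    mask = np.asarray(roi_mask.data).astype(bool)
    v = np.asarray(value_map.data)
    w = np.asarray(weights.w_map.data)
    t = np.asarray(weights.t_map.data)
    absw = np.abs(w)
    atrophic = mask & (np.sign(t) == ATROPHIC_T_SIGN) & (absw > 0)
    expanding = mask & (np.sign(t) == -ATROPHIC_T_SIGN) & (absw > 0)
    if denominator == "both_partitions":
        denom = absw[mask].sum()
        if denom == 0:
            return 0.0, True
        f = ((absw[atrophic] * v[atrophic]).sum() - (absw[expanding] * v[expanding]).sum()) / denom
    elif denominator == "per_partition":
        da = absw[atrophic].sum()
        de = absw[expanding].sum()
        if da == 0 and de == 0:
            return 0.0, True
        fa = (absw[atrophic] * v[atrophic]).sum() / da if da > 0 else 0.0
        fe = (absw[expanding] * v[expanding]).sum() / de if de > 0 else 0.0
        f = fa - fe
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return float(f), False


def gm_density_map(
    subject_gm_prob: Volume,
    field_to_subject: DeformationField,
    fwhm_mm: float = 4.7,
) -> GMDensityMap:
    """Propagate the subject grey-matter probability to template space
    (linear interpolation along the template->subject field) and smooth with
    a Gaussian of the given FWHM (mm, spacing-aware)."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be > 0")
    gm = np.asarray(subject_gm_prob.data)
    if gm.min() < -1e-9 or gm.max() > 1 + 1e-9:
        raise ValueError("grey-matter probability must lie in [0, 1]")
    propagated = apply_deformation(subject_gm_prob, field_to_subject, mode="linear")
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = [sigma_mm / s for s in propagated.spacing]
    sm = ndimage.gaussian_filter(np.asarray(propagated.data), sigma_vox, mode="constant")
    sm = np.clip(sm, 0.0, None)
    return GMDensityMap(Volume(sm, propagated.spacing, propagated.origin), modulated=False)


def modulate(density: GMDensityMap, jacobian: Volume) -> GMDensityMap:
    """Multiply grey-matter concentration by the Jacobian so the map measures
    absolute grey-matter volume.  Double modulation is an error."""
    if density.modulated:
        raise ValueError("map is already modulated")
    if jacobian.geometry != density.values.geometry:
        raise ValueError("Jacobian and density map must share a grid")
    if np.asarray(jacobian.data).min() <= 0:
        raise ValueError("Jacobian must be > 0 for modulation")
    out = density.values.with_data(density.values.data * jacobian.data)
    return GMDensityMap(out, modulated=True)
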