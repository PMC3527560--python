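"""Non-rigid registration and Jacobian analysis of deformation fields.

The bundled backend is a multiresolution variational registration: a dense
displacement field on the fixed-image grid is driven by a demons-type force
derived from intensity differences and regularized by Gaussian smoothing of
the field (a curvature-type penalty: smoothing suppresses exactly the
high-bending components of the update).  Three similarity options are
supported; normalized mutual information and the correlation ratio are
optimized by remapping the warped moving intensities onto the fixed image's
scale each outer iteration (conditional-mean intensity matching), after
which the intensity-difference force applies.

Fields are stored fixed -> moving: ``phi(x) = x + u(x)`` maps a fixed-grid
world coordinate (mm) to the corresponding moving-image coordinate.
Resampling the moving image at ``phi`` therefore pulls it onto the fixed
grid.  Jacobian determinants of ``phi`` measure local volume change of the
moving anatomy relative to the fixed grid: J < 1 is local contraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .imgio import Geometry, LabelVolume, Volume


@dataclass
class DeformationField:
    """Dense displacement field u (mm) on the fixed-image grid, fixed -> moving."""

    displacement: np.ndarray  # shape (nx, ny, nz, 3), mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quality_flag: str = "ok"  # ok | not_converged | folded

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")
        g = Geometry(self.displacement.shape[:3], tuple(self.spacing), tuple(self.origin))
        self.spacing, self.origin = g.spacing, g.origin

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.displacement.shape[:3], self.spacing, self.origin)

    @classmethod
    def identity(cls, geometry: Geometry) -> "DeformationField":
        return cls(np.zeros(geometry.shape + (3,)), geometry.spacing, geometry.origin)


@dataclass
class RegistrationConfig:
    similarity: Literal["nmi", "correlation_ratio", "intensity_difference"] = "intensity_difference"
    regularization_weight: float = 2.0  # scales the field-smoothing sigma (mm)
    n_levels: int = 3
    max_iter: int = 40
    step_voxels: float = 0.75  # force cap per iteration, in voxel units
    seed: int = 0
    n_bins: int = 32

    def __post_init__(self) -> None:
        if self.similarity not in ("nmi", "correlation_ratio", "intensity_difference"):
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")


# ---------------------------------------------------------------------------
# Similarity measures (higher is better for all three)


def _joint_histogram(a: np.ndarray, b: np.ndarray, n_bins: int) -> np.ndarray:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=n_bins)
    return hist


def nmi(a: np.ndarray, b: np.ndarray, n_bins: int = 32, mask: np.ndarray | None = None) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B), equal-width bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("empty mask in NMI computation")
        a, b = a[mask], b[mask]
    pab = _joint_histogram(a, b, n_bins)
    pab = pab / pab.sum()
    pa = pab.sum(axis=1)
    pb = pab.sum(axis=0)

    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hab = _entropy(pab.ravel())
    if hab == 0.0:  # both images constant
        return 2.0
    return (_entropy(pa) + _entropy(pb)) / hab


def correlation_ratio(fixed: np.ndarray, moving: np.ndarray, n_bins: int = 32) -> float:
    """Correlation ratio eta^2 of fixed given binned moving intensities."""
    f = np.asarray(fixed, dtype=float).ravel()
    m = np.asarray(moving, dtype=float).ravel()
    total_var = f.var()
    if total_var == 0:
        return 1.0
    lo, hi = m.min(), m.max()
    if hi == lo:
        return 0.0
    bins = np.clip(((m - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=f, minlength=n_bins)
    sq = np.bincount(bins, weights=f * f, minlength=n_bins)
    nz = counts > 0
    within = (sq[nz] - sums[nz] ** 2 / counts[nz]).sum() / f.size
    return float(1.0 - within / total_var)


def similarity_score(fixed: np.ndarray, moving: np.ndarray, kind: str, n_bins: int = 32) -> float:
    if kind == "nmi":
        return nmi(fixed, moving, n_bins)
    if kind == "correlation_ratio":
        return correlation_ratio(fixed, moving, n_bins)
    if kind == "intensity_difference":
        return -float(np.mean((np.asarray(fixed, float) - np.asarray(moving, float)) ** 2))
    raise ValueError(f"unknown similarity {kind!r}")


# ---------------------------------------------------------------------------
# Applying fields


def apply_deformation(
    vol: Volume | LabelVolume,
    field: DeformationField,
    mode: str = "linear",
    cval: float = 0.0,
) -> Volume | LabelVolume:
    """Pull the (moving) volume onto the field's fixed grid.

    Samples ``vol`` at ``x + u(x)`` for every fixed-grid voxel x.  ``nearest``
    is mandatory for label volumes; out-of-field samples get ``cval``.
    """
    is_labels = isinstance(vol, LabelVolume)
    data = vol.labels if is_labels else vol.data
    if is_labels and mode != "nearest":
        mode = "nearest"
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unsupported interpolation mode {mode!r}")
    geom = field.geometry
    world = geom.index_grid_world() + field.displacement
    coords = [
        (world[..., a] - vol.origin[a]) / vol.spacing[a] for a in range(3)
    ]
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), coords, order=order, mode="constant", cval=cval
    )
    if is_labels:
        return LabelVolume(np.round(out).astype(np.int32), geom.spacing, geom.origin, dict(vol.table))
    return Volume(out, geom.spacing, geom.origin)


def jacobian_determinant(field: DeformationField, check_positive: bool = False) -> Volume:
    """Determinant of the Jacobian of ``phi(x) = x + u(x)``.

    Central finite differences in physical units (spacing-aware); one-sided
    at the boundary faces.  With ``check_positive``, non-positive interior
    determinants raise with the offending voxel coordinates.
    """
    u = field.displacement
    sp = field.spacing
    # F[a][k] = d phi_k / d x_a = delta_ak + d u_k / d x_a
    grads = [np.gradient(u[..., k], *sp, axis=(0, 1, 2)) for k in range(3)]
    F = np.empty(u.shape[:3] + (3, 3))
    for a in range(3):
        for k in range(3):
            F[..., a, k] = grads[k][a] + (1.0 if a == k else 0.0)
    det = np.linalg.det(F)
    if check_positive:
        interior = np.zeros(det.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        bad = np.argwhere((det <= 0) & interior)
        if bad.size:
            raise ValueError(
                f"non-positive Jacobian determinant at interior voxel(s) {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
    return Volume(det, field.spacing, field.origin)


def bending_energy(field: DeformationField) -> float:
    """Sum of squared second derivatives of the displacement (curvature norm)."""
    u = field.displacement
    sp = field.spacing
    total = 0.0
    for k in range(3):
        for a in range(3):
            first = np.gradient(u[..., k], sp[a], axis=a)
            second = np.gradient(first, sp[a], axis=a)
            total += float((second**2).sum())
    return total


# ---------------------------------------------------------------------------
# Bundled variational backend


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.gaussian_filter(data, sigma=0.5 * factor)
    return sm[::factor, ::factor, ::factor]


def _remap_intensities(fixed: np.ndarray, warped: np.ndarray, n_bins: int) -> np.ndarray:
    """Replace warped intensities by E[fixed | warped bin] (histogram matching
    toward the fixed image); turns NMI/CR optimization into an intensity-
    difference problem on remapped images."""
    lo, hi = warped.min(), warped.max()
    if hi == lo:
        return np.full_like(warped, fixed.mean())
    bins = np.clip(((warped - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins.ravel(), minlength=n_bins).astype(float)
    sums = np.bincount(bins.ravel(), weights=fixed.ravel(), minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), fixed.mean())
    return means[bins]


def register_nonrigid(
    fixed: Volume, moving: Volume, cfg: RegistrationConfig | None = None
) -> DeformationField:
    """Estimate the fixed -> moving displacement field.

    Multiresolution (coarse-to-fine image pyramid); at each level the field
    is updated with a normalized intensity-difference force and re-smoothed
    with a Gaussian whose width grows with ``regularization_weight``.  Never
    raises on poor convergence: the returned field carries a quality flag.
    """
    cfg = cfg or RegistrationConfig()
    fg = fixed.geometry
    if fixed.geometry.spacing != moving.geometry.spacing and fixed.geometry.shape != moving.geometry.shape:
        pass  # different grids are fine; sampling goes through world coords
    F_full = np.asarray(fixed.data, dtype=float)
    scale = float(F_full.std()) or 1.0

    M_full = np.asarray(moving.data, dtype=float)

    u = None
    for level in range(cfg.n_levels - 1, -1, -1):
        factor = 2**level
        if min(s // factor for s in fg.shape) < 4:
            continue
        F = _downsample(F_full, factor)
        # smooth the moving image identically so identical inputs give zero force
        M_lvl = ndimage.gaussian_filter(M_full, 0.5 * factor) if factor > 1 else M_full
        lvl_spacing = tuple(s * factor for s in fg.spacing)
        lvl_geom = Geometry(F.shape, lvl_spacing, fg.origin)
        if u is None:
            u = np.zeros(F.shape + (3,))
        else:
            zoom = [F.shape[a] / u.shape[a] for a in range(3)]
            u = np.stack(
                [ndimage.zoom(u[..., k], zoom, order=1) for k in range(3)], axis=-1
            )
        world = lvl_geom.index_grid_world()
        sigma_mm = 1.0 + 1.0 * cfg.regularization_weight
        sigma_vox = [sigma_mm / s for s in lvl_spacing]
        max_step_mm = cfg.step_voxels * min(lvl_spacing)
        n_iter = max(5, cfg.max_iter // (1 if level == 0 else 2))
        for _ in range(n_iter):
            coords = [
                (world[..., a] + u[..., a] - moving.origin[a]) / moving.spacing[a]
                for a in range(3)
            ]
            W = ndimage.map_coordinates(M_lvl, coords, order=1, mode="nearest")
            if cfg.similarity in ("nmi", "correlation_ratio"):
                W = _remap_intensities(F, W, cfg.n_bins)
            diff = F - W
            gW = np.gradient(ndimage.gaussian_filter(W, 1.0), *lvl_spacing)
            gmag2 = gW[0] ** 2 + gW[1] ** 2 + gW[2] ** 2
            denom = gmag2 + (diff / scale) ** 2 * gmag2.mean() + 1e-12 * scale**2
            step = np.stack([diff * g / denom for g in gW], axis=-1)
            mag = np.sqrt((step**2).sum(axis=-1, keepdims=True))
            step *= np.minimum(1.0, max_step_mm / np.maximum(mag, 1e-12))
            u = u + step
            for k in range(3):
                u[..., k] = ndimage.gaussian_filter(u[..., k], sigma_vox)
    if u is None:  # grid too small for any level
        u = np.zeros(fg.shape + (3,))
    if u.shape[:3] != fg.shape:
        zoom = [fg.shape[a] / u.shape[a] for a in range(3)]
        u = np.stack([ndimage.zoom(u[..., k], zoom, order=1) for k in range(3)], axis=-1)

    out = DeformationField(u, fg.spacing, fg.origin)
    # quality control: similarity must not degrade; Jacobian must stay positive
    warped = apply_deformation(moving, out, mode="linear")
    s_before = similarity_score(F_full, apply_deformation(moving, DeformationField.identity(fg)).data, cfg.similarity, cfg.n_bins)
    s_after = similarity_score(F_full, warped.data, cfg.similarity, cfg.n_bins)
    det = jacobian_determinant(out).data[1:-1, 1:-1, 1:-1]
    if det.size and det.min() <= 0:
        out.quality_flag = "folded"
        warnings.warn("registration produced non-positive interior Jacobians", stacklevel=2)
    elif s_after < s_before - 0.02 * (abs(s_before) + 1e-6):
        # small tolerance: resampling blur can cost a little NMI/CR even
        # when the alignment itself improves
        out.quality_flag = "not_converged"
        warnings.warn("registration did not improve the similarity", stacklevel=2)
    return out
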