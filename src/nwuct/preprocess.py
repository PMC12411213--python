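"""Field-of-view selection, smoothing, skull stripping, and atlas registration.

The chain standardizes a head CT before bilateral density comparison:

1. ``select_field_of_view`` crops to the head (largest above-air component).
2. ``smooth`` applies a mild Gaussian in mm units.
3. ``skull_strip`` extracts the brain as the largest soft-tissue component
   enclosed by the bone shell.
4. ``register_to_atlas`` estimates a rigid or full affine transform onto the
   atlas template by minimizing a masked mean-squared intensity difference
   over a multi-resolution pyramid (deterministic: centroid/principal-axes
   initialization, Powell optimizer, no random restarts).
5. ``resample`` realizes a transform on the atlas grid (linear interpolation
   for intensities, nearest neighbor for labels).

All transforms are world(mm)->world(mm) 4x4 affines; the registration result
maps subject world coordinates into atlas world coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .errors import ExtractionError, ForegroundError, MaskError, ParameterError
from .volume_io import HU_AIR, CTVolume, LabelVolume, _as_bool_mask

_RIGID_ORTHO_TOL = 1e-6


@dataclass
class AffineTransform:
    """A world->world affine, with its degrees-of-freedom class.

    ``matrix`` maps homogeneous world coordinates of the *moving* image into
    the *fixed* (atlas) world frame.
    """

    matrix: np.ndarray
    dof_class: str = "affine"  # "rigid" | "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ParameterError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ParameterError("transform matrix must be invertible")
        if self.dof_class not in ("rigid", "affine"):
            raise ParameterError(f"unknown dof_class {self.dof_class!r}")
        if self.dof_class == "rigid":
            R = self.matrix[:3, :3]
            if (np.abs(R @ R.T - np.eye(3)).max() > 1e-5
                    or abs(np.linalg.det(R) - 1.0) > 1e-5):
                raise ParameterError("rigid transform must have orthonormal rotation")

    @classmethod
    def identity(cls, dof_class: str = "rigid") -> "AffineTransform":
        return cls(np.eye(4), dof_class)

    @classmethod
    def from_rigid(cls, translation_mm, rotation_deg, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        """Rigid transform: rotate (extrinsic x-y-z Euler, degrees) about
        ``center`` then translate."""
        R = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()
        c = np.asarray(center, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(translation_mm, float) + c - R @ c
        return cls(m, "rigid")

    @property
    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.dof_class)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other (apply ``other`` first)."""
        dof = "rigid" if self.dof_class == other.dof_class == "rigid" else "affine"
        return AffineTransform(self.matrix @ other.matrix, dof)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"matrix": self.matrix.tolist(), "dof_class": self.dof_class}, indent=2))

    @classmethod
    def load_json(cls, path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["matrix"]), d["dof_class"])


@dataclass
class PreprocessReport:
    """Bookkeeping for one subject's preprocessing run."""

    crop_bounds: tuple | None = None
    brain_voxel_count: int = 0
    registration_metric_final: float = float("nan")
    converged: bool = True
    dof_selected: str = "rigid"
    transform: "AffineTransform | None" = None


@dataclass
class RegistrationConfig:
    """Knobs for intensity-based registration (all deterministic).

    The metric samples only the eroded interior of the atlas brain mask and
    clamps both images to a soft-tissue display window before comparison:
    the ~1000 HU brain/bone rim otherwise dominates the masked MSE, and
    because interior points sample that edge from one side only, resampling
    blur turns it into a systematic shrink of the recovered transform.
    Both images receive identical extra Gaussian smoothing inside the metric
    (heavier for the global rigid stage, lighter for the affine refinement)
    so the cost is symmetric under blur and exactly zero at self-alignment.
    """

    dof_class: str = "affine"        # final stage; rigid stage always runs first
    pyramid_factors: tuple = (4, 2, 1)
    max_iter: int = 80               # Powell iterations per level
    max_points: int = 40000          # cap on metric sample points per level
    xtol: float = 3e-4
    ftol: float = 1e-9
    use_principal_axes: bool = True
    mask_erosion_vox: int = 3        # metric samples stay off the bone rim
    metric_clip: tuple = (-100.0, 150.0)   # HU clamp inside the metric
    metric_sigma_rigid: float = 1.0  # extra smoothing (voxels), rigid stage
    metric_sigma_affine: float = 0.5  # extra smoothing (voxels), affine stage
    trim_fraction: float = 0.15      # residual tail dropped in early stages:
                                     # robustness to focal hypodensity
    outlier_nsigma: float = 3.0      # final-pass exclusion threshold
    outlier_floor_hu: float = 3.0    # ... with an absolute floor
    affine_gain_threshold: float = 0.9  # keep the 12-dof result only if it
    # cuts the inlier metric below this fraction of the rigid optimum; the
    # extra degrees of freedom otherwise fit noise and drift (notably the
    # weakly constrained through-plane scale)
    affine_floor_hu2: float = 0.2    # ... and only if the rigid fit leaves
    # real misfit; near-zero residuals make the ratio test meaningless
    affine_max_outlier_fraction: float = 0.10  # with more unexplained
    # (lesioned) tissue than this, the 12-dof fit is not identifiable — it
    # can always "explain" a hemispheric hypodensity by warping toward the
    # healthy side — so the rigid solution is kept


# ---------------------------------------------------------------------------
# Field of view / smoothing / skull strip
# ---------------------------------------------------------------------------

def select_field_of_view(vol: CTVolume, air_threshold: float = -500.0,
                         margin: int = 2) -> tuple[CTVolume, tuple]:
    """Crop to the bounding box of the largest above-air connected component.

    The affine is shifted so retained voxels keep their world coordinates.
    Returns ``(cropped, crop_bounds)`` with per-axis ``(lo, hi)`` index ranges
    (half-open) into the original array.
    """
    fg = vol.data > air_threshold
    if not fg.any():
        raise ForegroundError(
            f"no voxels above {air_threshold} HU; cannot select a field of view")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    idx = np.argwhere(fg)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, vol.shape)
    bounds = tuple((int(a), int(b)) for a, b in zip(lo, hi))
    cropped = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    affine = vol.affine.copy()
    affine[:3, 3] = vol.world_coords(lo)
    return CTVolume(data=cropped.copy(), affine=affine), bounds


def smooth(vol: CTVolume, sigma_mm) -> CTVolume:
    """Gaussian smoothing with a physical (mm) standard deviation.

    ``sigma_mm`` may be scalar or per-axis; 0 returns the input unchanged.
    """
    sigma_mm = np.broadcast_to(np.asarray(sigma_mm, dtype=float), (3,)).copy()
    if np.any(sigma_mm < 0):
        raise ParameterError(f"sigma_mm must be >= 0, got {sigma_mm}")
    if np.all(sigma_mm == 0):
        return vol.with_data(vol.data.copy())
    sigma_vox = sigma_mm / vol.spacing
    return vol.with_data(ndimage.gaussian_filter(vol.data, sigma=sigma_vox))


def default_smoothing_sigma_mm(vol: CTVolume) -> float:
    """Default: half the in-plane voxel size (mild denoising)."""
    return 0.5 * float(np.min(vol.spacing[:2]))


def skull_strip(vol: CTVolume, bone_threshold: float = 300.0,
                brain_window: tuple = (0.0, 100.0)) -> LabelVolume:
    """Extract a brain mask from a head CT in HU.

    Candidate voxels fall inside ``brain_window``; if a bone shell is present
    the candidates are restricted to its enclosed interior, which removes
    scalp and face soft tissue.  The mask is the largest connected candidate
    component after morphological closing and hole filling, and never
    contains voxels at or above ``bone_threshold``.
    """
    lo, hi = brain_window
    if lo >= hi:
        raise ParameterError(f"inverted brain window {brain_window}")
    data = vol.data
    cand = (data >= lo) & (data <= hi)
    bone = data >= bone_threshold
    if bone.any():
        interior = ndimage.binary_fill_holes(bone) & ~bone
        cand &= interior
    if not cand.any():
        raise ExtractionError("no voxels in the brain window inside the skull")
    struct = ndimage.generate_binary_structure(3, 1)
    cand = ndimage.binary_closing(cand, structure=struct, iterations=2)
    cand = ndimage.binary_fill_holes(cand)
    cand &= data < bone_threshold
    lab, n = ndimage.label(cand)
    if n == 0:
        raise ExtractionError("brain extraction produced an empty mask")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return LabelVolume(labels=mask.astype(np.int16), affine=vol.affine.copy(),
                       code_map={1: {"name": "brain", "hemisphere": None}})


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _weighted_moments(vol: CTVolume, mask: np.ndarray):
    """Intensity-weighted centroid (mm) and second-moment matrix over a mask."""
    idx = np.argwhere(mask)
    w = np.clip(vol.data[mask] - HU_AIR, 0.0, None)
    if w.sum() <= 0:
        w = np.ones(len(idx))
    pts = vol.world_coords(idx)
    c = np.average(pts, axis=0, weights=w)
    d = pts - c
    cov = (d * w[:, None]).T @ d / w.sum()
    return c, cov


def _principal_axes_rotation(cov_fix: np.ndarray, cov_mov: np.ndarray) -> np.ndarray:
    """Rotation aligning fixed principal axes onto moving ones, or identity.

    Guarded: requires clearly anisotropic moments and an implied rotation
    < 45 degrees, otherwise principal axes are unreliable and identity is
    returned.  Axis signs are chosen to keep the rotation nearest identity.
    """
    wf, Uf = np.linalg.eigh(cov_fix)
    wm, Um = np.linalg.eigh(cov_mov)
    if wf[0] <= 0 or wm[0] <= 0:
        return np.eye(3)
    if wf[2] / wf[0] < 1.1 or wm[2] / wm[0] < 1.1:
        return np.eye(3)
    best = np.eye(3)
    best_dev = np.inf
    for signs in ([1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
                  [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1]):
        R = Um @ np.diag(signs) @ Uf.T
        if np.linalg.det(R) < 0:
            continue
        dev = np.abs(R - np.eye(3)).max()
        if dev < best_dev:
            best_dev = dev
            best = R
    angle = np.linalg.norm(Rotation.from_matrix(best).as_rotvec())
    if angle > np.deg2rad(45):
        return np.eye(3)
    return best


def _rigid_params_to_matrix(p, center):
    """p = [tx, ty, tz (mm), rx, ry, rz (deg)] -> 4x4 about ``center``."""
    R = Rotation.from_euler("xyz", p[3:6], degrees=True).as_matrix()
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = p[:3] + center - R @ center
    return m


def _affine_params_to_matrix(p, center):
    """p = [9 matrix entries, tx, ty, tz] -> 4x4 about ``center``."""
    A = np.asarray(p[:9], float).reshape(3, 3)
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = np.asarray(p[9:12], float) + center - A @ center
    return m


def _pyramid_points(atlas: CTVolume, atlas_data: np.ndarray,
                    atlas_mask: np.ndarray, factor: int, max_points: int):
    """Strided sample points (world mm) and values from a prepared array."""
    sl = (slice(None, None, factor),) * 3
    msk = atlas_mask[sl]
    idx = np.argwhere(msk) * factor
    vals = atlas_data[sl][msk]
    if len(idx) > max_points:
        step = int(np.ceil(len(idx) / max_points))
        idx, vals = idx[::step], vals[::step]
    return atlas.world_coords(idx), vals


def register_to_atlas(subject: CTVolume, subject_brain, atlas: CTVolume,
                      atlas_brain, config: RegistrationConfig | None = None
                      ) -> tuple[AffineTransform, PreprocessReport]:
    """Estimate the subject->atlas world affine by masked-MSE minimization.

    Internally optimizes the atlas->subject map M (so metric evaluation needs
    no matrix inversion): for sample points y inside the atlas brain mask, the
    cost is ``mean((subject(M y) - atlas(y))^2)``.  A rigid stage runs over
    the full pyramid; for ``dof_class='affine'`` a 12-dof stage refines the
    rigid result on the finer levels.  Non-convergence is reported via
    ``report.converged``, never raised.
    """
    cfg = config or RegistrationConfig()
    a_mask = _as_bool_mask(atlas_brain)
    s_mask = _as_bool_mask(subject_brain)
    if not a_mask.any() or not s_mask.any():
        raise MaskError("empty brain mask supplied to registration")
    if cfg.mask_erosion_vox > 0:
        # The brain/skull rim carries a ~1000 HU jump that linear resampling
        # blurs; sampling it biases the MSE optimum by up to half a voxel.
        eroded = ndimage.binary_erosion(a_mask, iterations=cfg.mask_erosion_vox)
        if eroded.any():
            a_mask = eroded

    c_atlas, cov_a = _weighted_moments(atlas, a_mask)
    c_subj, cov_s = _weighted_moments(subject, s_mask)
    R0 = (_principal_axes_rotation(cov_a, cov_s)
          if cfg.use_principal_axes else np.eye(3))
    t0 = c_subj - c_atlas
    rot0_deg = Rotation.from_matrix(R0).as_euler("xyz", degrees=True)

    metric_mask = a_mask
    if cfg.mask_erosion_vox > 0:
        eroded = ndimage.binary_erosion(a_mask, iterations=cfg.mask_erosion_vox)
        if eroded.any():
            metric_mask = eroded

    clip_lo, clip_hi = cfg.metric_clip
    atlas_base = np.clip(atlas.data, clip_lo, clip_hi)
    subj_base = np.clip(subject.data, clip_lo, clip_hi)
    inv_subj_affine = np.linalg.inv(subject.affine)
    cache: dict = {}

    def level_pair(factor, sigma):
        """Identically smoothed atlas/subject arrays for one level."""
        key = (factor, sigma)
        if key not in cache:
            s = np.sqrt((factor / 2.0) ** 2 + sigma ** 2) if factor > 1 else sigma
            cache[key] = (
                ndimage.gaussian_filter(atlas_base, s) if s else atlas_base,
                ndimage.gaussian_filter(subj_base, s) if s else subj_base,
            )
        return cache[key]

    def residuals_at(m, pts, vals, sdata):
        x = pts @ m[:3, :3].T + m[:3, 3]
        ijk = x @ inv_subj_affine[:3, :3].T + inv_subj_affine[:3, 3]
        return ndimage.map_coordinates(sdata, ijk.T, order=1, cval=clip_lo) - vals

    def make_cost(pts, vals, sdata, to_matrix, center, scales, p_ref,
                  trim=True):
        n_keep = (max(1, int(round((1.0 - cfg.trim_fraction) * len(pts))))
                  if trim else len(pts))

        def cost(z):
            sq = residuals_at(to_matrix(p_ref + z * scales, center),
                              pts, vals, sdata) ** 2
            if n_keep < len(sq):
                # trimmed least squares: a focal lesion mismatching the
                # atlas must not drag the transform toward itself
                sq = np.partition(sq, n_keep - 1)[:n_keep]
            return float(np.mean(sq))
        return cost

    def inliers(m, pts, vals, sdata):
        """Points whose residual is consistent with noise at solution ``m``.

        Threshold = nsigma x robust residual scale (MAD), floored so a
        noise-free exact match keeps every point.
        """
        r = residuals_at(m, pts, vals, sdata)
        sigma = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        thr = max(cfg.outlier_nsigma * sigma, cfg.outlier_floor_hu)
        keep = np.abs(r) <= thr
        return keep if keep.sum() >= 100 else np.ones(len(r), dtype=bool)

    converged = True
    final_metric = np.nan

    def powell(cost, nparam):
        # Bounds keep the line search off the flat out-of-field plateau,
        # where the metric is constant and bracketing would run away.
        return minimize(cost, np.zeros(nparam), method="Powell",
                        bounds=[(-4.0, 4.0)] * nparam,
                        options={"maxiter": cfg.max_iter, "xtol": cfg.xtol,
                                 "ftol": cfg.ftol})

    # Stage 1: rigid over the full pyramid with the trimmed metric, then an
    # untrimmed fine-step refinement restricted to residual inliers (the
    # trim is needed while far from alignment; at the end it would soften
    # the optimum, so outliers are excluded explicitly instead).
    p = np.concatenate([t0, rot0_deg])
    scales = np.array([10.0, 10.0, 10.0, 5.0, 5.0, 5.0])
    fine = cfg.pyramid_factors[-1]
    for factor in cfg.pyramid_factors:
        adata, sdata = level_pair(factor, cfg.metric_sigma_rigid)
        pts, vals = _pyramid_points(atlas, adata, metric_mask, factor,
                                    cfg.max_points)
        cost = make_cost(pts, vals, sdata, _rigid_params_to_matrix, c_atlas,
                         scales, p)
        res = powell(cost, 6)
        p = p + res.x * scales
        converged &= bool(res.success)
        final_metric = float(res.fun)
    adata, sdata = level_pair(fine, cfg.metric_sigma_rigid)
    pts, vals = _pyramid_points(atlas, adata, metric_mask, fine, cfg.max_points)
    # two rounds of inlier re-estimation: with an extensive lesion the first
    # (trim-based) optimum is still biased, so its inlier set improves after
    # one refinement
    for _round in range(2):
        keep = inliers(_rigid_params_to_matrix(p, c_atlas), pts, vals, sdata)
        for shrink in (1.0, 0.125):
            cost = make_cost(pts[keep], vals[keep], sdata,
                             _rigid_params_to_matrix, c_atlas,
                             scales * shrink, p, trim=False)
            res = powell(cost, 6)
            p = p + res.x * scales * shrink
            converged &= bool(res.success)
            final_metric = float(res.fun)
    M = _rigid_params_to_matrix(p, c_atlas)
    M_rigid = M.copy()
    dof_selected = "rigid"

    # Stage 2: full affine on the finer levels, same trim-then-refine plan.
    if cfg.dof_class == "affine":
        pa = np.concatenate([M[:3, :3].ravel(), p[:3]])
        scales_a = np.concatenate([np.full(9, 0.05), np.full(3, 3.0)])
        for factor in cfg.pyramid_factors[-2:]:
            adata, sdata = level_pair(factor, cfg.metric_sigma_affine)
            pts, vals = _pyramid_points(atlas, adata, metric_mask, factor,
                                        cfg.max_points)
            cost = make_cost(pts, vals, sdata, _affine_params_to_matrix,
                             c_atlas, scales_a, pa)
            res = powell(cost, 12)
            pa = pa + res.x * scales_a
            converged &= bool(res.success)
            final_metric = float(res.fun)
        adata, sdata = level_pair(fine, cfg.metric_sigma_affine)
        pts, vals = _pyramid_points(atlas, adata, metric_mask, fine,
                                    cfg.max_points)
        keep = inliers(_affine_params_to_matrix(pa, c_atlas), pts, vals, sdata)
        for shrink in (1.0, 0.125):
            cost = make_cost(pts[keep], vals[keep], sdata,
                             _affine_params_to_matrix, c_atlas,
                             scales_a * shrink, pa, trim=False)
            res = powell(cost, 12)
            pa = pa + res.x * scales_a * shrink
            converged &= bool(res.success)
        M_affine = _affine_params_to_matrix(pa, c_atlas)
        # Parsimony check on a model-independent robust cost, computed on
        # the heavier smoothed pair and restricted to structure-bearing
        # atlas points (gradient above ~1 HU/voxel; homogeneous interior
        # points say nothing about misfit).  On lightly smoothed data an
        # off-lattice transform also wins spuriously because linear
        # interpolation averages voxel noise.  The two candidates are scored
        # on the intersection of their residual-inlier sets: hypodense
        # tissue the atlas lacks is excluded under either model, while a
        # transform that distorted itself toward a lesion fits the healthy
        # tissue worse and loses.  The 12-dof result is kept only when it
        # buys a clear improvement over the rigid optimum.
        adata_c, sdata_c = level_pair(fine, cfg.metric_sigma_rigid)
        grad = np.linalg.norm(np.gradient(adata_c), axis=0)
        struct_mask = metric_mask & (grad > 1.0)
        if struct_mask.sum() < 500:
            struct_mask = metric_mask
        pts_c, vals_c = _pyramid_points(atlas, adata_c, struct_mask, fine,
                                        cfg.max_points)
        common = (inliers(M_rigid, pts_c, vals_c, sdata_c)
                  & inliers(M_affine, pts_c, vals_c, sdata_c))
        if common.sum() < 100:
            common = np.ones(len(pts_c), dtype=bool)

        def robust_cost(m):
            return float(np.mean(
                residuals_at(m, pts_c[common], vals_c[common], sdata_c) ** 2))

        cost_rigid = robust_cost(M_rigid)
        cost_affine = robust_cost(M_affine)
        outlier_fraction = 1.0 - float(
            inliers(M_rigid, pts, vals, sdata).mean())
        if (outlier_fraction <= cfg.affine_max_outlier_fraction
                and cost_rigid > cfg.affine_floor_hu2
                and cost_affine < cfg.affine_gain_threshold * cost_rigid):
            M = M_affine
            final_metric = cost_affine
            dof_selected = "affine"
        else:
            M = M_rigid
            final_metric = cost_rigid

    if cfg.dof_class == "rigid":
        # Re-orthonormalize: Powell steps keep it rigid by construction, but
        # guard against accumulated floating-point drift.
        U, _, Vt = np.linalg.svd(M[:3, :3])
        M[:3, :3] = U @ Vt
    transform = AffineTransform(np.linalg.inv(M), cfg.dof_class)
    report = PreprocessReport(
        brain_voxel_count=int(s_mask.sum()),
        registration_metric_final=final_metric,
        converged=converged,
        dof_selected=dof_selected,
        transform=transform,
    )
    return transform, report


def resample(vol, transform: AffineTransform | None, target_grid,
             order: int | None = None):
    """Resample ``vol`` onto ``target_grid`` under a world->world transform.

    ``transform`` maps moving (``vol``) world coordinates to the target's
    world frame (pass ``None`` for identity).  Intensity volumes use linear
    interpolation with -1024 HU fill; label volumes use nearest neighbor with
    0 fill and preserve their code map.
    """
    is_label = isinstance(vol, LabelVolume)
    data = vol.labels if is_label else vol.data
    if order is None:
        order = 0 if is_label else 1
    cval = 0 if is_label else HU_AIR
    t_affine = target_grid.affine
    shape = target_grid.shape
    M = np.eye(4) if transform is None else np.linalg.inv(transform.matrix)
    src_affine_inv = np.linalg.inv(vol.affine)
    full = src_affine_inv @ M @ t_affine  # target index -> source index
    ijk = np.indices(shape, dtype=float).reshape(3, -1)
    src = full[:3, :3] @ ijk + full[:3, 3:4]
    out = ndimage.map_coordinates(data.astype(float), src, order=order,
                                  cval=cval).reshape(shape)
    if is_label:
        return LabelVolume(labels=np.rint(out).astype(vol.labels.dtype),
                           affine=t_affine.copy(), code_map=dict(vol.code_map))
    return CTVolume(data=out, affine=t_affine.copy())
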