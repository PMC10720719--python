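"""Normalization and spatial alignment: masking, bias correction, modal
intensity scaling, rigid registration, minimum-deformation-template (MDT)
construction, B-spline warp estimation, two-step warp propagation, and
mask-renormalized Gaussian smoothing.

The registration chain mirrors longitudinal small-animal MRI practice: all
geometric transforms are estimated on the *pre-injection* images only (so the
bright/dark manganese bolus can never bias the alignment) and then applied
unchanged to every post-injection session of the same subject.  Each image is
resampled exactly once through its concatenated transform chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .image import BrainMask, VolumeImage
from .transforms import (
    ComposedTransform,
    RigidTransform,
    Transform,
    WarpTransform,
    resample,
)

__all__ = [
    "compute_brain_mask",
    "erode_mask",
    "estimate_bias_field",
    "apply_bias_field",
    "correct_bias",
    "histogram_mode",
    "modal_scale",
    "ncc",
    "register_rigid",
    "RigidConfig",
    "WarpConfig",
    "estimate_warp",
    "MDTResult",
    "build_mdt",
    "propagate_to_timepoints",
    "smooth_gaussian",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Masking, bias, modal scaling
# ---------------------------------------------------------------------------

def compute_brain_mask(img: VolumeImage) -> BrainMask:
    """Skull-strip by intensity: Otsu threshold, largest 6-connected
    component, morphological closing (ball radius 2), hole filling."""
    vox = np.asarray(img.voxels)
    if np.ptp(vox) == 0:
        raise ValueError("cannot mask an all-constant image (Otsu undefined)")
    thr = threshold_otsu(vox)
    binary = vox > thr
    if not binary.any():
        raise ValueError("empty foreground after Otsu thresholding")
    six = ndimage.generate_binary_structure(3, 1)
    comp, n = ndimage.label(binary, structure=six)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        binary = comp == (1 + int(np.argmax(sizes)))
    closed = ndimage.binary_closing(binary, structure=ball(2))
    filled = ndimage.binary_fill_holes(closed, structure=six)
    return BrainMask(filled, img.affine.copy())


def erode_mask(mask: BrainMask, mm: float) -> BrainMask:
    """Erode a mask by ``mm`` (Euclidean), trimming partial-volume rim voxels."""
    if mm <= 0:
        return BrainMask(mask.data.copy(), mask.affine)
    voxel_mm = np.linalg.norm(np.asarray(mask.affine)[:3, :3], axis=0)
    dist = ndimage.distance_transform_edt(mask.data, sampling=voxel_mm)
    return BrainMask(dist > mm, mask.affine)


def _poly_terms(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix x^i y^j z^k, i+j+k <= order, on (..., 3) coords."""
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((x**i) * (y**j) * (z**k))
    return np.stack(cols, axis=-1)


def estimate_bias_field(
    img: VolumeImage, mask: BrainMask, order: int = 3, robust: bool = True
) -> np.ndarray:
    """Estimate a multiplicative bias field by a log-domain polynomial fit.

    A degree-``order`` 3D polynomial is least-squares fitted to log intensity
    over mask voxels and exponentiated, then normalized to unit geometric
    mean over the mask.  With ``robust`` (default) the fit is re-estimated
    twice after trimming voxels whose residual exceeds 2.5 scaled MADs, so
    focal signal anomalies — above all the dark Mn(II) injection core and its
    bright halo — cannot tilt the low-order field.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    vox = np.asarray(img.voxels, dtype=np.float64)
    m = mask.data
    if np.any(vox[m] <= 0):
        raise ValueError("bias correction requires positive in-mask intensities")
    # normalised coordinates keep the Vandermonde well conditioned
    ctr = img.center_world()
    scale = np.maximum(np.asarray(img.shape) * img.voxel_mm / 2.0, 1e-6)
    world = (img.world_grid() - ctr) / scale
    A_full = _poly_terms(world[m], order)
    y_full = np.log(vox[m])
    coef, *_ = np.linalg.lstsq(A_full, y_full, rcond=None)
    if robust:
        for _ in range(2):
            resid = y_full - A_full @ coef
            mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if mad <= 0:
                break
            keep = np.abs(resid - np.median(resid)) <= 2.5 * mad
            if keep.sum() < A_full.shape[1] * 10:
                break
            coef, *_ = np.linalg.lstsq(A_full[keep], y_full[keep], rcond=None)
    log_field = _poly_terms(world.reshape(-1, 3), order) @ coef
    log_field = log_field.reshape(img.shape)
    log_field -= log_field[m].mean()  # unit geometric mean over the mask
    return np.exp(log_field)


def apply_bias_field(img: VolumeImage, field: np.ndarray) -> VolumeImage:
    """Divide an image by a (same-grid) multiplicative bias field."""
    field = np.asarray(field, dtype=np.float64)
    if field.shape != img.shape:
        raise ValueError("bias field grid does not match the image")
    out = np.asarray(img.voxels, dtype=np.float64) / field
    return img.like(out.astype(np.float32))


def correct_bias(
    img: VolumeImage, mask: BrainMask, order: int = 3, robust: bool = True
) -> VolumeImage:
    """Bias-correct one image: estimate the field on it, divide it out.

    For longitudinal sessions of one subject, prefer estimating the field on
    the pre-injection image (:func:`estimate_bias_field`) and applying it
    unchanged to the post-injection sessions — the same estimate-on-pre,
    apply-to-post principle the geometric two-step alignment uses — so that
    session-specific signal (the injection bolus) can never imprint a
    differential whole-brain trend between timepoints.
    """
    return apply_bias_field(img, estimate_bias_field(img, mask, order=order, robust=robust))


def histogram_mode(
    img: VolumeImage, mask: BrainMask, n_bins: int = 256
) -> float:
    """Mode of the in-mask intensity histogram.

    The histogram spans the 1st-99th percentile of in-mask intensities with
    ``n_bins`` equal-width bins; returns the centre of the fullest bin, ties
    broken toward the lower bin.
    """
    vals = np.asarray(img.voxels)[mask.data]
    if vals.size == 0:
        raise ValueError("empty mask")
    if vals.size < n_bins:
        raise ValueError(
            f"histogram_mode needs at least n_bins={n_bins} in-mask voxels, got {vals.size}"
        )
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        return float(lo)  # effectively constant: single occupied bin
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    k = int(np.argmax(counts))  # argmax takes the first (lower) maximal bin
    return float(0.5 * (edges[k] + edges[k + 1]))


def modal_scale(
    img: VolumeImage, mask: BrainMask, reference_mode: float, n_bins: int = 256
) -> tuple[VolumeImage, float]:
    """Scale every voxel so the in-mask histogram mode matches ``reference_mode``."""
    mode = histogram_mode(img, mask, n_bins=n_bins)
    if mode <= 0:
        raise ValueError(f"image mode must be positive, got {mode}")
    factor = float(reference_mode) / mode
    return img.like(np.asarray(img.voxels) * factor), factor


# ---------------------------------------------------------------------------
# Similarity + rigid registration
# ---------------------------------------------------------------------------

def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation of two arrays over an optional mask."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


@dataclass
class RigidConfig:
    """Multi-resolution rigid registration settings."""

    levels: tuple[int, ...] = (4, 2, 1)
    max_points: int = 40000
    bound_deg: float = 10.0
    bound_mm: float = 2.0
    xtol: float = 1e-4
    maxfev_per_level: int = 600


def _pyramid_level(vox: np.ndarray, mask: np.ndarray | None, factor: int):
    if factor == 1:
        return np.asarray(vox, dtype=np.float32), mask
    sm = ndimage.gaussian_filter(np.asarray(vox, dtype=np.float32), sigma=factor / 2.0)
    sub = sm[::factor, ::factor, ::factor]
    msub = None if mask is None else mask[::factor, ::factor, ::factor]
    return sub, msub


def _level_affine(affine: np.ndarray, factor: int) -> np.ndarray:
    out = affine.copy()
    out[:3, :3] = affine[:3, :3] * factor
    return out


def _rigid_from_params(p: np.ndarray, center: np.ndarray) -> RigidTransform:
    return RigidTransform(p[:3], p[3:], center=center)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    fixed_mask: np.ndarray | None = None,
    config: RigidConfig | None = None,
) -> RigidTransform:
    """Estimate the 6-parameter rigid transform maximizing masked NCC.

    The returned transform is the pull-back map (fixed world -> moving
    world): ``resample(moving, transform, fixed)`` aligns the moving image
    onto the fixed grid.  Optimization is 3-level multi-resolution
    derivative-free (Powell) within parameter bounds; a solution pinned to
    the bounds raises.  The identity is always a candidate, so the accepted
    NCC is never below the unaligned NCC.
    """
    config = config or RigidConfig()
    center = fixed.center_world()
    mov_inv = np.linalg.inv(moving.affine)
    mov_vox_levels = {}

    def objective_factory(level: int):
        fvox, fmask = _pyramid_level(np.asarray(fixed.voxels), fixed_mask, level)
        if level not in mov_vox_levels:
            mov_vox_levels[level] = _pyramid_level(np.asarray(moving.voxels), None, level)[0]
        mvox = mov_vox_levels[level]
        laff = _level_affine(fixed.affine, level)
        if fmask is None:
            sel = np.ones(fvox.shape, dtype=bool)
        else:
            sel = fmask.astype(bool)
        idx = np.argwhere(sel)
        if idx.shape[0] > config.max_points:
            stride = int(np.ceil(idx.shape[0] / config.max_points))
            idx = idx[::stride]
        pts = idx @ laff[:3, :3].T + laff[:3, 3]
        fvals = fvox[tuple(idx.T)].astype(np.float64)
        fvals = fvals - fvals.mean()
        fnorm = np.sqrt(fvals @ fvals)
        minv = np.linalg.inv(_level_affine(moving.affine, level))

        scales = np.array([config.bound_deg] * 3 + [config.bound_mm] * 3)

        def neg_ncc(p: np.ndarray) -> float:
            # soft quadratic wall outside the bounds keeps Powell's
            # unconstrained line searches from settling in far-away basins
            excess = np.maximum(np.abs(p) - scales, 0.0) / scales
            wall = 10.0 * float(excess @ excess)
            T = _rigid_from_params(p, center)
            src = T.map_points(pts)
            midx = src @ minv[:3, :3].T + minv[:3, 3]
            mv = ndimage.map_coordinates(mvox, midx.T, order=1, mode="constant", cval=0.0)
            mv = mv - mv.mean()
            denom = fnorm * np.sqrt(mv @ mv)
            if denom == 0:
                return wall
            return wall - float((fvals @ mv) / denom)

        return neg_ncc

    bounds = [(-config.bound_deg, config.bound_deg)] * 3 + [(-config.bound_mm, config.bound_mm)] * 3
    p = np.zeros(6)
    for level in config.levels:
        f = objective_factory(level)
        res = optimize.minimize(
            f,
            p,
            method="Powell",
            options={
                "xtol": config.xtol if level == 1 else 10 * config.xtol,
                "ftol": 1e-9,
                "maxfev": config.maxfev_per_level,
            },
        )
        p = np.asarray(res.x)
    # the search itself is unconstrained (Powell line searches degrade badly
    # under box constraints); a solution outside the configured bounds is an
    # alignment failure and is rejected rather than clipped
    for v, (lo, hi) in zip(p, bounds):
        if v <= lo or v >= hi:
            raise RuntimeError(
                f"rigid optimization left the parameter bounds (±{config.bound_deg} deg, "
                f"±{config.bound_mm} mm): params={np.round(p, 4).tolist()}"
            )
    fine = objective_factory(1)
    if fine(p) > fine(np.zeros(6)):
        p = np.zeros(6)  # never accept a solution worse than no alignment
    return _rigid_from_params(p, center)


# ---------------------------------------------------------------------------
# B-spline warp estimation
# ---------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = 2.0 / 3.0 - t[m1] ** 2 + 0.5 * t[m1] ** 3
    out[m2] = ((2.0 - t[m2]) ** 3) / 6.0
    return out


@dataclass
class WarpConfig:
    """B-spline warp estimation settings."""

    grid_spacing_mm: float = 0.5
    reg_weight: float = 0.01
    displacement_cap_mm: float = 1.0
    levels: tuple[int, ...] = (2, 1)
    maxiter_per_level: tuple[int, ...] = (200, 25)
    grad_norm: bool = True  # equalize voxel conditioning by 1/|grad F|


@dataclass
class _ControlGrid:
    origin: np.ndarray  # world mm of control point (0,0,0)
    spacing: float
    shape: tuple[int, int, int]

    def basis_1d(self, coords: np.ndarray, axis: int) -> np.ndarray:
        """Dense basis matrix B[i, m] = beta3((x_i - p_m)/spacing)."""
        p = self.origin[axis] + self.spacing * np.arange(self.shape[axis])
        return _bspline3((coords[:, None] - p[None, :]) / self.spacing)


def _make_control_grid(fixed: VolumeImage, spacing: float) -> _ControlGrid:
    lo = fixed.index_to_world(np.zeros(3))
    hi = fixed.index_to_world(np.asarray(fixed.shape, dtype=float) - 1.0)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    n = np.ceil((hi - lo) / spacing).astype(int) + 4
    origin = lo - 1.5 * spacing
    return _ControlGrid(origin=origin, spacing=spacing, shape=tuple(int(v) for v in n))


def _bending_energy_and_grad(c: np.ndarray, spacing: float) -> tuple[float, np.ndarray]:
    """Second-difference bending penalty on the control lattice (per point)."""
    energy = 0.0
    grad = np.zeros_like(c)
    n = c[..., 0].size
    for ax in range(3):
        if c.shape[ax] < 3:
            continue
        d2 = np.diff(c, n=2, axis=ax)
        energy += 0.5 * float((d2**2).sum())
        # adjoint of the second difference
        g = np.zeros_like(c)
        sl = [slice(None)] * 4
        for off, w in ((0, 1.0), (1, -2.0), (2, 1.0)):
            sl[ax] = slice(off, c.shape[ax] - 2 + off)
            g[tuple(sl)] += w * d2
        grad += g
    return energy / (n * spacing**2), grad / (n * spacing**2)


def estimate_warp(
    pre_img: VolumeImage,
    mdt: VolumeImage,
    mask: np.ndarray | None = None,
    config: WarpConfig | None = None,
    grid_spacing_mm: float | None = None,
    reg_weight: float | None = None,
) -> WarpTransform:
    """Estimate a cubic-B-spline warp aligning ``pre_img`` (already rigidly
    aligned) to the MDT.

    Control-point displacements are optimized by L-BFGS-B on masked SSD
    (normalized by the fixed image's in-mask variance) plus
    ``reg_weight`` x a bending-energy penalty, over a multi-resolution
    pyramid; control displacements are box-bounded by the displacement cap,
    which bounds the dense field through the B-spline partition of unity.
    Raises if the data cost increases across consecutive resolution levels
    (divergence guard).
    """
    config = config or WarpConfig()
    if grid_spacing_mm is not None:
        config = WarpConfig(**{**config.__dict__, "grid_spacing_mm": grid_spacing_mm})
    if reg_weight is not None:
        config = WarpConfig(**{**config.__dict__, "reg_weight": reg_weight})
    grid = _make_control_grid(mdt, config.grid_spacing_mm)
    c = np.zeros((*grid.shape, 3))
    mov_fullres = np.asarray(pre_img.voxels, dtype=np.float32)
    level_costs = []
    for level, maxiter in zip(config.levels, config.maxiter_per_level):
        fvox, fmask = _pyramid_level(np.asarray(mdt.voxels), mask, level)
        mvox, _ = _pyramid_level(mov_fullres, None, level)
        laff = _level_affine(mdt.affine, level)
        maff_inv = np.linalg.inv(_level_affine(pre_img.affine, level))
        sel = np.ones(fvox.shape, dtype=bool) if fmask is None else fmask.astype(bool)
        nx, ny, nz = fvox.shape
        # world coordinates along each axis (axis-aligned grids in this
        # pipeline; general affines go through the resample() path instead)
        ii = np.arange(nx) * laff[0, 0] + laff[0, 3]
        jj = np.arange(ny) * laff[1, 1] + laff[1, 3]
        kk = np.arange(nz) * laff[2, 2] + laff[2, 3]
        Bx = grid.basis_1d(ii, 0)
        By = grid.basis_1d(jj, 1)
        Bz = grid.basis_1d(kk, 2)
        world = np.stack(np.meshgrid(ii, jj, kk, indexing="ij"), axis=-1)
        fsel = fvox[sel].astype(np.float64)
        var_f = max(float(fsel.var()), 1e-12)
        nmask = max(int(sel.sum()), 1)
        # cubic-spline coefficients once per level: a C2 interpolant whose
        # finite-difference gradient is consistent with the sampled cost
        # (a linear interpolant's cell-wise slopes would stall L-BFGS)
        mcoef = ndimage.spline_filter(mvox.astype(np.float64), order=3, mode="constant")
        # cost and gradient are evaluated at in-mask voxels only
        sel_idx = np.nonzero(sel)
        world_sel = world[sel]
        # gradient-magnitude normalisation: residuals are scaled by
        # 1/sqrt(|grad F|^2 + g0^2), so every voxel contributes a term of the
        # order of its *displacement* error.  Without it the brain-edge
        # gradient (an order of magnitude above interior texture) dominates
        # the cost and the interior never converges.
        if config.grad_norm:
            fgrad = np.stack(np.gradient(fvox.astype(np.float64)), axis=-1)
            gmag = np.linalg.norm(fgrad, axis=-1)[sel] / float(np.mean(np.abs(np.diag(laff[:3, :3]))))
            g0 = max(float(np.median(gmag)), 1e-6)
            wsel = 1.0 / np.sqrt(gmag**2 + g0**2)
            wsel *= np.sqrt(nmask / float((wsel**2 * (fsel - fsel.mean()) ** 2).sum() / var_f))
            w2 = wsel**2
        else:
            w2 = np.ones(nmask)

        def _sample(coords: np.ndarray) -> np.ndarray:
            return ndimage.map_coordinates(
                mcoef, coords, order=3, mode="constant", cval=0.0, prefilter=False
            )

        h = 0.5  # voxels; FD step through the interpolator

        def cost_grad(cflat: np.ndarray):
            cc = cflat.reshape(*grid.shape, 3)
            u = np.einsum("im,jn,kp,mnpd->ijkd", Bx, By, Bz, cc, optimize=True)
            pos = world_sel + u[sel]
            midx = pos @ maff_inv[:3, :3].T + maff_inv[:3, 3]
            coords = midx.T
            mw = _sample(coords)
            r = mw - fsel
            cost_data = 0.5 * float((w2 * r) @ r) / (nmask * var_f)
            # chain rule: d cost / d u_world = r/(N var) * dM/dworld(pos)
            gidx = np.empty((3, coords.shape[1]))
            for d in range(3):
                step = np.zeros((3, 1))
                step[d] = h
                gidx[d] = (_sample(coords + step) - _sample(coords - step)) / (2 * h)
            # index-space gradient -> world-space via the inverse affine
            gworld = gidx.T @ maff_inv[:3, :3]
            G = np.zeros((*fvox.shape, 3))
            G[sel_idx] = gworld * ((w2 * r) / (nmask * var_f))[:, None]
            gc = np.einsum("im,jn,kp,ijkd->mnpd", Bx, By, Bz, G, optimize=True)
            e_bend, g_bend = _bending_energy_and_grad(cc, config.grid_spacing_mm)
            cost = cost_data + config.reg_weight * e_bend
            grad = gc + config.reg_weight * g_bend
            return cost, grad.ravel()

        bounds = [(-config.displacement_cap_mm, config.displacement_cap_mm)] * c.size
        res = optimize.minimize(
            cost_grad,
            c.ravel(),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-9},
        )
        c = res.x.reshape(*grid.shape, 3)
        level_costs.append(float(res.fun))
        if len(level_costs) >= 4 and all(
            level_costs[i] > level_costs[i - 1] for i in range(len(level_costs) - 3, len(level_costs))
        ):
            raise RuntimeError("warp estimation diverged: cost increased over 3 consecutive levels")

    # dense displacement on the fixed grid at full resolution
    ii = np.arange(mdt.shape[0]) * mdt.affine[0, 0] + mdt.affine[0, 3]
    jj = np.arange(mdt.shape[1]) * mdt.affine[1, 1] + mdt.affine[1, 3]
    kk = np.arange(mdt.shape[2]) * mdt.affine[2, 2] + mdt.affine[2, 3]
    Bx = grid.basis_1d(ii, 0)
    By = grid.basis_1d(jj, 1)
    Bz = grid.basis_1d(kk, 2)
    dense = np.einsum("im,jn,kp,mnpd->ijkd", Bx, By, Bz, c, optimize=True)
    return WarpTransform(
        displacement_mm=dense,
        affine=mdt.affine.copy(),
        control_points=c,
        control_spacing_mm=config.grid_spacing_mm,
    )


# ---------------------------------------------------------------------------
# MDT construction and propagation
# ---------------------------------------------------------------------------

@dataclass
class MDTResult:
    """Minimum deformation template plus per-subject transform chains."""

    mdt: VolumeImage
    rigid_transforms: list  # pull-back rigid per input (native -> pass-2 target)
    warp_transforms: list  # WarpTransform per input (or None)
    reference_index: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def chain(self, i: int) -> Transform:
        """Concatenated pull-back transform for input ``i`` (one resampling)."""
        rigid = self.rigid_transforms[i]
        warp = self.warp_transforms[i]
        if warp is None:
            return rigid
        return ComposedTransform([rigid, warp])


def build_mdt(
    pre_images: list[VolumeImage],
    seed: int,
    rigid_config: RigidConfig | None = None,
    warp_config: WarpConfig | None = None,
    with_warp: bool = True,
    diagnostic_fwhm_mm: float = 0.3,
) -> MDTResult:
    """Two-pass minimum deformation template.

    Pass 1: a reference is drawn by seeded random choice, every image is
    rigid-aligned to it, and the aligned images are voxel-averaged.  Pass 2:
    every image is re-aligned (rigid, then B-spline warp) to the pass-1
    average and averaged again, giving the final MDT.  Inputs must already be
    masked, bias-corrected, and modally scaled.  Convergence diagnostics
    report the mean pairwise NCC of the pass-2 aligned images at the
    pipeline's analysis smoothing scale.
    """
    if len(pre_images) < 2:
        raise ValueError("build_mdt needs at least 2 pre-injection images")
    rng = np.random.default_rng(seed)
    ref_idx = int(rng.integers(len(pre_images)))
    ref = pre_images[ref_idx]
    ref_mask = compute_brain_mask(ref).data

    aligned1 = []
    for i, img in enumerate(pre_images):
        if i == ref_idx:
            aligned1.append(np.asarray(img.voxels, dtype=np.float64))
            continue
        t = register_rigid(img, ref, fixed_mask=ref_mask, config=rigid_config)
        aligned1.append(np.asarray(resample(img, t, ref).voxels, dtype=np.float64))
    avg1 = VolumeImage(np.mean(aligned1, axis=0).astype(np.float32), ref.affine.copy())
    avg1_mask = compute_brain_mask(avg1).data

    rigids, warps, aligned2 = [], [], []
    for img in pre_images:
        t = register_rigid(img, avg1, fixed_mask=avg1_mask, config=rigid_config)
        rigids.append(t)
        if with_warp:
            moved = resample(img, t, avg1)
            w = estimate_warp(moved, avg1, mask=avg1_mask, config=warp_config)
            warps.append(w)
            chain = ComposedTransform([t, w])
        else:
            warps.append(None)
            chain = t
        aligned2.append(np.asarray(resample(img, chain, avg1).voxels, dtype=np.float64))
    mdt = VolumeImage(np.mean(aligned2, axis=0).astype(np.float32), avg1.affine.copy())

    mdt_for_diag = VolumeImage(mdt.voxels, mdt.affine)
    mask_img = BrainMask(avg1_mask, avg1.affine)
    smoothed = [
        smooth_gaussian(VolumeImage(a.astype(np.float32), avg1.affine), diagnostic_fwhm_mm, mask=mask_img).voxels
        for a in aligned2
    ]
    pairs = [
        ncc(a, b, avg1_mask) for a, b in combinations(smoothed, 2)
    ] or [1.0]
    diagnostics = {
        "mean_pairwise_ncc": float(np.mean(pairs)),
        "min_pairwise_ncc": float(np.min(pairs)),
        "diagnostic_fwhm_mm": diagnostic_fwhm_mm,
        "reference_index": ref_idx,
    }
    return MDTResult(
        mdt=mdt_for_diag,
        rigid_transforms=rigids,
        warp_transforms=warps,
        reference_index=ref_idx,
        seed=seed,
        diagnostics=diagnostics,
    )


def propagate_to_timepoints(
    chain: Transform, sessions: list[VolumeImage], target: VolumeImage
) -> list[VolumeImage]:
    """Apply one subject's pre-injection transform chain, unchanged, to all of
    that subject's sessions (two-step propagation).

    Every session must live on the subject's native grid; registration is
    never re-estimated on Mn(II)-enhanced images, so the applied transform is
    invariant to the post-injection image content.
    """
    if not sessions:
        return []
    aff0, shape0 = sessions[0].affine, sessions[0].shape
    for s in sessions[1:]:
        if s.shape != shape0 or not np.allclose(s.affine, aff0):
            raise ValueError("sessions of one subject must share the native grid")
    return [resample(s, chain, target) for s in sessions]


def smooth_gaussian(
    img: VolumeImage, fwhm_mm: float = 0.3, mask: BrainMask | None = None
) -> VolumeImage:
    """Isotropic Gaussian smoothing specified by FWHM in mm, mask-renormalized.

    sigma per axis is (fwhm / voxel size) / (2 sqrt(2 ln 2)) voxels.  With a
    mask, ``smooth(img*mask)/smooth(mask)`` is used inside the mask so
    brain-edge voxels are not dimmed by zero background; a constant image is
    exactly preserved inside the mask.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return img.like(np.asarray(img.voxels).copy())
    sigma_vox = (fwhm_mm / img.voxel_mm) * FWHM_TO_SIGMA
    vox = np.asarray(img.voxels, dtype=np.float64)
    if mask is None:
        return img.like(ndimage.gaussian_filter(vox, sigma=sigma_vox).astype(np.float32))
    m = mask.data.astype(np.float64)
    num = ndimage.gaussian_filter(vox * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox)
    out = np.zeros_like(vox)
    inside = mask.data
    out[inside] = num[inside] / den[inside]
    return img.like(out.astype(np.float32))
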