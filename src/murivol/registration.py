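"""Simplified intensity-based registration.

A small, self-contained stand-in for the production-grade tools used in
multi-atlas pipelines (block-matching affine + velocity-field non-rigid):

* :func:`register_affine` — multi-resolution Powell search over translation /
  rotation / log-scale maximizing normalized mutual information (NMI).
* :func:`register_nonrigid` — cubic-B-spline free-form deformation whose
  control displacements ascend an analytic NMI gradient (linear Parzen window
  in the moving intensity), with Gaussian smoothing of the update as the
  regularizer and a backtracking line search on the true NMI.

Both are pluggable: anything producing an :class:`~murivol.images.AffineTransform`
or :class:`~murivol.images.DeformationField` can replace them downstream.

Transforms follow the pull-back convention internally (fixed world -> moving
world); the affine returned by :func:`register_affine` is the moving -> fixed
map, so its inverse is what warps the moving image onto the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .images import AffineTransform, DeformationField, LabeledImage

__all__ = [
    "RegistrationError",
    "AffineConfig",
    "NonrigidConfig",
    "nmi",
    "register_affine",
    "register_nonrigid",
    "warp_image",
]


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# similarity


def _bin_index(v: np.ndarray, bins: int) -> np.ndarray:
    lo = v.min()
    scale = bins / (v.max() - lo + 1e-12)
    return np.minimum((v - lo) * scale, bins - 1).astype(np.int64)


def _entropy(x: np.ndarray) -> float:
    x = x[x > 0]
    return float(-np.sum(x * np.log(x)))


def nmi(fixed: np.ndarray, moving: np.ndarray, mask: np.ndarray | None = None,
        bins: int = 32) -> float:
    """Normalized mutual information (H(F) + H(M)) / H(F, M) in [1, 2]."""
    if mask is not None:
        if not mask.any():
            raise RegistrationError("no overlapping voxels to evaluate similarity")
        fixed, moving = fixed[mask], moving[mask]
    jf = _bin_index(np.asarray(fixed).ravel(), bins)
    jm = _bin_index(np.asarray(moving).ravel(), bins)
    h = np.bincount(jf * bins + jm, minlength=bins * bins).reshape(bins, bins)
    p = h / h.sum()
    hf, hm, hfm = _entropy(p.sum(axis=1)), _entropy(p.sum(axis=0)), _entropy(p.ravel())
    if hfm == 0:
        return 2.0
    return (hf + hm) / hfm


# ---------------------------------------------------------------------------
# warping


def _world_to_index(img: LabeledImage, world: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(img.affine)
    return world @ inv[:3, :3].T + inv[:3, 3]


def _fixed_world_grid(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def warp_image(moving: LabeledImage, pullback, grid_like: LabeledImage,
               order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``moving`` onto ``grid_like``'s grid through a pull-back map.

    ``pullback`` maps fixed world points to moving world points: either an
    :class:`AffineTransform` (interpreted as that map directly) or a
    :class:`DeformationField`.
    """
    if isinstance(pullback, AffineTransform):
        # single index->index affine: C-speed resampling path
        comp = np.linalg.inv(moving.affine) @ pullback.matrix @ grid_like.affine
        return ndimage.affine_transform(
            moving.data, comp[:3, :3], offset=comp[:3, 3],
            output_shape=grid_like.shape, order=order, mode="constant", cval=cval,
            prefilter=(order > 1))
    if isinstance(pullback, DeformationField):
        same_grid = (pullback.shape == grid_like.shape
                     and np.allclose(pullback.grid_affine, grid_like.affine))
        shape = grid_like.shape
        out = np.empty(shape, dtype=moving.data.dtype)
        src = moving.data if order <= 1 else ndimage.spline_filter(moving.data,
                                                                   order=order)
        # slab-chunked to bound peak memory on large grids
        slab = max(1, int(4e6 // (shape[1] * shape[2])))
        for i0 in range(0, shape[0], slab):
            i1 = min(i0 + slab, shape[0])
            idx = np.indices((i1 - i0,) + shape[1:]).reshape(3, -1).T.astype(float)
            idx[:, 0] += i0
            world = idx @ grid_like.affine[:3, :3].T + grid_like.affine[:3, 3]
            if same_grid:
                disp = pullback.displacement[i0:i1].reshape(-1, 3)
            else:
                disp = pullback.displacement_at(world)
            mapped = pullback.affine.apply(world) + disp
            coords = _world_to_index(moving, mapped).T
            out[i0:i1] = ndimage.map_coordinates(
                src, coords, order=order, mode="constant", cval=cval,
                prefilter=False).reshape((i1 - i0,) + shape[1:])
        return out
    raise TypeError(f"unsupported transform type {type(pullback)!r}")


def _shrink(img: LabeledImage, factor: int) -> LabeledImage:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img.data, sigma=0.5 * factor)
    data = sm[::factor, ::factor, ::factor]
    aff = img.affine.copy()
    aff[:3, :3] *= factor
    return LabeledImage(data, tuple(s * factor for s in img.spacing), aff)


# ---------------------------------------------------------------------------
# affine registration


@dataclass(frozen=True)
class AffineConfig:
    levels: tuple[int, ...] = (4, 2)      # shrink factors, coarse to fine
    maxiter: tuple[int, ...] = (2, 2)     # Powell outer iterations per level
    bins: int = 32
    model: str = "trs"                    # t | ts | tr | trs: translation/scale/rotation
    init_align_centers: bool = True


def _params_to_matrix(params: np.ndarray, center: np.ndarray,
                      model: str = "trs") -> np.ndarray:
    t = params[0:3]
    if model == "t":
        r, s = np.zeros(3), np.ones(3)
    elif model == "ts":
        r, s = np.zeros(3), np.exp(params[3:6])
    elif model == "tr":
        r, s = params[3:6], np.ones(3)
    else:
        r, s = params[3:6], np.exp(params[6:9])
    cx, cy, cz = np.cos(r)
    sx, sy, sz = np.sin(r)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    lin = rz @ ry @ rx @ np.diag(s)
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = t + center - lin @ center
    return mat


def _nparams(model: str) -> int:
    return {"t": 3, "ts": 6, "tr": 6, "trs": 9}[model]


def register_affine(fixed: LabeledImage, moving: LabeledImage,
                    config: AffineConfig | None = None) -> AffineTransform:
    """Affine registration maximizing NMI.

    Returns the moving -> fixed world map; apply its inverse as the pull-back
    when resampling the moving image or propagating its labels.
    """
    if fixed.data.ndim != 3 or moving.data.ndim != 3:
        raise ValueError("both images must be 3-D")
    config = config or AffineConfig()
    n = _nparams(config.model)
    params = np.zeros(n)
    center = (np.asarray(fixed.shape) / 2.0) @ fixed.affine[:3, :3].T + fixed.affine[:3, 3]
    # initialize translation from intensity centroids (helps non-overlap)
    if config.init_align_centers:
        def centroid(img):
            d = img.data - img.data.min()
            tot = d.sum()
            if tot <= 0:
                return (np.asarray(img.shape) / 2.0) @ img.affine[:3, :3].T + img.affine[:3, 3]
            idx = np.array(ndimage.center_of_mass(d))
            return idx @ img.affine[:3, :3].T + img.affine[:3, 3]
        params[0:3] = centroid(moving) - centroid(fixed)

    for level, it in zip(config.levels, config.maxiter):
        f = _shrink(fixed, level)
        m = _shrink(moving, level)
        vox = min(f.spacing)

        def neg_nmi(p):
            mat = _params_to_matrix(p * scale, center, config.model)
            warped = warp_image(m, AffineTransform(mat), f, order=1,
                                cval=float(m.data.min()))
            return -nmi(f.data, warped, bins=config.bins)

        # scale params so Powell's unit steps are ~0.5 voxel / small angles
        scale = np.ones(n)
        scale[0:3] = 0.5 * vox
        if config.model == "ts":
            scale[3:6] = 0.01
        elif n >= 6:
            scale[3:6] = 0.02
        if n >= 9:
            scale[6:9] = 0.01
        res = minimize(neg_nmi, params / scale, method="Powell",
                       options={"maxiter": it, "xtol": 1e-3, "ftol": 1e-7})
        params = res.x * scale
        if not np.isfinite(res.fun):
            raise RegistrationError("affine registration diverged (non-finite NMI)")
    pullback = _params_to_matrix(params, center, config.model)
    return AffineTransform(np.linalg.inv(pullback))


# ---------------------------------------------------------------------------
# non-rigid registration


@dataclass(frozen=True)
class NonrigidConfig:
    control_spacing: tuple[int, int, int] = (4, 4, 4)  # voxels, >= 2
    maxiter: int = 30
    bins: int = 32
    shrink: int = 1
    smooth_sigma: float = 1.0   # control-grid units, regularizes the update
    step_mm: float = 0.2        # initial line-search step (mm, at the p95 gradient)
    max_step_mm: float = 0.5
    min_step_mm: float = 0.002


def _bspline_upsample(control: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Cubic-spline interpolation of a (cx, cy, cz, 3) control grid to a dense
    (nx, ny, nz, 3) displacement."""
    out = np.empty(shape + (3,))
    zoom = [shape[d] / control.shape[d] for d in range(3)]
    for c in range(3):
        out[..., c] = ndimage.zoom(control[..., c], zoom, order=3, mode="nearest",
                                   grid_mode=True, prefilter=True)
    return out


def _nmi_force(fixed: np.ndarray, warped: np.ndarray, bins: int):
    """Per-voxel d(NMI)/d(moving intensity), linear Parzen window in moving."""
    fv = fixed
    f_edges = np.linspace(fv.min(), fv.max() + 1e-9, bins + 1)
    m_lo, m_hi = warped.min(), warped.max() + 1e-9
    m_edges = np.linspace(m_lo, m_hi, bins + 1)
    dm = m_edges[1] - m_edges[0]
    jf = np.clip(np.digitize(fv, f_edges) - 1, 0, bins - 1)
    # fractional moving-bin coordinate
    mc = np.clip((warped - m_lo) / dm - 0.5, 0.0, bins - 1.0 - 1e-9)
    k0 = np.floor(mc).astype(np.int64)
    w = mc - k0
    n = fv.size
    h = np.zeros((bins, bins))
    np.add.at(h, (jf.ravel(), k0.ravel()), (1.0 - w).ravel())
    np.add.at(h, (jf.ravel(), np.minimum(k0 + 1, bins - 1).ravel()), w.ravel())
    p = h / n
    pm = p.sum(axis=0)
    pf = p.sum(axis=1)
    def H(x):
        x = x[x > 0]
        return -np.sum(x * np.log(x))
    hf, hm, hfm = H(pf), H(pm), H(p.ravel())
    if hfm <= 0:
        return np.zeros_like(warped), 2.0
    eps = 1e-12
    dHm = -(np.log(pm + eps) + 1.0)          # (bins,)
    dHfm = -(np.log(p + eps) + 1.0)          # (bins, bins)
    g = (dHm[None, :] * hfm - (hf + hm) * dHfm) / hfm ** 2  # dNMI/dp_jk
    # voxel-wise derivative via the two Parzen weights
    gk0 = g[jf.ravel(), k0.ravel()]
    gk1 = g[jf.ravel(), np.minimum(k0 + 1, bins - 1).ravel()]
    dv = ((gk1 - gk0) / (dm * n)).reshape(warped.shape)
    return dv, (hf + hm) / hfm


def register_nonrigid(fixed: LabeledImage, moving: LabeledImage,
                      init: AffineTransform | None = None,
                      config: NonrigidConfig | None = None) -> DeformationField:
    """Free-form-deformation refinement of an affine initialization.

    Gradient ascent on NMI over cubic-B-spline control displacements; each
    candidate update is Gaussian-smoothed on the control grid (smoothness
    regularization) and accepted only if the full-resolution NMI improves.
    ``maxiter=0`` returns the init-only (zero-displacement) field.
    """
    config = config or NonrigidConfig()
    if any(c < 2 for c in config.control_spacing):
        raise ValueError("control-grid spacing must be >= 2 voxels")
    init = init or AffineTransform.identity()
    pull_affine = init.inverse()  # fixed world -> moving world

    f = _shrink(fixed, config.shrink)
    m = moving
    shape = f.shape
    ctrl_shape = tuple(max(int(np.ceil(shape[d] / config.control_spacing[d])) + 1, 4)
                       for d in range(3))
    control = np.zeros(ctrl_shape + (3,))

    def field_from(control):
        # stored on the (possibly shrunk) working grid; consumers interpolate
        disp = _bspline_upsample(control, shape)
        return DeformationField(pull_affine, disp,
                                control_spacing=tuple(config.control_spacing),
                                control_grid=control.copy(),
                                grid_affine=f.affine)

    def warp_on(fgrid, control):
        disp = _bspline_upsample(control, fgrid.shape)
        fld = DeformationField(pull_affine, disp, tuple(config.control_spacing),
                               grid_affine=fgrid.affine)
        return warp_image(m, fld, fgrid, order=1, cval=float(m.data.min()))

    if config.maxiter == 0:
        return field_from(control)

    # monotone gradient ascent: the (smoothed) NMI gradient is normalized by a
    # high percentile so updates stay localized to genuinely mismatched
    # regions, then scaled by a backtracking line search on the true NMI
    warped = warp_on(f, control)
    current = nmi(f.data, warped, bins=config.bins)
    step = config.step_mm
    for _ in range(config.maxiter):
        dv, _ = _nmi_force(f.data, warped, config.bins)
        grad_img = np.array(np.gradient(warped, *f.spacing))
        force = dv[None] * grad_img  # (3, nx, ny, nz): dNMI/d(displacement), mm^-1
        # project voxel forces onto the control grid (B-spline adjoint,
        # approximated by smoothing + sampling) and regularize
        grad_ctrl = np.empty(ctrl_shape + (3,))
        zoom = [ctrl_shape[d] / shape[d] for d in range(3)]
        for c in range(3):
            sm = ndimage.gaussian_filter(force[c], sigma=[s / 2 for s in
                                                          config.control_spacing])
            grad_ctrl[..., c] = ndimage.zoom(sm, zoom, order=1, mode="nearest",
                                             grid_mode=True)
            grad_ctrl[..., c] = ndimage.gaussian_filter(
                grad_ctrl[..., c], sigma=config.smooth_sigma)
        gmag = np.abs(grad_ctrl)
        if not gmag.any():
            break
        gscale = np.percentile(gmag[gmag > 0], 95)
        direction = np.clip(grad_ctrl / gscale, -1.0, 1.0)
        improved = False
        while step >= config.min_step_mm:
            cand = control + direction * step
            wc = warp_on(f, cand)
            val = nmi(f.data, wc, bins=config.bins)
            if val > current + 1e-10:
                control, warped, current = cand, wc, val
                improved = True
                step = min(step * 1.5, config.max_step_mm)
                break
            step *= 0.5
        if not improved:
            break  # converged: no admissible step improves NMI
    return field_from(control)
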