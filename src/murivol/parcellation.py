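"""Multi-atlas segmentation propagation.

The pipeline mirrors the standard multi-atlas recipe: preprocess the target
(optional polynomial bias correction), register every atlas to it (global
affine, then optional non-rigid refinement), propagate the atlas labels with
nearest-neighbour interpolation, rank the warped atlases per voxel by local
normalized cross-correlation against the target, and fuse the top-ranked
candidate labels by majority vote. Utilities for QA mask correction,
hemisphere splitting, volume extraction and spline resampling complete the
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import AffineTransform, DeformationField, LabeledImage, LabelInfo, LabelMap
from .registration import (AffineConfig, NonrigidConfig, register_affine,
                           register_nonrigid, warp_image)

__all__ = [
    "AtlasEntry",
    "ParcellationConfig",
    "correct_bias",
    "propagate_labels",
    "local_ncc",
    "fuse_labels",
    "qa_correct_mask",
    "split_hemispheres",
    "extract_volumes",
    "total_brain_volume",
    "resample_image",
    "parcellate",
]


@dataclass(frozen=True)
class AtlasEntry:
    """One atlas: intensity image + manual-style labels on a shared grid."""

    image: LabeledImage
    labels: LabelMap
    atlas_id: str

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("atlas image and labels must share a grid")


# ---------------------------------------------------------------------------
# preprocessing


def correct_bias(image: LabeledImage, order: int = 2) -> LabeledImage:
    """Divide out a smooth multiplicative bias field (simplified N4 stand-in).

    A degree-``order`` 3-D polynomial is least-squares fitted to the log
    intensities of above-background voxels and divided out; the masked mean
    intensity is preserved. ``order=0`` reduces to a global rescale (identity
    after mean restoration).
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    data = image.data
    if not np.any(data > 0):
        raise ValueError("cannot correct an all-zero image")
    lo, hi = data.min(), data.max()
    mask = data > lo + 0.1 * (hi - lo) if hi > lo else data > 0
    if not mask.any():
        raise ValueError("no above-background voxels to estimate the bias field")
    coords = [np.linspace(-1.0, 1.0, n) for n in image.shape]
    grids = np.meshgrid(*coords, indexing="ij")
    terms = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                terms.append(grids[0] ** i * grids[1] ** j * grids[2] ** k)
    design = np.stack([t[mask] for t in terms], axis=1)
    logv = np.log(np.maximum(data[mask], 1e-12))
    coef, *_ = np.linalg.lstsq(design, logv, rcond=None)
    logfield = np.tensordot(np.stack(terms, axis=-1), coef, axes=1)
    fld = np.exp(logfield - logfield[mask].mean())  # mean-1 field over mask
    corrected = data / fld
    corrected *= data[mask].mean() / corrected[mask].mean()
    return image.with_data(corrected)


def resample_image(image: LabeledImage, target_spacing, order: int = 3) -> LabeledImage:
    """Spline-resample onto an isotropic-or-not target spacing, preserving the
    world extent (field-of-view centers aligned)."""
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    ts = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in ts):
        raise ValueError("target spacing must be > 0")
    if order not in range(6):
        raise ValueError("spline order must be in 0..5")
    ss = image.spacing
    new_shape = tuple(max(int(round(image.shape[d] * ss[d] / ts[d])), 1)
                      for d in range(3))
    # align the centers of the two voxel lattices
    matrix = np.diag([ts[d] / ss[d] for d in range(3)])
    offset = [((ss[d] * (image.shape[d] - 1)) - (ts[d] * (new_shape[d] - 1)))
              / (2.0 * ss[d]) for d in range(3)]
    data = ndimage.affine_transform(image.data, matrix, offset=offset,
                                    output_shape=new_shape, order=order,
                                    mode="nearest", prefilter=(order > 1))
    return LabeledImage(data, ts)


# ---------------------------------------------------------------------------
# propagation and fusion


def propagate_labels(labels: LabelMap, transform, target: LabeledImage) -> LabelMap:
    """Pull atlas labels onto the target grid by nearest-neighbour resampling.

    ``transform`` maps target world coordinates to atlas world coordinates
    (pull-back); voxels mapped outside the atlas become background.
    """
    ldtype = np.float32 if labels.data.size > 4_000_000 else np.float64
    src = LabeledImage(labels.data.astype(ldtype), labels.spacing, labels.affine)
    warped = warp_image(src, transform, target, order=0, cval=0.0)
    out = np.round(warped).astype(np.int32)
    if not out.any() and labels.data.any():
        warnings.warn("propagated labels are all background (target outside atlas)")
    # NN resampling can only produce ids already present in the source
    return LabelMap(out, target.spacing, dict(labels.labels), target.affine)


def _box_sum(arr: np.ndarray, window: int) -> np.ndarray:
    """Sum over the centered cubic window, clipped at the image border."""
    half = window // 2
    out = arr
    for ax in range(3):
        c = np.cumsum(out, axis=ax)
        c = np.concatenate([np.zeros_like(np.take(c, [0], axis=ax)), c], axis=ax)
        n = arr.shape[ax]
        hi = np.minimum(np.arange(n) + half + 1, n)
        lo = np.maximum(np.arange(n) - half, 0)
        out = np.take(c, hi, axis=ax) - np.take(c, lo, axis=ax)
    return out


def local_ncc(fixed: LabeledImage, warped: LabeledImage, window: int = 5) -> np.ndarray:
    """Per-voxel Pearson correlation within a centered cubic window.

    Windows are clipped at the image border; windows in which either image is
    constant score 0, so flat background never outranks informative atlases.
    """
    if fixed.shape != warped.shape:
        raise ValueError("images must share a grid")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > max(fixed.shape):
        raise ValueError("window larger than the image")
    # float32 on big grids keeps peak memory bounded; float64 elsewhere so
    # small-grid results match a double-precision oracle exactly
    dtype = np.float32 if fixed.data.size > 4_000_000 else np.float64
    f = fixed.data.astype(dtype, copy=False)
    w = warped.data.astype(dtype, copy=False)
    n = _box_sum(np.ones(f.shape, dtype=dtype), window)
    sf = _box_sum(f, window)
    sw = _box_sum(w, window)
    sff = _box_sum(f * f, window)
    sww = _box_sum(w * w, window)
    sfw = _box_sum(f * w, window)
    cov = sfw - sf * sw / n
    vf = sff - sf ** 2 / n
    vw = sww - sw ** 2 / n
    tol = 1e-10 * np.maximum(sff.max(), sww.max()) / n.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vf * vw)
    r[(vf <= tol) | (vw <= tol)] = 0.0
    return np.clip(r, -1.0, 1.0)


def fuse_labels(candidates: list[LabelMap], similarities: list[np.ndarray],
                top_k: int | None = None) -> LabelMap:
    """Locally-ranked majority-vote fusion.

    At each voxel the candidates are ranked by their local similarity
    (descending; ties by candidate order) and the ``top_k`` best vote. Ties in
    the vote go to the label whose supporters have the larger summed
    similarity, then to the lowest label id.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate label map")
    if len(candidates) != len(similarities):
        raise ValueError("one similarity map per candidate required")
    shape = candidates[0].shape
    for c in candidates:
        if c.shape != shape:
            raise ValueError("candidate grids differ")
    for s in similarities:
        if np.shape(s) != shape:
            raise ValueError("similarity grid does not match candidates")
    n = len(candidates)
    top_k = int(np.ceil(n / 2)) if top_k is None else int(top_k)
    if not 1 <= top_k <= n:
        raise ValueError(f"top_k must be in 1..{n}")
    big = candidates[0].data.size > 4_000_000
    lab_dtype = np.int16 if (big and max(m for c in candidates
                                         for m in (max(c.labels, default=0),)) < 32767) \
        else np.int32
    lab = np.stack([c.data.astype(lab_dtype, copy=False) for c in candidates])
    sim = np.stack([np.asarray(s, dtype=np.float32 if big else np.float64)
                    for s in similarities])
    order = np.argsort(-sim, axis=0, kind="stable")[:top_k]  # ranks, ties by index
    top_lab = np.take_along_axis(lab, order, axis=0)
    top_sim = np.take_along_axis(sim, order, axis=0)
    values = np.unique(lab)
    best_label = np.full(shape, -1, dtype=np.int32)
    best_count = np.full(shape, -1, dtype=np.int16)
    best_sum = np.full(shape, -np.inf, dtype=sim.dtype)
    for v in values:  # ascending: strict improvement keeps the lowest id on ties
        m = top_lab == v
        cnt = m.sum(axis=0, dtype=np.int16)
        ssum = np.where(m, top_sim, 0.0).sum(axis=0, dtype=sim.dtype)
        better = (cnt > best_count) | ((cnt == best_count) & (ssum > best_sum))
        better &= cnt > 0
        best_label = np.where(better, v, best_label)
        best_count = np.where(better, cnt, best_count)
        best_sum = np.where(better, ssum, best_sum)
    merged: dict[int, LabelInfo] = {}
    for c in candidates:
        merged.update(c.labels)
    out = np.where(best_label < 0, 0, best_label).astype(np.int32)
    keep = {k: v for k, v in merged.items()}
    return LabelMap(out, candidates[0].spacing, keep, candidates[0].affine)


# ---------------------------------------------------------------------------
# QA and bookkeeping


def qa_correct_mask(labels: LabelMap, removal_mask: np.ndarray
                    ) -> tuple[LabelMap, dict[int, int]]:
    """Zero out flagged voxels (e.g. misclassified external CSF at the brain
    edge); returns the corrected map and per-label removal counts."""
    removal_mask = np.asarray(removal_mask, dtype=bool)
    if removal_mask.shape != labels.shape:
        raise ValueError("removal mask grid does not match the label map")
    removed: dict[int, int] = {}
    hit = removal_mask & (labels.data > 0)
    for lid in np.unique(labels.data[hit]):
        removed[int(lid)] = int(np.sum(labels.data[hit] == lid))
    data = labels.data.copy()
    data[removal_mask] = 0
    return labels.with_data(data), removed


def split_hemispheres(labels: LabelMap, axis: int = 0,
                      plane_index: int | None = None) -> LabelMap:
    """Split bilateral labels into left/right twins at a geometric midplane.

    Voxels with index < plane go left. Midline structures are untouched.
    Raises if the map was already split.
    """
    if any(v.hemisphere in ("L", "R") for v in labels.labels.values()):
        raise ValueError("label map is already hemisphere-split")
    plane = labels.shape[axis] // 2 if plane_index is None else int(plane_index)
    idx = np.arange(labels.shape[axis])
    left = (idx < plane).reshape([-1 if a == axis else 1 for a in range(3)])
    out = np.zeros_like(labels.data)
    new_labels: dict[int, LabelInfo] = {}
    next_id = 1
    for lid in sorted(labels.labels):
        info = labels.labels[lid]
        mask = labels.data == lid
        if not info.bilateral:
            new_labels[next_id] = info
            out[mask] = next_id
            next_id += 1
            continue
        for side, side_mask in (("L", mask & left), ("R", mask & ~left)):
            new_labels[next_id] = LabelInfo(f"{info.name}_{side}", info.tissue,
                                            side, bilateral=True)
            out[side_mask] = next_id
            if not side_mask.any():
                warnings.warn(f"bilateral label {info.name!r} has no {side} voxels")
            next_id += 1
    return LabelMap(out, labels.spacing, new_labels, labels.affine)


def extract_volumes(labels: LabelMap) -> pd.DataFrame:
    """Per-label voxel counts and volumes (mm^3).

    The sum of all structure volumes equals the brain-mask volume exactly
    (the mask is the union of labels); it is stored in
    ``df.attrs['total_brain_volume_mm3']``.
    """
    voxvol = labels.voxel_volume
    counts = np.bincount(labels.data.ravel(), minlength=max(labels.labels, default=0) + 1)
    rows = []
    for lid in sorted(labels.labels):
        info = labels.labels[lid]
        n = int(counts[lid]) if lid < counts.size else 0
        rows.append({"label_id": lid, "structure": info.name, "tissue": info.tissue,
                     "hemisphere": info.hemisphere, "n_voxels": n,
                     "volume_mm3": n * voxvol, "empty": n == 0})
    df = pd.DataFrame(rows)
    df.attrs["total_brain_volume_mm3"] = float(df["volume_mm3"].sum()) if rows else 0.0
    return df


def total_brain_volume(df: pd.DataFrame) -> float:
    """Total brain volume: sum of all parcellated structures (ventricles included)."""
    return float(df["volume_mm3"].sum())


# ---------------------------------------------------------------------------
# the full multi-atlas stage


@dataclass(frozen=True)
class ParcellationConfig:
    affine: AffineConfig = field(default_factory=AffineConfig)
    nonrigid: NonrigidConfig | None = field(default_factory=NonrigidConfig)
    ncc_window: int = 5
    top_k: int | None = None          # default ceil(n_atlases / 2)
    bias_order: int | None = None     # None: skip bias correction


def parcellate(target: LabeledImage, atlases: list[AtlasEntry],
               config: ParcellationConfig | None = None) -> LabelMap:
    """Multi-atlas parcellation of one target image."""
    if len(atlases) == 0:
        raise ValueError("need at least one atlas")
    config = config or ParcellationConfig()
    img = target
    if config.bias_order is not None:
        img = correct_bias(img, config.bias_order)
    candidates, sims = [], []
    for atlas in atlases:
        aff = register_affine(img, atlas.image, config.affine)
        if config.nonrigid is not None:
            transform = register_nonrigid(img, atlas.image, aff, config.nonrigid)
        else:
            transform = aff.inverse()
        warped = img.with_data(warp_image(atlas.image, transform, img, order=1,
                                          cval=float(atlas.image.data.min())))
        sims.append(local_ncc(img, warped, config.ncc_window))
        del warped
        candidates.append(propagate_labels(atlas.labels, transform, img))
    return fuse_labels(candidates, sims, config.top_k)
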