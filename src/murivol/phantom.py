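"""Labeled 3-D phantom rendering.

Subjects are rendered as a fixed template layout of non-overlapping ellipsoids
inside a cubic field of view: per-subject anatomy differs only through the
requested per-structure volumes (and an optional global linear scale emulating
gradient drift). Bilateral structures appear as mirror-image ellipsoid pairs
about the mid-sagittal plane and share one (unsplit) label.

Volume accuracy: for each structure the renderer evaluates a supersampled
occupancy fraction per voxel and assigns exactly ``round(V / voxel_volume)``
voxels, chosen by descending occupancy (ties broken by the ellipsoid quadratic
form), so the rendered volume is within half a voxel of the request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortSpec, ModalityParams, StructureDef, SubjectTrajectory
from .images import LabeledImage, LabelInfo, LabelMap

__all__ = [
    "GeometryError",
    "PhantomPair",
    "TEMPLATE_LAYOUT",
    "render_phantom",
    "render_pair",
    "make_atlases",
]


class GeometryError(RuntimeError):
    """Requested volumes cannot be placed on the grid."""


# name -> (lateral offset, y, z, axis ratios); positions are fractions of the
# field of view, lateral offset is from the mid-sagittal plane (x = 0.5).
# Midline structures have offset 0 and a single ellipsoid.
# Solved so that worst-case study volumes (wild-type growth, ventricular
# expansion, white-matter swelling, atlas jitter) keep every ellipsoid pair
# >= 0.4 mm apart inside a 11.7 mm field of view.
TEMPLATE_LAYOUT: dict[str, tuple[float, float, float, tuple[float, float, float]]] = {
    "neocortex":           (0.2806, 0.6723, 0.6338, (0.80, 1.30, 1.00)),
    "cerebellum":          (0.0000, 0.5290, 0.2722, (1.30, 0.75, 1.00)),
    "thalamus":            (0.3169, 0.2724, 0.3393, (0.85, 1.10, 1.00)),
    "olfactory_bulb":      (0.1293, 0.3036, 0.8190, (0.80, 1.20, 1.00)),
    "hippocampus":         (0.2645, 0.7931, 0.1687, (0.90, 1.20, 0.90)),
    "caudate_putamen":     (0.3414, 0.1900, 0.6639, (0.90, 1.10, 1.00)),
    "hypothalamus":        (0.1316, 0.1793, 0.1341, (1.00, 1.20, 0.80)),
    "internal_capsule":    (0.3733, 0.4925, 0.1270, (0.80, 1.40, 0.80)),
    "ventricles":          (0.0937, 0.2170, 0.5342, (0.70, 1.60, 0.90)),
    "fimbria":             (0.3789, 0.6237, 0.3280, (0.80, 1.50, 0.70)),
    "anterior_commissure": (0.0000, 0.1375, 0.3445, (1.60, 0.70, 0.70)),
}


@dataclass(frozen=True)
class PhantomPair:
    """Coarse "in vivo" and fine "ex vivo" renderings of one subject."""

    invivo_image: LabeledImage
    invivo_labels: LabelMap
    exvivo_image: LabeledImage
    exvivo_labels: LabelMap
    subject_id: str
    timepoint: float
    seed: int


def _occupancy(shape, spacing, center_mm, semi_mm, supersample=2):
    """Supersampled in-ellipsoid occupancy fraction over a bounding box.

    Returns (slices, occ, q) where ``q`` is the quadratic form at voxel
    centers (1 on the nominal surface).
    """
    lo, hi = [], []
    for d in range(3):
        a = int(np.floor((center_mm[d] - 1.4 * semi_mm[d]) / spacing - 0.5))
        b = int(np.ceil((center_mm[d] + 1.4 * semi_mm[d]) / spacing + 0.5))
        lo.append(max(a, 0))
        hi.append(min(b + 1, shape[d]))
    if any(h <= l for l, h in zip(lo, hi)):
        raise GeometryError("structure bounding box falls outside the grid")
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    s = supersample
    # voxel center of index i is (i + 0.5) * spacing; subsample offsets
    offs = (np.arange(s) + 0.5) / s - 0.5
    axes_sub = []
    axes_ctr = []
    for d in range(3):
        idx = np.arange(lo[d], hi[d])
        ctr = (idx + 0.5) * spacing
        sub = (ctr[:, None] + offs[None, :] * spacing - center_mm[d]) / semi_mm[d]
        axes_sub.append(sub)
        axes_ctr.append((ctr - center_mm[d]) / semi_mm[d])
    # occupancy: fraction of s^3 subsamples with q < 1 (looped to bound memory)
    x2 = axes_sub[0] ** 2
    y2 = axes_sub[1] ** 2
    z2 = axes_sub[2] ** 2
    count = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=np.uint16)
    for a in range(s):
        for b in range(s):
            for c in range(s):
                qs = (x2[:, a][:, None, None] + y2[:, b][None, :, None]
                      + z2[:, c][None, None, :])
                count += (qs < 1.0).astype(np.uint16)
    occ = count / float(s ** 3)
    q = (axes_ctr[0][:, None, None] ** 2 + axes_ctr[1][None, :, None] ** 2
         + axes_ctr[2][None, None, :] ** 2)
    return sl, occ, q


def _place(label_grid, label_id, spacing, center_mm, volume_mm3, ratios,
           supersample=2):
    """Assign exactly round(V / voxvol) voxels to ``label_id`` around a center."""
    voxvol = spacing ** 3
    n_target = int(round(volume_mm3 / voxvol))
    if n_target == 0:
        return 0
    # semi-axes with the requested analytic volume
    base = (volume_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = tuple(base * r for r in ratios)
    sl, occ, q = _occupancy(label_grid.shape, spacing, center_mm, semi, supersample)
    free = label_grid[sl] == 0
    score_occ = np.where(free, occ, -1.0)
    score_q = np.where(free, q, np.inf)
    flat_order = np.lexsort((score_q.ravel(), -score_occ.ravel()))
    if n_target > flat_order.size:
        raise GeometryError(
            f"label {label_id}: {n_target} voxels requested but the grid "
            f"region holds only {flat_order.size}")
    chosen = flat_order[:n_target]
    if score_occ.ravel()[chosen[-1]] < 0 or score_q.ravel()[chosen[-1]] > 2.0:
        raise GeometryError(
            f"label {label_id}: cannot place {n_target} voxels "
            "(grid capacity or structure overlap)")
    idx = np.unravel_index(chosen, occ.shape)
    sub = label_grid[sl]
    sub[idx] = label_id
    label_grid[sl] = sub
    return n_target


def render_phantom(volumes: dict, structures, modality: ModalityParams,
                   seed: int, linear_scale: float = 1.0,
                   layout: dict | None = None, supersample: int = 2,
                   ) -> tuple[LabeledImage, LabelMap]:
    """Render per-structure volumes (mm^3) as a labeled intensity phantom.

    Parameters
    ----------
    volumes : mapping structure name -> volume in mm^3 (>= 0).
    structures : sequence of :class:`StructureDef` giving tissue class and
        laterality; order defines label ids (1-based).
    modality : grid shape, voxel spacing (mm), tissue intensity means and
        Gaussian noise SD.
    seed : seeds the intensity noise; the geometry is deterministic.
    linear_scale : optional multiplier on linear dimensions (volumes scale
        with its cube), emulating an uncalibrated gradient drift.
    """
    layout = TEMPLATE_LAYOUT if layout is None else layout
    shape = tuple(modality.grid_shape)
    spacing = float(modality.spacing_mm)
    fov = tuple(n * spacing for n in shape)
    label_grid = np.zeros(shape, dtype=np.int32)
    labels: dict[int, LabelInfo] = {}
    vol_factor = float(linear_scale) ** 3
    for lid, s in enumerate(structures, start=1):
        v = volumes.get(s.name, 0.0) * vol_factor
        if v < 0:
            raise ValueError(f"volume for {s.name!r} must be >= 0")
        if s.name not in layout:
            raise GeometryError(f"no template position for structure {s.name!r}")
        dx, fy, fz, ratios = layout[s.name]
        labels[lid] = LabelInfo(s.name, s.tissue,
                                "unsplit" if s.bilateral else "midline",
                                bilateral=s.bilateral)
        placed = 0
        if s.bilateral:
            n_vox = int(round(v / spacing ** 3))
            v_left = (n_vox // 2) * spacing ** 3
            v_right = v - v_left
            for side, vv in ((-1.0, v_left), (+1.0, v_right)):
                c = ((0.5 + side * dx) * fov[0], fy * fov[1], fz * fov[2])
                placed += _place(label_grid, lid, spacing, c, vv, ratios, supersample)
        else:
            c = (0.5 * fov[0], fy * fov[1], fz * fov[2])
            placed = _place(label_grid, lid, spacing, c, v, ratios, supersample)
        if placed == 0:
            labels.pop(lid)  # vanished (sub-voxel) structure, e.g. collapsed CSF
    dtype = np.float32 if np.prod(shape) > 4_000_000 else np.float64
    intens = np.full(shape, modality.intensity.get("background", 0.0), dtype=dtype)
    for lid, info in labels.items():
        intens[label_grid == lid] = modality.intensity[info.tissue]
    if modality.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x9e3779b9)))
        intens += rng.normal(0.0, modality.noise_sd, size=shape).astype(dtype)
    image = LabeledImage(intens, (spacing,) * 3)
    label_map = LabelMap(label_grid, (spacing,) * 3, labels)
    return image, label_map


def render_pair(traj: SubjectTrajectory, spec: CohortSpec, seed: int,
                timepoint_index: int = -1) -> PhantomPair:
    """Render the terminal in vivo / ex vivo image pair for one subject."""
    times = traj.timepoints
    k = range(len(times))[timepoint_index]
    drift = spec.gradient_drift_per_month
    scale = 1.0 + drift * (times[k] - times[0]) if drift else 1.0
    iv_img, iv_lab = render_phantom(
        traj.invivo_volumes[k], spec.structures, spec.invivo,
        seed=seed * 1000 + 2 * k, linear_scale=scale)
    ex_img, ex_lab = render_phantom(
        traj.exvivo_volumes, spec.structures, spec.exvivo,
        seed=seed * 1000 + 2 * k + 1)
    return PhantomPair(iv_img, iv_lab, ex_img, ex_lab,
                       traj.subject_id, times[k], seed)


def make_atlases(spec: CohortSpec, n_atlases: int = 3, seed: int = 1234,
                 volume_jitter: float = 0.06, noise_sd: float | None = None,
                 modality: str = "invivo"):
    """Synthetic atlas set: template renderings with jittered structure volumes.

    Stand-in for a manually labeled atlas database, which (like the real one)
    exists in both an in vivo and an ex vivo variant: ``modality="exvivo"``
    applies the wild-type ex vivo tissue-change factors to the atlas volumes
    (so atlas ventricles are collapsed too) and renders at the ex vivo
    resolution; ``"exvivo_downsampled"`` uses ex vivo volumes on the in vivo
    grid. Each atlas's volumes are multiplied by ``exp(N(0, jitter))`` so the
    set brackets the population anatomy. Returns a list of
    ``(LabeledImage, LabelMap, atlas_id)`` tuples.
    """
    if n_atlases < 1:
        raise ValueError("need at least one atlas")
    from .cohort import apply_exvivo_effect  # local: avoids cycle at import
    base = {s.name: s.beta0 + s.beta1 * spec.timepoints[0] for s in spec.structures}
    if modality == "invivo":
        mod = spec.invivo
    elif modality == "exvivo":
        mod = spec.exvivo
        base = apply_exvivo_effect(base, spec, "WT")
    elif modality == "exvivo_downsampled":
        mod = spec.invivo
        base = apply_exvivo_effect(base, spec, "WT")
    else:
        raise ValueError(f"unknown atlas modality {modality!r}")
    if noise_sd is not None:
        mod = ModalityParams(mod.spacing_mm, mod.grid_shape, mod.intensity,
                             noise_sd)
    out = []
    for a in range(n_atlases):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 77, a)))
        vols = {k: v * float(np.exp(rng.normal(0.0, volume_jitter)))
                for k, v in base.items()}
        img, lab = render_phantom(vols, spec.structures, mod,
                                  seed=int(seed) * 100 + a)
        out.append((img, lab, f"{modality}_atlas{a:02d}"))
    return out
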