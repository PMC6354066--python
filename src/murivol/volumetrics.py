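"""In vivo vs ex vivo comparison metrics.

* Percentage volume difference (PVD): the volume change expressed as a
  percentage of the mean of the two measurements, ``100 * (Vex - Vin) /
  ((Vex + Vin) / 2)``. Bounded in [-200, 200]; a structure collapsing to zero
  (e.g. the ventricles ex vivo) approaches -200%.
* Bland-Altman summaries of the proportional differences: bias (mean PVD) and
  1.96-SD limits of agreement.
* Gray/white contrast-to-noise ratio (CNR): pooled GM minus pooled WM mean
  intensity over the noise SD in a signal-free background region, which is
  defined once in a groupwise space and propagated to every subject through
  the inverse of its groupwise affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .images import AffineTransform, LabeledImage, LabelMap
from .registration import warp_image

__all__ = [
    "BlandAltmanSummary",
    "CNRRecord",
    "pvd",
    "bland_altman",
    "groupwise_background_roi",
    "cnr",
]


def pvd(v_in: float, v_ex: float) -> float:
    """Percentage volume difference of an (in vivo, ex vivo) volume pair."""
    if v_in < 0 or v_ex < 0:
        raise ValueError("volumes must be non-negative")
    if v_in + v_ex == 0:
        raise ValueError("PVD undefined: both volumes are zero")
    return 100.0 * (v_ex - v_in) / ((v_ex + v_in) / 2.0)


@dataclass(frozen=True)
class BlandAltmanSummary:
    bias: float        # mean proportional difference, %
    sd: float          # SD of the differences (ddof 1)
    loa_lower: float   # bias - 1.96 sd
    loa_upper: float   # bias + 1.96 sd
    n: int


def bland_altman(pairs) -> BlandAltmanSummary:
    """Bland-Altman summary of proportional (PVD) differences.

    ``pairs`` is an iterable of (V_in, V_ex); needs n >= 2 for the sample SD.
    """
    diffs = np.array([pvd(a, b) for a, b in pairs])
    if diffs.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanSummary(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd,
                              int(diffs.size))


def groupwise_background_roi(affines: list[AffineTransform], roi: np.ndarray,
                             reference: LabeledImage,
                             subjects: list[LabeledImage],
                             brain_masks: list[np.ndarray] | None = None,
                             ) -> tuple[list[np.ndarray], list[bool]]:
    """Map a background ROI from groupwise space into every subject.

    ``affines[i]`` is subject-i -> groupwise world; the ROI (a boolean grid on
    the reference/groupwise grid) is propagated with the inverse transform.
    If a brain mask is supplied and the propagated ROI touches it, the subject
    is QA-flagged (noise estimates should then exclude it).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != reference.shape:
        raise ValueError("ROI must live on the groupwise (reference) grid")
    rois, flags = [], []
    src = LabeledImage(roi.astype(np.float64), reference.spacing, reference.affine)
    for i, subj in enumerate(subjects):
        # pull-back subject world -> groupwise world is the forward affine
        mapped = warp_image(src, affines[i], subj, order=0) > 0.5
        flag = False
        if brain_masks is not None and np.logical_and(mapped, brain_masks[i]).any():
            flag = True
            warnings.warn(f"propagated background ROI overlaps brain mask "
                          f"for subject {i}; flagged for exclusion")
        rois.append(mapped)
        flags.append(flag)
    return rois, flags


@dataclass(frozen=True)
class CNRRecord:
    signal_gm: float
    signal_wm: float
    noise: float
    cnr: float


def cnr(image: LabeledImage, labels: LabelMap, background: np.ndarray) -> CNRRecord:
    """Gray/white CNR: (mean GM - mean WM) / SD(background).

    GM and WM intensities are pooled over all structures of each tissue class;
    ventricular CSF belongs to neither pool. The background grid must be
    non-empty, have positive variance and be disjoint from the labels.
    """
    background = np.asarray(background, dtype=bool)
    if background.shape != image.shape or labels.shape != image.shape:
        raise ValueError("image, labels and background must share a grid")
    if not background.any():
        raise ValueError("background ROI is empty")
    if np.logical_and(background, labels.data > 0).any():
        raise ValueError("background ROI overlaps labeled tissue")
    gm_ids = [lid for lid, v in labels.labels.items() if v.tissue == "GM"]
    wm_ids = [lid for lid, v in labels.labels.items() if v.tissue == "WM"]
    gm_mask = np.isin(labels.data, gm_ids)
    wm_mask = np.isin(labels.data, wm_ids)
    if not gm_mask.any() or not wm_mask.any():
        raise ValueError("need non-empty GM and WM label sets")
    noise = float(image.data[background].std(ddof=1))
    if noise <= 0:
        raise ValueError("background ROI has zero variance; cannot estimate noise")
    s_gm = float(image.data[gm_mask].mean())
    s_wm = float(image.data[wm_mask].mean())
    return CNRRecord(s_gm, s_wm, noise, (s_gm - s_wm) / noise)
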