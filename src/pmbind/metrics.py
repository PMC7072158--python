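"""Plasma-membrane localization metrics.

The central quantities are ratios of mean fluorescence between the
plasma-membrane annulus and the cytoplasm of a single cell:

* ``%PM = 100 * I_PM / (I_PM + I_Cyt)`` — fraction of signal at the
  membrane, bounded in (0, 100];
* ``PM index = I_PM / I_Cyt`` — membrane-to-cytosol ratio, > 1 for a
  membrane-enriched protein;
* ``dissociation index = PM index(before) / PM index(after)`` — how much a
  treatment (e.g. rapamycin-induced phosphoinositide depletion) displaces
  the protein from the membrane; > 1 means loss of membrane localization.

Being ratios, all three are invariant to detector gain; they are *not*
invariant to additive background, which pulls %PM toward 50 (an offset
inflates both means equally).  Optional background subtraction (mean
intensity outside the cell mask) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .exceptions import MetricError, SegmentationError, UndefinedMetricError
from .imaging import CellMasks, Image, erosions_for_physical_width, \
    make_pm_annulus, segment_cell


@dataclass(frozen=True)
class LocalizationResult:
    """Localization metrics for one cell in one frame.

    ``pm_index`` is NaN (and ``pm_index_defined`` False) when the
    cytoplasmic mean is zero.
    """

    I_PM: float
    I_Cyt: float
    pm_index: float
    percent_pm: float
    pm_index_defined: bool = True


@dataclass(frozen=True)
class DissociationResult:
    """PM indices before/after a treatment and their ratio."""

    pm_index_before: float
    pm_index_after: float
    dissociation_index: float


def _roi_means(image: np.ndarray, interior: np.ndarray, n_rois: int,
               roi_size: int, seed: int) -> float:
    """Mean of means over seeded square ROIs fully inside the interior."""
    from scipy import ndimage as ndi

    half = roi_size // 2
    safe = ndi.distance_transform_edt(interior) > half * np.sqrt(2) + 1
    coords = np.argwhere(safe)
    if len(coords) < n_rois:
        raise MetricError(
            f"interior too small to place {n_rois} ROI(s) of size {roi_size}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(coords), size=n_rois, replace=False)
    means = []
    for cy, cx in coords[idx]:
        patch = image[cy - half:cy + half + 1, cx - half:cx + half + 1]
        means.append(patch.mean())
    return float(np.mean(means))


def quantify_localization(
    image: Image,
    masks: CellMasks,
    cytoplasm_mode: str = "whole",
    n_rois: int = 2,
    roi_size: int = 7,
    roi_seed: int = 0,
    background_subtract: bool = False,
) -> LocalizationResult:
    """Compute %PM and PM index for one cell.

    ``I_PM`` is the pixel mean over the annulus.  ``I_Cyt`` is either the
    mean over the whole interior (``cytoplasm_mode="whole"``, the default)
    or the average of ``n_rois`` seeded square regions sampled inside it
    (``"rois"``), reproducing the practice of measuring a couple of
    cytosolic patches per cell.  With ``background_subtract`` the mean
    intensity outside the cell mask is removed from both means first.
    """
    px = image.pixels
    if px.shape != masks.cell.shape:
        raise MetricError("mask shape does not match image")
    if not masks.pm_annulus.any() or not masks.interior.any():
        raise MetricError("empty annulus or interior region")

    bg = 0.0
    if background_subtract:
        outside = ~masks.cell
        if outside.any():
            bg = float(px[outside].mean())

    I_pm = float(px[masks.pm_annulus].mean()) - bg
    if cytoplasm_mode == "whole":
        I_cyt = float(px[masks.interior].mean()) - bg
    elif cytoplasm_mode == "rois":
        I_cyt = _roi_means(px, masks.interior, n_rois, roi_size, roi_seed) - bg
    else:
        raise ValueError(f"unknown cytoplasm_mode {cytoplasm_mode!r}")

    total = I_pm + I_cyt
    if total <= 0:
        raise UndefinedMetricError("I_PM + I_Cyt is zero: %PM undefined")
    percent_pm = 100.0 * I_pm / total
    if I_cyt > 0:
        return LocalizationResult(I_PM=I_pm, I_Cyt=I_cyt,
                                  pm_index=I_pm / I_cyt,
                                  percent_pm=percent_pm)
    return LocalizationResult(I_PM=I_pm, I_Cyt=I_cyt, pm_index=float("nan"),
                              percent_pm=percent_pm, pm_index_defined=False)


def quantify_image(
    image: Image,
    method: Union[str, float] = "otsu",
    n_erosions: Optional[int] = None,
    rim_width: float = 0.4,
    min_area: int = 25,
    **kwargs,
) -> LocalizationResult:
    """End-to-end quantification: segment, build annulus, measure.

    ``n_erosions=None`` derives the erosion count from the image's pixel
    size and the target physical rim width (µm).  Extra keyword arguments
    are passed to :func:`quantify_localization`.
    """
    cell = segment_cell(image, method=method, min_area=min_area)
    if n_erosions is None:
        n_erosions = erosions_for_physical_width(image.pixel_size, rim_width)
    masks = make_pm_annulus(cell, n_erosions)
    return quantify_localization(image, masks, **kwargs)


def dissociation_index(
    stack,
    t_before: int = 0,
    t_after: int = -1,
    masks: Union[CellMasks, Sequence[CellMasks], None] = None,
    method: Union[str, float] = "otsu",
    n_erosions: Optional[int] = None,
    rim_width: float = 0.4,
    orientation: str = "before/after",
    **kwargs,
) -> DissociationResult:
    """Dissociation index between two frames of a time-lapse stack.

    ``masks`` may be a single :class:`CellMasks` used for both frames, a
    per-frame sequence, or ``None`` to segment each frame with the pipeline
    (falling back to the *before* frame's masks if the *after* frame fails
    segmentation — cells move little over a few minutes).  The default
    orientation is before/after, so displacement from the membrane reads as
    an index above 1; pass ``orientation="after/before"`` to invert.
    """
    if orientation not in ("before/after", "after/before"):
        raise ValueError("orientation must be 'before/after' or 'after/before'")
    idx_before = range(stack.n_frames)[t_before]
    idx_after = range(stack.n_frames)[t_after]

    def masks_for(i: int, fallback: Optional[CellMasks]) -> CellMasks:
        if isinstance(masks, CellMasks):
            return masks
        if masks is not None:
            return masks[i]
        image = stack.frame(i)
        try:
            cell = segment_cell(image, method=method)
            n = n_erosions if n_erosions is not None else \
                erosions_for_physical_width(image.pixel_size, rim_width)
            return make_pm_annulus(cell, n)
        except SegmentationError:
            if fallback is None:
                raise
            return fallback

    m_before = masks_for(idx_before, None)
    m_after = masks_for(idx_after, m_before)

    r_before = quantify_localization(stack.frame(idx_before), m_before, **kwargs)
    r_after = quantify_localization(stack.frame(idx_after), m_after, **kwargs)
    if not (r_before.pm_index_defined and r_after.pm_index_defined):
        raise UndefinedMetricError("PM index undefined at one of the time points")
    if r_after.pm_index <= 0 or r_before.pm_index <= 0:
        raise UndefinedMetricError("PM index must be positive at both time points")

    di = r_before.pm_index / r_after.pm_index
    if orientation == "after/before":
        di = 1.0 / di
    return DissociationResult(pm_index_before=r_before.pm_index,
                              pm_index_after=r_after.pm_index,
                              dissociation_index=di)


def normalize_to_reference(values: Sequence[float],
                           reference_values: Sequence[float]) -> List[float]:
    """Express values as a percentage of a reference group's mean.

    Used to report mutant %PM relative to wild type (wild type mean → 100).
    """
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0 or ref.mean() <= 0:
        raise ValueError("reference mean must be positive")
    scale = 100.0 / ref.mean()
    return [float(v) * scale for v in values]
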