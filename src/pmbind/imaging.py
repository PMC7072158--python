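"""Cell segmentation and plasma-membrane annulus construction.

The membrane mask is built by the threshold → binarize → erode → subtract
procedure used in confocal localization studies: the binary cell mask is
eroded ``n`` times with a 3x3 square structuring element (one pixel of rim
removed per erosion, 8-connected, matching ImageJ's binary erode) and the
eroded mask is subtracted from the original to leave an annulus hugging the
cell periphery.  The annulus stands for plasma-membrane fluorescence; the
eroded remainder ("interior") stands for the cytoplasm.

The number of erosions can be tied to a physical rim width (~400 nm is the
conventional optical-resolution-scale choice) through
:func:`erosions_for_physical_width`, which converts the target width to
pixels and clips to the 2-4 range used in practice across zoom levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .exceptions import DegenerateAnnulusError, SegmentationError

# one pixel of rim per erosion, 8-connected — ImageJ binary-erode semantics
STRUCTURING_ELEMENT = np.ones((3, 3), dtype=bool)

DEFAULT_RIM_WIDTH_UM = 0.4  # ~400 nm


@dataclass(frozen=True)
class Image:
    """A single-channel 2-D fluorescence image.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensities in arbitrary fluorescence
        units (AFU).
    pixel_size
        Physical pixel pitch in µm/pixel.
    channel
        Free-text channel label (e.g. ``"mCherry"``).
    time_index
        Frame index within a time series, if applicable.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = ""
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image must be 2-D and at least 8x8, got shape {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("image intensities must be finite and nonnegative")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class CellMasks:
    """Cell / plasma-membrane annulus / interior partition of one cell.

    ``pm_annulus`` and ``interior`` are disjoint and their union is ``cell``.
    ``n_erosions_used`` records how many erosions produced the interior
    (0 for painted ground-truth masks from the synthetic generator).
    """

    cell: np.ndarray
    pm_annulus: np.ndarray
    interior: np.ndarray
    n_erosions_used: int = 0

    def __post_init__(self) -> None:
        self.cell = np.asarray(self.cell, dtype=bool)
        self.pm_annulus = np.asarray(self.pm_annulus, dtype=bool)
        self.interior = np.asarray(self.interior, dtype=bool)
        if not (self.cell.shape == self.pm_annulus.shape == self.interior.shape):
            raise ValueError("mask shapes differ")
        if np.any(self.pm_annulus & self.interior):
            raise ValueError("pm_annulus and interior overlap")
        if not np.array_equal(self.pm_annulus | self.interior, self.cell):
            raise ValueError("pm_annulus and interior do not tile the cell mask")


def segment_cell(
    image: Image,
    method: Union[str, float] = "otsu",
    min_area: int = 25,
    fill_holes: bool = True,
) -> np.ndarray:
    """Segment the single largest cell in an image.

    The image is thresholded (Otsu by default, or a fixed intensity given as
    a number or ``"fixed:<value>"``), binarized, hole-filled (so nuclei or
    vacuole voids cannot create internal annuli later) and reduced to its
    largest connected foreground component.

    Returns a boolean mask.  Raises :class:`SegmentationError` on a uniform
    image or when the largest component is below ``min_area`` pixels.
    """
    px = image.pixels
    if isinstance(method, str):
        if method == "otsu":
            if np.ptp(px) == 0:
                raise SegmentationError("uniform image: no threshold separates foreground")
            thresh = threshold_otsu(px)
        elif method.startswith("fixed:"):
            thresh = float(method.split(":", 1)[1])
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    else:
        thresh = float(method)

    binary = px > thresh
    if not binary.any():
        raise SegmentationError(f"no pixels above threshold {thresh:g}")
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)

    labels, n = ndi.label(binary, structure=STRUCTURING_ELEMENT)
    if n == 0:
        raise SegmentationError("no foreground component found")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area:
        raise SegmentationError(
            f"largest component has {areas[best - 1]} px, below min_area={min_area}"
        )
    return labels == best


def segment_cells(
    image: Image,
    method: Union[str, float] = "otsu",
    min_area: int = 25,
    fill_holes: bool = True,
) -> list:
    """Segment every cell in an image, largest first.

    Like :func:`segment_cell` but returns one boolean mask per connected
    component with area ≥ ``min_area``, sorted by decreasing area.
    """
    px = image.pixels
    if isinstance(method, str):
        if method == "otsu":
            if np.ptp(px) == 0:
                raise SegmentationError("uniform image: no threshold separates foreground")
            thresh = threshold_otsu(px)
        elif method.startswith("fixed:"):
            thresh = float(method.split(":", 1)[1])
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    else:
        thresh = float(method)
    binary = px > thresh
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary, structure=STRUCTURING_ELEMENT)
    masks = [labels == i for i in range(1, n + 1) if (labels == i).sum() >= min_area]
    masks.sort(key=lambda m: -int(m.sum()))
    if not masks:
        raise SegmentationError(f"no component reaches min_area={min_area}")
    return masks


def make_pm_annulus(cell: np.ndarray, n_erosions: int = 2) -> CellMasks:
    """Build the plasma-membrane annulus by erode-and-subtract.

    The cell mask is eroded ``n_erosions`` times with the 3x3 square element;
    the eroded mask is the interior (cytoplasm) and its complement within the
    cell is the annulus.  Raises :class:`DegenerateAnnulusError` if erosion
    empties the mask, and ``ValueError`` if the input is not a single
    connected component.
    """
    cell = np.asarray(cell, dtype=bool)
    if n_erosions < 1:
        raise ValueError("n_erosions must be >= 1")
    if not cell.any():
        raise ValueError("cell mask is empty")
    _, n = ndi.label(cell, structure=STRUCTURING_ELEMENT)
    if n != 1:
        raise ValueError(f"cell mask must be a single connected component, found {n}")

    interior = ndi.binary_erosion(cell, structure=STRUCTURING_ELEMENT,
                                  iterations=n_erosions, border_value=0)
    if not interior.any():
        raise DegenerateAnnulusError(
            f"object too small: {n_erosions} erosion(s) emptied the mask"
        )
    annulus = cell & ~interior
    return CellMasks(cell=cell, pm_annulus=annulus, interior=interior,
                     n_erosions_used=n_erosions)


def erosions_for_physical_width(
    pixel_size: float, target_width: float = DEFAULT_RIM_WIDTH_UM
) -> int:
    """Number of 1-px erosions approximating a physical rim width.

    Rounds ``target_width / pixel_size`` to the nearest integer and clips to
    the conventional 2-4 range (the rim should span roughly 400 nm regardless
    of zoom).  Both arguments are in µm.
    """
    if not (pixel_size > 0):
        raise ValueError("pixel_size must be positive")
    if not (target_width > 0):
        raise ValueError("target_width must be positive")
    n = int(np.round(target_width / pixel_size))
    return int(np.clip(n, 2, 4))
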