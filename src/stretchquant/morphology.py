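"""Morphology metrics: phalloidin cell-area index and puncta area density.

In confluent monolayers individual cell boundaries are ambiguous, so cell
area is measured as the total thresholded phalloidin (actin) area in the
field divided by the number of nuclei — an average spread area per cell.
Punctate channel staining (e.g. a mechanosensitive channel clustering after
injury) is quantified by white-top-hat filtering at the spot scale to remove
diffuse background, thresholding the residual, gating components by size and
contrast inside a reference mask, and normalizing the count by the reference
area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .calcium import li_threshold
from .exceptions import DegenerateImageError, ValidationError
from .nuclei import LabelMap


@dataclass
class CellAreaIndex:
    phalloidin_area: float
    nuclei_count: int
    index: float  # area per cell
    units: str = "px^2"


@dataclass
class PunctaResult:
    puncta_count: int
    puncta_total_area: float
    reference_area: float
    density: float  # count per unit reference area
    units: str = "px^2"


def cell_area_index(
    phalloidin_image: np.ndarray,
    nuclei_labels,
    pixel_size: float | None = None,
) -> CellAreaIndex:
    """Total thresholded phalloidin area divided by the intact-nucleus count.

    The cytoplasm mask is the Li (minimum cross-entropy) suprathreshold region
    of the phalloidin channel. Raises on zero nuclei — an undefined index is
    an error, never a silent zero.
    """
    if isinstance(nuclei_labels, LabelMap):
        count = nuclei_labels.n_objects
    elif np.isscalar(nuclei_labels):
        count = int(nuclei_labels)
    else:
        count = int(np.asarray(nuclei_labels).max())
    if count < 1:
        raise ValidationError("cell-area index undefined with zero nuclei")
    image = np.asarray(phalloidin_image, dtype=float)
    mask = image > li_threshold(image)
    scale = 1.0 if pixel_size is None else pixel_size**2
    area = float(mask.sum()) * scale
    return CellAreaIndex(
        phalloidin_area=area,
        nuclei_count=count,
        index=area / count,
        units="px^2" if pixel_size is None else "um^2",
    )


def detect_puncta(
    image: np.ndarray,
    reference_mask: np.ndarray,
    spot_scale: float = 3.0,
    min_contrast: float = 0.0,
    size_range: tuple[float, float] = (1.0, 200.0),
    pixel_size: float | None = None,
) -> PunctaResult:
    """Count punctate spots inside a reference region; density = count / area.

    A white top-hat at ``spot_scale`` px suppresses any background smoother
    than the spot size; the residual is Li-thresholded; 8-connected components
    whose area lies in ``size_range`` and whose mean residual is at least
    ``min_contrast`` count as puncta. The reference mask (thresholded
    cytoplasm by convention, or the full field) provides the normalizing area
    so that density is not diluted by empty substrate.
    """
    if spot_scale <= 0:
        raise ValidationError(f"spot_scale must be > 0, got {spot_scale}")
    mask = np.asarray(reference_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("reference_mask is empty")
    image = np.asarray(image, dtype=float)
    if image.shape != mask.shape:
        raise ValidationError("image and reference_mask shapes differ")

    residual = skmorph.white_tophat(image, footprint=skmorph.disk(int(round(spot_scale))))
    scale = 1.0 if pixel_size is None else pixel_size**2
    ref_area = float(mask.sum()) * scale
    units = "px^2" if pixel_size is None else "um^2"
    try:
        thr = li_threshold(residual)
    except DegenerateImageError:
        return PunctaResult(0, 0.0, ref_area, 0.0, units)
    # floor the threshold at 6x the robust noise scale of the residual so
    # thresholding never happens inside the camera-noise band (the global
    # cross-entropy minimum can fall there when spots are a tiny pixel
    # fraction of the field)
    med = np.median(residual)
    noise_floor = 6.0 * 1.4826 * float(np.median(np.abs(residual - med)))
    thr = max(thr, noise_floor)

    spots = (residual > thr) & mask
    labels, k = ndi.label(spots, structure=ndi.generate_binary_structure(2, 2))
    count = 0
    total_area = 0.0
    lo, hi = size_range
    if k:
        areas = np.bincount(labels.ravel())[1:]
        means = ndi.mean(residual, labels=labels, index=np.arange(1, k + 1))
        keep = (areas >= lo) & (areas <= hi) & (means >= min_contrast)
        count = int(keep.sum())
        total_area = float(areas[keep].sum()) * scale
    return PunctaResult(
        puncta_count=count,
        puncta_total_area=total_area,
        reference_area=ref_area,
        density=count / ref_area,
        units=units,
    )
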