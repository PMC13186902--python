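"""Nuclear segmentation: two-step Otsu, solidity filtering, somatic expansion.

The segmentation strategy targets monolayer nuclear stains containing both
intact nuclei and dimmer nuclear fragments: a first Otsu threshold separates
all stained material from background, a second Otsu applied to the foreground
pixels only separates bright intact nuclei from dim fragments, and a solidity
filter removes irregular or overlapping shapes among what remains. Accepted
nuclei can then be expanded outward to define somatic regions of interest for
cytoplasmic intensity measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .exceptions import DegenerateDataWarning, DegenerateImageError, ValidationError


@dataclass
class LabelMap:
    """H x W integer object labels; 0 is background, objects are 1..K."""

    labels: np.ndarray
    pixel_size: float | None = None  # um per px, if known

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError(f"labels must be integer, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValidationError(
                f"labels must be contiguous 1..K, found {present.tolist()[:10]}..."
            )

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class NucleusRecord:
    """Per-object measurements used for the intact/fragment decision."""

    label: int
    area: float  # px^2
    solidity: float
    centroid: tuple[float, float]
    intact: bool


def _as_labels(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)


def otsu_threshold(counts, bin_centers=None) -> float:
    """Otsu threshold of an intensity histogram (or of a raw image).

    Maximizes between-class variance over all split points; on ties the lowest
    maximizing threshold is returned. Pass either a histogram as
    ``(counts, bin_centers)`` or a raw image array as ``counts`` alone.
    """
    counts = np.asarray(counts)
    if bin_centers is None and counts.ndim >= 2:
        # exact discrete Otsu: one bin per distinct intensity value
        values, value_counts = np.unique(counts.ravel(), return_counts=True)
        if values.size < 2:
            raise DegenerateImageError(
                "single-valued image: Otsu threshold is undefined"
            )
        counts, bin_centers = value_counts, values
    elif bin_centers is None:
        raise ValidationError("histogram input requires explicit bin_centers")
    bin_centers = np.asarray(bin_centers, dtype=float)
    keep = counts > 0
    if keep.sum() < 2:
        raise DegenerateImageError(
            "histogram has fewer than 2 occupied bins: threshold is undefined"
        )
    counts, bin_centers = counts[keep].astype(float), bin_centers[keep]
    split = float(filters.threshold_otsu(hist=(counts, bin_centers)))
    # skimage returns the top bin of the background class; report the midpoint
    # of the gap so the threshold sits strictly between the two classes
    i = min(int(np.searchsorted(bin_centers, split)), len(bin_centers) - 2)
    return float(0.5 * (bin_centers[i] + bin_centers[i + 1]))


def two_step_otsu_segment(
    image: np.ndarray,
    mode: str = "two_step",
    connectivity: int = 2,
    pixel_size: float | None = None,
) -> LabelMap:
    """Segment bright nuclei by thresholding twice, then label components.

    Step 1: Otsu on the full image separates stained material from background.
    Step 2: Otsu re-applied to the foreground pixels only; the final mask keeps
    pixels above this second threshold, discarding dim material (fragments,
    debris). If the foreground is single-valued the second step is skipped.

    ``mode`` selects the strategy: ``"two_step"`` (default, as above),
    ``"single"`` (one global Otsu), or ``"three_class"`` (one three-class
    multi-Otsu, keeping the brightest class).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3 and image.shape[0] == 1:
        image = image[0]
    if image.ndim != 2:
        raise ValidationError(f"expected a single frame, got shape {image.shape}")
    if np.unique(image).size < 2:
        raise DegenerateImageError("image is single-valued; nothing to segment")

    if mode == "single":
        mask = image > otsu_threshold(image)
    elif mode == "three_class":
        t_lo, t_hi = filters.threshold_multiotsu(image, classes=3)
        mask = image > t_hi
    elif mode == "two_step":
        t1 = otsu_threshold(image)
        fg = image > t1
        if not fg.any():
            warnings.warn(
                "empty foreground after first Otsu step", DegenerateDataWarning
            )
            return LabelMap(np.zeros(image.shape, dtype=np.int32), pixel_size)
        fg_values = image[fg]
        if np.unique(fg_values).size < 2:
            mask = fg  # flat foreground: second split undefined, keep step 1
        else:
            t2 = otsu_threshold(fg_values.reshape(1, -1))
            mask = image > t2
    else:
        raise ValidationError(f"unknown segmentation mode {mode!r}")

    labels = measure.label(mask, connectivity=connectivity)
    return LabelMap(labels.astype(np.int32), pixel_size)


def filter_by_solidity(
    labels,
    min_solidity: float = 0.9,
    min_area: float = 40.0,
    max_area: float = np.inf,
) -> tuple[LabelMap, list[NucleusRecord]]:
    """Keep intact objects (solid enough, sized within bounds); relabel 1..K'.

    Returns the filtered map plus one :class:`NucleusRecord` per *input*
    object, with ``intact`` flagging whether it survived. Solidity is object
    area over convex-hull area, so fragments and overlapping clumps score low.
    """
    if not (0 < min_solidity <= 1):
        raise ValidationError(f"min_solidity must be in (0, 1], got {min_solidity}")
    lab = _as_labels(labels)
    pixel_size = labels.pixel_size if isinstance(labels, LabelMap) else None
    records: list[NucleusRecord] = []
    out = np.zeros_like(lab, dtype=np.int32)
    next_label = 0
    for prop in measure.regionprops(lab):
        intact = (
            prop.solidity >= min_solidity and min_area <= prop.area <= max_area
        )
        records.append(
            NucleusRecord(
                label=prop.label,
                area=float(prop.area),
                solidity=float(prop.solidity),
                centroid=tuple(map(float, prop.centroid)),
                intact=bool(intact),
            )
        )
        if intact:
            next_label += 1
            out[lab == prop.label] = next_label
    return LabelMap(out, pixel_size), records


def expand_to_soma(labels, distance: float) -> LabelMap:
    """Grow each label outward by up to ``distance`` px (Euclidean).

    Contested pixels go to the nearest seed label; exact distance ties go to
    the lower label id, so the output is deterministic. Original nuclear
    pixels always keep their label, and expansions of neighbouring nuclei
    partition the contested corridor with no overlap.
    """
    if distance < 0:
        raise ValidationError(f"distance must be >= 0, got {distance}")
    lab = _as_labels(labels)
    pixel_size = labels.pixel_size if isinstance(labels, LabelMap) else None
    if distance == 0 or lab.max() == 0:
        return LabelMap(lab.copy().astype(np.int32), pixel_size)

    best_dist = np.full(lab.shape, np.inf)
    out = np.zeros_like(lab, dtype=np.int32)
    # ascending label order + strict inequality => ties resolve to lower id
    for label_id in range(1, int(lab.max()) + 1):
        d = ndi.distance_transform_edt(lab != label_id)
        closer = d < best_dist
        out[closer] = label_id
        best_dist[closer] = d[closer]
    out[best_dist > distance] = 0
    return LabelMap(out, pixel_size)
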