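"""Per-dynamic tip localisation from three contiguous-slice segmentations.

One real-time *dynamic* acquires three parallel slices; the balloon can show
up in more than one of them (or as several spurious blobs).  To hand a single
coordinate to a slice-tracking system, all predicted regions across the three
slices are pooled and the one with the highest underlying signal intensity
wins — the slice containing most of the balloon has the strongest signal.
The winner's centroid is the tip estimate; no state is carried between
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "Region",
    "DynamicTriplet",
    "TipEstimate",
    "extract_regions",
    "select_candidate",
    "track_sequence",
    "TipTracker",
]


@dataclass(frozen=True)
class Region:
    """One connected component of a predicted mask."""

    slice_index: int
    pixels: tuple[tuple[int, int], ...]
    centroid: tuple[float, float]
    intensity_score: float

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class DynamicTriplet:
    """Three contiguous slices of one dynamic, with their binary masks.

    ``masks`` may be ``None`` when the triplet is raw input still to be
    segmented (see :func:`track_sequence`).
    """

    slices: np.ndarray  # (3, H, W)
    masks: np.ndarray | None = None  # (3, H, W)
    dynamic_index: int = 0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.shape[0] != 3:
            raise ValueError("a dynamic consists of exactly 3 contiguous slices")
        if self.masks is not None:
            self.masks = np.asarray(self.masks)
            if self.masks.shape != self.slices.shape:
                raise ValueError("masks must match the slices' shape")


@dataclass(frozen=True)
class TipEstimate:
    """Unique per-dynamic output: the tip location, or 'absent'."""

    present: bool
    slice_index: int | None = None
    tip: tuple[float, float] | None = None
    intensity_score: float | None = None


def extract_regions(mask: np.ndarray, image: np.ndarray, slice_index: int = 0,
                    scoring: Literal["mean", "peak"] = "mean") -> list[Region]:
    """Connected components (8-connectivity) of ``mask`` with centroids and
    intensity scores over the underlying ``image``.

    ``scoring``: ``"mean"`` averages the image intensity over the region's
    pixels (robust to region size); ``"peak"`` takes the maximum.
    """
    mask = np.asarray(mask)
    image = np.asarray(image, dtype=np.float64)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    labels = measure.label(mask > 0, connectivity=2)
    regions = []
    for rp in measure.regionprops(labels, intensity_image=image):
        score = float(rp.intensity_mean if scoring == "mean" else rp.intensity_max)
        regions.append(Region(
            slice_index=slice_index,
            pixels=tuple(map(tuple, rp.coords)),
            centroid=tuple(rp.centroid),
            intensity_score=score,
        ))
    return regions


def _selection_key(r: Region):
    # max intensity wins; ties: lowest slice, then largest region,
    # then smallest (row, col) centroid — fully deterministic
    return (-r.intensity_score, r.slice_index, -r.size, r.centroid)


def select_candidate(triplet: DynamicTriplet,
                     scoring: Literal["mean", "peak"] = "mean") -> TipEstimate:
    """Reduce all regions across a dynamic's three slices to one tip estimate.

    Pools the connected components of all three masks; the region with the
    highest intensity score is the final balloon segmentation and its
    centroid the tip.  No region anywhere means 'absent'.
    """
    if triplet.masks is None:
        raise ValueError("triplet has no masks; segment the slices first")
    regions: list[Region] = []
    for k in range(3):
        regions.extend(extract_regions(triplet.masks[k], triplet.slices[k], k, scoring))
    if not regions:
        return TipEstimate(present=False)
    best = min(regions, key=_selection_key)
    return TipEstimate(present=True, slice_index=best.slice_index,
                       tip=best.centroid, intensity_score=best.intensity_score)


def track_sequence(dynamics: Sequence[DynamicTriplet], model,
                   scoring: Literal["mean", "peak"] = "mean") -> list[TipEstimate]:
    """Segment and localise the tip for every dynamic independently.

    ``model`` is a fitted :class:`~cathtrack.segmentation.CatheterSegmenter`;
    any masks already attached to the triplets are ignored and re-predicted.
    """
    return TipTracker(model, scoring=scoring).predict(dynamics)


class TipTracker:
    """Callable pipeline stage: trained segmenter -> per-dynamic tip estimates."""

    def __init__(self, model, scoring: Literal["mean", "peak"] = "mean"):
        self.model = model
        self.scoring = scoring

    def predict_triplet(self, triplet: DynamicTriplet) -> tuple[TipEstimate, np.ndarray]:
        """Returns the tip estimate and the three predicted masks."""
        masks = self.model.predict(triplet.slices)
        seg = DynamicTriplet(slices=triplet.slices, masks=masks,
                             dynamic_index=triplet.dynamic_index)
        return select_candidate(seg, self.scoring), masks

    def predict(self, dynamics: Sequence[DynamicTriplet]) -> list[TipEstimate]:
        return [self.predict_triplet(t)[0] for t in dynamics]
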