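"""SISN: slice information of segmentation of nodules.

Six features summarizing which axial slices of a segmentation stack contain
the nodule.  The ratio of labeled slices to total slices is the feature
documented by the study that motivated this package; the remaining five
(first, last, centroid, span, peak) are this package's reconstruction — the
minimal slice-position statistics that locate the nodule along the axial
axis.  All six are normalized by the total slice count and lie in [0, 1];
slice indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SISNFeatures", "compute_sisn", "sisn_from_areas"]


@dataclass(frozen=True)
class SISNFeatures:
    """Slice-position summary of a nodule segmentation.

    ratio
        labeled slices / total slices.
    first, last
        0-based index of the first / last labeled slice, / total.
    centroid
        area-weighted mean labeled-slice index, / total.
    span
        (last − first + 1) / total; envelope of the labeled run, so
        ``ratio <= span`` with equality iff the run has no gaps.
    peak
        index of the slice with the largest labeled area, / total; ties
        break toward the lowest slice index.
    """

    ratio: float
    first: float
    last: float
    centroid: float
    span: float
    peak: float

    def as_dict(self) -> dict[str, float]:
        return {
            "SISN_ratio": self.ratio,
            "SISN_first": self.first,
            "SISN_last": self.last,
            "SISN_centroid": self.centroid,
            "SISN_span": self.span,
            "SISN_peak": self.peak,
        }


def sisn_from_areas(areas: np.ndarray) -> SISNFeatures:
    """SISN features from per-slice labeled areas (voxels or mm²).

    ``areas`` is a 1-D array, one entry per axial slice, zero where the
    slice contains no labeled voxel.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.ndim != 1 or areas.size == 0:
        raise ValueError("areas must be a nonempty 1-D array (one per slice)")
    total = areas.size
    labeled = np.nonzero(areas > 0)[0]
    if labeled.size == 0:
        raise ValueError("no labeled voxels")
    first, last = int(labeled[0]), int(labeled[-1])
    centroid = float(np.sum(labeled * areas[labeled]) / np.sum(areas[labeled]))
    peak = int(np.argmax(areas))  # argmax takes the lowest index on ties
    return SISNFeatures(
        ratio=labeled.size / total,
        first=first / total,
        last=last / total,
        centroid=centroid / total,
        span=(last - first + 1) / total,
        peak=peak / total,
    )


def compute_sisn(stack) -> SISNFeatures:
    """SISN features from a 3-D binary mask (slices × rows × cols).

    Accepts a raw integer/boolean array or any object with a ``mask``
    attribute (e.g. a simulated phantom stack).  Requires at least one
    slice and one labeled voxel.
    """
    mask = getattr(stack, "mask", stack)
    mask = np.asarray(mask)
    if mask.ndim != 3 or mask.shape[0] == 0:
        raise ValueError("mask must be 3-D with at least one slice")
    areas = (mask != 0).sum(axis=(1, 2)).astype(np.float64)
    return sisn_from_areas(areas)
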