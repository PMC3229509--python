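"""Nucleus segmentation: brightness split, h-maxima seeds, seeded watershed.

Intensity variation between nuclei (dim tumor nuclei next to bright stromal
and inflammatory nuclei) makes a single global seeding pass over-segment the
bright population or miss the dim one.  The image is therefore split at an
Otsu threshold over the masked (non-background) pixels into a bright and a
dark sub-image, and seeding + watershed run independently on each; the two
label sets are merged with disjoint label ranges.

Seeds come from the h-maxima transform: regional maxima that survive the
suppression of peaks shallower than ``h`` grey levels.  The watershed floods
the inverted intensity landscape from those seeds, so every masked pixel
reachable from a seed is assigned to exactly one nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import relabel_sequential, watershed

from .preprocess import otsu_threshold
from .synthetic import GroundTruth

__all__ = [
    "NucleusRecord",
    "SegmentationReport",
    "split_by_brightness",
    "h_maxima_seeds",
    "seeded_watershed",
    "segment_nuclei",
    "records_from_labels",
    "evaluate_segmentation",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus with its shape and intensity statistics.

    Shape statistics follow the ellipse with the same normalized second
    central moments as the pixel set; intensity statistics are taken over
    the nucleus's own pixels in the shading-corrected image.
    """

    label: int
    coords: np.ndarray                  # (N, 2) row/col pixel coordinates
    centroid: Tuple[float, float]
    bbox: Tuple[int, int, int, int]     # min_row, min_col, max_row, max_col (exclusive)
    area_px: int
    mean_intensity: float
    min_intensity: float
    max_intensity: float
    median_intensity: float
    std_intensity: float
    major_axis_px: float
    minor_axis_px: float
    eccentricity: float
    equivalent_diameter_px: float
    extent: float
    perimeter_px: float

    @classmethod
    def from_coords(cls, label: int, coords: np.ndarray,
                    image: np.ndarray | None = None) -> "NucleusRecord":
        """Build a record from bare pixel coordinates (used by tests and by
        graph construction on externally produced label images)."""
        coords = np.asarray(coords, dtype=np.intp)
        if coords.size == 0:
            raise ValueError("nucleus must have at least one pixel")
        rmin, cmin = coords.min(axis=0)
        rmax, cmax = coords.max(axis=0)
        shape = (int(rmax) + 1, int(cmax) + 1)
        m = np.zeros(shape, dtype=np.uint8)
        m[coords[:, 0], coords[:, 1]] = 1
        rp = regionprops(m, intensity_image=image[:shape[0], :shape[1]]
                         if image is not None else None)[0]
        return cls._from_regionprop(label, rp, image)

    @classmethod
    def _from_regionprop(cls, label: int, rp, image: np.ndarray | None) -> "NucleusRecord":
        coords = np.asarray(rp.coords, dtype=np.intp)
        if image is not None:
            vals = np.asarray(image)[coords[:, 0], coords[:, 1]].astype(float)
        else:
            vals = np.zeros(len(coords))
        return cls(
            label=int(label),
            coords=coords,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            bbox=tuple(int(v) for v in rp.bbox),
            area_px=int(rp.area),
            mean_intensity=float(vals.mean()),
            min_intensity=float(vals.min()),
            max_intensity=float(vals.max()),
            median_intensity=float(np.median(vals)),
            std_intensity=float(vals.std()),
            major_axis_px=float(rp.axis_major_length),
            minor_axis_px=float(rp.axis_minor_length),
            eccentricity=float(rp.eccentricity),
            equivalent_diameter_px=float(rp.equivalent_diameter_area),
            extent=float(rp.extent),
            perimeter_px=float(rp.perimeter),
        )


def split_by_brightness(image: np.ndarray, mask: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Split masked objects into bright/dark sub-images at their Otsu level.

    The threshold is computed over the masked (non-background) pixels; each
    8-connected mask component then goes wholly to the bright output when
    its mean masked intensity reaches the threshold, else to the dark one —
    the populations to separate are whole bright or dark *objects*, and a
    pixel-level cut would slice mid-intensity nuclei (bright center, dim
    rim) in two.  The outputs are zero outside their partition, their
    supports are disjoint and their union is the masked image.  A constant
    masked region goes entirely to the dark output with a warning.
    """
    img = np.asarray(image)
    m = np.asarray(mask).astype(bool)
    bright = np.zeros_like(img)
    dark = np.zeros_like(img)
    vals = img[m]
    if vals.size == 0:
        return bright, dark
    try:
        t = otsu_threshold(vals)
    except ValueError:
        warnings.warn("constant masked region: no brightness split possible")
        dark[m] = img[m]
        return bright, dark
    comp = cc_label(m, connectivity=2)
    n = comp.max()
    sums = np.bincount(comp.ravel(), weights=img.ravel().astype(float),
                       minlength=n + 1)
    counts = np.bincount(comp.ravel(), minlength=n + 1)
    means = np.divide(sums, np.maximum(counts, 1))
    is_bright = means >= t
    is_bright[0] = False
    hi = m & is_bright[comp]
    lo = m & ~is_bright[comp]
    bright[hi] = img[hi]
    dark[lo] = img[lo]
    return bright, dark


def h_maxima_seeds(image: np.ndarray, h: int) -> np.ndarray:
    """Labeled watershed seeds from the h-maxima transform.

    The image is morphologically reconstructed (by dilation) from itself
    minus ``h``, which levels every peak shallower than ``h`` grey levels;
    the regional maxima of the reconstruction — one filled plateau per
    surviving peak — are labeled with 8-connectivity.  (Taking the maxima
    of the reconstruction rather than the ``residue >= h`` set keeps each
    noisy plateau as a single connected seed.)  A constant image yields a
    single seed spanning it: every pixel is a regional maximum.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    img = np.asarray(image).astype(np.int32)
    if img.min() == img.max():
        # constant image: the whole frame is one plateau -> one seed
        return np.ones(img.shape, dtype=np.int32)
    marker = np.clip(img - h, 0, None)
    rec = reconstruction(marker, img, method="dilation",
                         footprint=np.ones((3, 3)))
    peaks = local_maxima(rec, connectivity=2, allow_borders=True)
    return cc_label(peaks, connectivity=2).astype(np.int32)


def seeded_watershed(image: np.ndarray, seeds: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Watershed on the inverted intensity, flooding from the given seeds.

    Every masked pixel reachable from a seed gets that seed's label; pixels
    outside the mask stay 0.  Raises ``ValueError`` when no seed lies inside
    the mask.
    """
    img = np.asarray(image)
    m = np.asarray(mask).astype(bool)
    seeds = np.asarray(seeds).copy()
    seeds[~m] = 0
    if seeds.max() == 0:
        raise ValueError("seeded watershed requires at least one seed inside the mask")
    inverted = (255 - img.astype(np.int32))
    return watershed(inverted, markers=seeds, mask=m, connectivity=2).astype(np.int32)


def segment_nuclei(image: np.ndarray, mask: np.ndarray, h: int = 10,
                   smooth_kernel: int = 3) -> Tuple[np.ndarray, List[NucleusRecord]]:
    """Segment all nuclei in a preprocessed core.

    Splits the masked image into bright/dark populations, seeds each with
    the h-maxima transform and runs the seeded watershed per population,
    then merges the label images with disjoint label ranges.  Seeding and
    flooding run on a median-smoothed copy (``smooth_kernel``; <= 1
    disables) so pixel noise cannot spawn spurious seeds; the returned
    :class:`NucleusRecord` intensity statistics are taken from ``image``
    itself — the shading-corrected, pre-median intensity image.
    """
    from .preprocess import median_smooth

    img = np.asarray(image)
    m = np.asarray(mask).astype(bool)
    labels = np.zeros(img.shape, dtype=np.int32)
    if not m.any():
        return labels, []
    topo = median_smooth(img, smooth_kernel) if smooth_kernel > 1 else img
    bright, dark = split_by_brightness(topo, m)
    offset = 0
    for part in (dark, bright):
        part_mask = m & (part > 0)
        if not part_mask.any():
            continue
        seeds = h_maxima_seeds(part, h)
        seeds[~part_mask] = 0
        if seeds.max() == 0:
            continue
        ws = seeded_watershed(part, seeds, part_mask)
        ws[ws > 0] += offset
        labels[ws > 0] = ws[ws > 0]
        offset = labels.max()
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)
    return labels, records_from_labels(labels, img)


def records_from_labels(labels: np.ndarray, image: np.ndarray
                        ) -> List[NucleusRecord]:
    """NucleusRecords for every positive label of a label image."""
    rps = regionprops(np.asarray(labels))
    return [NucleusRecord._from_regionprop(rp.label, rp, image) for rp in rps]


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class SegmentationReport:
    """Correct / over- / under-segmented counts with percentage fields."""

    total: int
    correct: int
    over_segmented: int
    under_segmented: int

    def __post_init__(self):
        if self.correct + self.over_segmented + self.under_segmented != self.total:
            raise ValueError("segmentation counts must partition the total")

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.total if self.total else 0.0

    @property
    def pct_correct(self) -> float:
        return self._pct(self.correct)

    @property
    def pct_over(self) -> float:
        return self._pct(self.over_segmented)

    @property
    def pct_under(self) -> float:
        return self._pct(self.under_segmented)

    def as_dict(self) -> Dict[str, float]:
        return {
            "total": self.total,
            "correct": self.correct,
            "over_segmented": self.over_segmented,
            "under_segmented": self.under_segmented,
            "pct_correct": self.pct_correct,
            "pct_over": self.pct_over,
            "pct_under": self.pct_under,
        }


def evaluate_segmentation(result: np.ndarray,
                          truth: "GroundTruth | np.ndarray") -> SegmentationReport:
    """Score a segmentation against ground-truth nuclei by maximal overlap.

    Each result label is matched to the truth nucleus it overlaps most, and
    each truth nucleus to the result label covering it most.  A truth
    nucleus whose best-covering result label is shared with another truth
    nucleus (or that no result label touches) counts under-segmented; one
    claimed as best match by two or more result labels counts
    over-segmented; the rest are correct one-to-one matches.
    """
    truth_labels = truth.label_image if isinstance(truth, GroundTruth) else np.asarray(truth)
    result = np.asarray(result)
    if result.shape != truth_labels.shape:
        raise ValueError("result and truth label images must share dimensions")

    t_ids = np.unique(truth_labels)
    t_ids = t_ids[t_ids > 0]
    total = int(t_ids.size)
    if total == 0:
        return SegmentationReport(0, 0, 0, 0)

    both = (truth_labels > 0) & (result > 0)
    pairs, counts = np.unique(
        np.stack([truth_labels[both], result[both]]), axis=1, return_counts=True)
    # overlap table: truth id, result id, pixel count
    t_of, r_of, n_of = pairs[0], pairs[1], counts

    # best result label per truth nucleus
    best_r: Dict[int, int] = {}
    best_n: Dict[int, int] = {}
    for t, r, n in zip(t_of, r_of, n_of):
        if n > best_n.get(t, 0) or (n == best_n.get(t, 0) and r < best_r.get(t, np.iinfo(np.int64).max)):
            best_n[t], best_r[t] = n, r
    # majority truth per result label
    maj_t: Dict[int, int] = {}
    maj_n: Dict[int, int] = {}
    for t, r, n in zip(t_of, r_of, n_of):
        if n > maj_n.get(r, 0) or (n == maj_n.get(r, 0) and t < maj_t.get(r, np.iinfo(np.int64).max)):
            maj_n[r], maj_t[r] = n, t

    claims: Dict[int, int] = {}          # result label -> #truth nuclei claiming it
    for t in t_ids:
        if t in best_r:
            claims[best_r[t]] = claims.get(best_r[t], 0) + 1
    votes: Dict[int, int] = {}           # truth id -> #result labels majority-covering it
    for r, t in maj_t.items():
        votes[t] = votes.get(t, 0) + 1

    correct = over = under = 0
    for t in t_ids:
        t = int(t)
        if t not in best_r or claims[best_r[t]] >= 2:
            under += 1                   # merged with a neighbour or missed
        elif votes.get(t, 0) >= 2:
            over += 1                    # split across result labels
        else:
            correct += 1
    return SegmentationReport(total, correct, over, under)
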