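"""Synthetic DAPI-like TMA core images with per-nucleus ground truth.

Real fluorescence cores of triple-negative breast cancer show two nuclear
populations in the DAPI channel: tumor nuclei, which are darker and grow in
tight clusters whose nearest pixels are only a few pixels apart, and stromal
nuclei, which are brighter and sparser — elongated fibroblasts and small,
bright, round lymphocytes among them.  This module renders that statistical
structure (plus a smooth multiplicative shading field, additive Gaussian
noise and saturated "overstained" blobs) so every downstream stage of the
pipeline can be exercised with exact ground truth and no real slides.

The generator is fully determined by ``SyntheticCoreSpec.rng_seed``: one
:class:`numpy.random.Generator` stream per core, consumed in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk

__all__ = [
    "SyntheticCoreSpec",
    "GroundTruth",
    "PlacementError",
    "generate_core",
    "default_spec",
    "well_separated_spec",
]

TUMOR = "tumor"
STROMA = "stroma"
FIBROBLAST = "fibroblast"
LYMPHOCYTE = "lymphocyte"
GENERIC_STROMA = "generic_stroma"


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without violating spacing rules."""


@dataclass(frozen=True)
class SyntheticCoreSpec:
    """Parameters of one synthetic core.

    Intensities are 8-bit levels.  ``tumor_mean_intensity`` must be below
    ``stroma_mean_intensity``: tumor nuclei are the darker population.
    ``fraction_clustered_stroma`` controls how many generic stromal nuclei
    are laid down in loose pairs/triples (pixel gaps <= 4, so they link into
    small stromal subgraphs); the remainder are solitary with gaps > 4.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    core_radius_px: int = 230
    n_tumor_clusters: int = 6
    tumor_nuclei_per_cluster: int = 8
    tumor_mean_intensity: int = 95
    stroma_mean_intensity: int = 165
    n_stroma_nuclei: int = 40
    fraction_fibroblast: float = 0.2
    fraction_lymphocyte: float = 0.2
    fraction_clustered_stroma: float = 0.4
    shading_amplitude: float = 0.15
    noise_sd: float = 3.0
    n_overstained_blobs: int = 1
    background_level: int = 10
    intensity_sd: float = 7.0
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.tumor_mean_intensity <= 255
                and 0 <= self.stroma_mean_intensity <= 255):
            raise ValueError("mean intensities must be 8-bit levels")
        if self.tumor_mean_intensity >= self.stroma_mean_intensity:
            raise ValueError("tumor nuclei must be darker than stromal nuclei")
        for name in ("n_tumor_clusters", "tumor_nuclei_per_cluster",
                     "n_stroma_nuclei", "n_overstained_blobs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_fibroblast", "fraction_lymphocyte",
                     "fraction_clustered_stroma", "shading_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.fraction_fibroblast + self.fraction_lymphocyte > 1.0 + 1e-12:
            raise ValueError("fibroblast + lymphocyte fractions must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.image_height_px, self.image_width_px) < 2 * self.core_radius_px // 2:
            # only guard absurd geometry; the core disc may be cropped by the frame
            pass


@dataclass
class GroundTruth:
    """Per-nucleus ground truth for one rendered core.

    ``label_image`` holds 0 for background and k for nucleus k; ``classes``
    and ``subtypes`` map each positive label to its tissue class/subtype.
    Tumor-class centroids always lie inside ``tumor_region_mask``.
    """

    label_image: np.ndarray
    classes: Dict[int, str] = field(default_factory=dict)
    subtypes: Dict[int, str] = field(default_factory=dict)
    tumor_region_mask: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_nuclei(self) -> int:
        return len(self.classes)

    def centroids(self) -> Dict[int, Tuple[float, float]]:
        out = {}
        for lab in self.classes:
            rr, cc = np.nonzero(self.label_image == lab)
            out[lab] = (float(rr.mean()), float(cc.mean()))
        return out


def default_spec(**overrides) -> SyntheticCoreSpec:
    """The default stated world: clustered dark tumor, brighter sparse stroma."""
    return replace(SyntheticCoreSpec(), **overrides)


def well_separated_spec(**overrides) -> SyntheticCoreSpec:
    """A core of solitary, well-spaced nuclei (for segmentation benchmarks)."""
    base = dict(
        n_tumor_clusters=25,
        tumor_nuclei_per_cluster=1,
        n_stroma_nuclei=25,
        fraction_clustered_stroma=0.0,
        n_overstained_blobs=0,
    )
    base.update(overrides)
    return replace(SyntheticCoreSpec(), **base)


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_coords(center_r: float, center_c: float, a: float, b: float,
                    theta: float, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a filled rotated ellipse clipped to the frame."""
    rr, cc = draw_ellipse(center_r, center_c, a, b, shape=shape, rotation=theta)
    return rr, cc


def _min_l1_to(occupied_dt: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> float:
    """Minimum city-block distance from candidate pixels to occupied pixels,
    read off a precomputed chamfer (taxicab) distance transform."""
    if occupied_dt is None:
        return np.inf
    return float(occupied_dt[rr, cc].min())


def _l1_dt(mask: np.ndarray) -> np.ndarray:
    """City-block distance to the nearest True pixel (inf if mask empty)."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndi.distance_transform_cdt(~mask, metric="taxicab").astype(float)


class _Canvas:
    """Mutable placement state: label image + lazily refreshed distance maps."""

    def __init__(self, shape: Tuple[int, int]):
        self.shape = shape
        self.labels = np.zeros(shape, dtype=np.int32)
        self._dt = np.full(shape, np.inf)
        self._dirty = False

    def dist_to_all(self, rr, cc) -> float:
        if self._dirty:
            self._dt = _l1_dt(self.labels > 0)
            self._dirty = False
        return float(self._dt[rr, cc].min())

    def paint(self, rr, cc, label: int) -> None:
        self.labels[rr, cc] = label
        self._dirty = True


def _inside_core(rr, cc, center, radius) -> bool:
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return bool((d2 <= radius ** 2).all())


# ---------------------------------------------------------------------------
# generator

_MAX_TRIES = 250

# relative center-to-rim intensity contrast of a rendered nucleus
_RADIAL_CONTRAST = 0.12


def generate_core(spec: SyntheticCoreSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Render one synthetic core and its ground truth.

    Returns ``(image, truth)`` where ``image`` is a 2-D uint8 array and
    ``truth`` carries the label image, per-nucleus class/subtype and the
    tumor-region mask.  Identical specs (seed included) give bit-identical
    output.

    Raises
    ------
    PlacementError
        If nuclei cannot be placed after bounded retries (over-packed core).
    ValueError
        If the spec violates its invariants.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = (spec.image_height_px, spec.image_width_px)
    center = (shape[0] / 2.0, shape[1] / 2.0)
    canvas = _Canvas(shape)

    classes: Dict[int, str] = {}
    subtypes: Dict[int, str] = {}
    intensities: Dict[int, float] = {}
    next_label = 1

    def draw_intensity(mean: float, lo: float = 30.0, hi: float = 250.0) -> float:
        return float(np.clip(rng.normal(mean, spec.intensity_sd), lo, hi))

    # --- tumor clusters -----------------------------------------------------
    cluster_extent = 14.0 * np.sqrt(max(spec.tumor_nuclei_per_cluster, 1)) \
        + (10.0 if spec.tumor_nuclei_per_cluster > 1 else 0.0)
    cluster_sep = 2.0 * cluster_extent + 6.0
    max_rad = max(spec.core_radius_px - cluster_extent - 4.0,
                  0.3 * spec.core_radius_px)
    cluster_centers = []
    for _ in range(spec.n_tumor_clusters):
        for _try in range(_MAX_TRIES):
            ang = rng.uniform(0, 2 * np.pi)
            rad = min(max_rad, spec.core_radius_px * 0.78) * np.sqrt(rng.uniform())
            cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= cluster_sep
                   for p in cluster_centers):
                cluster_centers.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_tumor_clusters} tumor clusters "
                f"with separation {cluster_sep:.0f}px in this core")

    tumor_labels = []
    for ccen in cluster_centers:
        members: list[Tuple[np.ndarray, np.ndarray]] = []
        cluster_mask = np.zeros(shape, dtype=bool)
        cluster_dt = None
        for k in range(spec.tumor_nuclei_per_cluster):
            placed = False
            for _try in range(_MAX_TRIES):
                a = rng.uniform(10.0, 14.0)
                b = rng.uniform(8.0, 11.0)
                theta = rng.uniform(0, np.pi)
                if k == 0:
                    pos = ccen
                else:
                    base_rr, base_cc = members[rng.integers(len(members))]
                    brow = float(base_rr.mean())
                    bcol = float(base_cc.mean())
                    ang = rng.uniform(0, 2 * np.pi)
                    step = rng.uniform(18.0, 26.0)
                    pos = (brow + step * np.sin(ang), bcol + step * np.cos(ang))
                    if np.hypot(pos[0] - ccen[0], pos[1] - ccen[1]) > cluster_extent:
                        continue  # keep the cluster compact around its seed
                if k > 0:
                    # walk the candidate along the approach axis until its
                    # gap to the cluster lands in the 2..4 px link window
                    ok = False
                    for _adj in range(6):
                        rr, cc = _ellipse_coords(pos[0], pos[1], a, b, theta, shape)
                        if rr.size < 150 or not _inside_core(rr, cc, center,
                                                            spec.core_radius_px):
                            break
                        d_cluster = _min_l1_to(cluster_dt, rr, cc)
                        if 2.0 <= d_cluster <= 4.0:
                            ok = True
                            break
                        vec = np.array([pos[0] - brow, pos[1] - bcol])
                        norm = np.hypot(*vec) or 1.0
                        pos = (pos[0] - vec[0] / norm * (d_cluster - 3.0),
                               pos[1] - vec[1] / norm * (d_cluster - 3.0))
                    if not ok:
                        continue
                    if canvas.dist_to_all(rr, cc) < d_cluster:
                        continue  # nearer to foreign tissue than own cluster
                else:
                    rr, cc = _ellipse_coords(pos[0], pos[1], a, b, theta, shape)
                    if rr.size < 150 or not _inside_core(rr, cc, center,
                                                         spec.core_radius_px):
                        continue
                    if canvas.dist_to_all(rr, cc) <= 6:
                        continue  # keep clusters clear of everything else
                lab = next_label
                canvas.paint(rr, cc, lab)
                cluster_mask[rr, cc] = True
                cluster_dt = _l1_dt(cluster_mask)
                members.append((rr, cc))
                classes[lab] = TUMOR
                subtypes[lab] = TUMOR
                intensities[lab] = draw_intensity(spec.tumor_mean_intensity)
                tumor_labels.append(lab)
                next_label += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    "tumor nucleus placement failed after bounded retries; "
                    "core is over-packed for this spec")

    # --- stromal nuclei -----------------------------------------------------
    n_fib = int(round(spec.fraction_fibroblast * spec.n_stroma_nuclei))
    n_lym = int(round(spec.fraction_lymphocyte * spec.n_stroma_nuclei))
    n_gen = max(spec.n_stroma_nuclei - n_fib - n_lym, 0)
    n_grouped = int(round(spec.fraction_clustered_stroma * n_gen))

    def place_stroma(subtype: str, near: Tuple[np.ndarray, np.ndarray] | None,
                     group_dt: np.ndarray | None) -> Tuple[int, Tuple[np.ndarray, np.ndarray]]:
        nonlocal next_label
        for _try in range(_MAX_TRIES):
            if subtype == FIBROBLAST:
                a, b = rng.uniform(16.0, 21.0), rng.uniform(4.2, 5.5)
                mean = spec.stroma_mean_intensity
            elif subtype == LYMPHOCYTE:
                a = b = rng.uniform(8.0, 9.5)  # area ~200-280 px, always < 500
                mean = min(spec.stroma_mean_intensity + 55, 250)
            else:
                a, b = rng.uniform(9.0, 12.0), rng.uniform(7.0, 9.5)
                mean = spec.stroma_mean_intensity
            theta = rng.uniform(0, np.pi)
            if near is None:
                ang = rng.uniform(0, 2 * np.pi)
                rad = spec.core_radius_px * 0.92 * np.sqrt(rng.uniform())
                pos = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
            else:
                brow, bcol = float(near[0].mean()), float(near[1].mean())
                ang = rng.uniform(0, 2 * np.pi)
                step = rng.uniform(18.0, 25.0)
                pos = (brow + step * np.sin(ang), bcol + step * np.cos(ang))
            if near is None:
                rr, cc = _ellipse_coords(pos[0], pos[1], a, b, theta, shape)
                if rr.size < 150 or not _inside_core(rr, cc, center, spec.core_radius_px):
                    continue
                if canvas.dist_to_all(rr, cc) <= 6:  # solitary: gaps > 4
                    continue
            else:
                ok = False
                for _adj in range(6):
                    rr, cc = _ellipse_coords(pos[0], pos[1], a, b, theta, shape)
                    if rr.size < 150 or not _inside_core(rr, cc, center,
                                                         spec.core_radius_px):
                        break
                    d_group = _min_l1_to(group_dt, rr, cc)
                    if 2.0 <= d_group <= 4.0:
                        ok = True
                        break
                    vec = np.array([pos[0] - brow, pos[1] - bcol])
                    norm = np.hypot(*vec) or 1.0
                    pos = (pos[0] - vec[0] / norm * (d_group - 3.0),
                           pos[1] - vec[1] / norm * (d_group - 3.0))
                if not ok or canvas.dist_to_all(rr, cc) < d_group:
                    continue
            lab = next_label
            canvas.paint(rr, cc, lab)
            classes[lab] = STROMA
            subtypes[lab] = subtype
            intensities[lab] = draw_intensity(mean)
            if subtype == LYMPHOCYTE:
                # lymphocytes must outshine every other nucleus
                intensities[lab] = float(np.clip(intensities[lab],
                                                 spec.stroma_mean_intensity + 35, 250))
            next_label += 1
            return lab, (rr, cc)
        raise PlacementError("stromal nucleus placement failed; core over-packed")

    # loose stromal groups of 2-3 (linkable pairs give the stroma class graphs)
    placed_grouped = 0
    while placed_grouped < n_grouped:
        size = min(int(rng.integers(2, 4)), n_grouped - placed_grouped)
        if size < 2:
            size = 2 if n_grouped - placed_grouped >= 2 else 1
        group_mask = np.zeros(shape, dtype=bool)
        group_dt = None
        anchor = None
        for i in range(size):
            lab, (rr, cc) = place_stroma(GENERIC_STROMA,
                                         anchor if i > 0 else None, group_dt)
            group_mask[rr, cc] = True
            group_dt = _l1_dt(group_mask)
            anchor = (rr, cc)
            placed_grouped += 1
    for _ in range(n_gen - n_grouped):
        place_stroma(GENERIC_STROMA, None, None)
    for _ in range(n_fib):
        place_stroma(FIBROBLAST, None, None)
    for _ in range(n_lym):
        place_stroma(LYMPHOCYTE, None, None)

    labels = canvas.labels

    # --- overstained blobs (saturated, not nuclei) --------------------------
    overstain = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_overstained_blobs):
        for _try in range(_MAX_TRIES):
            ang = rng.uniform(0, 2 * np.pi)
            rad = spec.core_radius_px * 0.85 * np.sqrt(rng.uniform())
            pos = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
            blob_r = rng.uniform(28.0, 34.0)
            rr, cc = _ellipse_coords(pos[0], pos[1], blob_r, blob_r, 0.0, shape)
            if not _inside_core(rr, cc, center, spec.core_radius_px):
                continue
            if canvas.dist_to_all(rr, cc) <= 6 or overstain[rr, cc].any():
                continue
            overstain[rr, cc] = True  # saturated debris, not a nucleus label
            break

    # --- render -------------------------------------------------------------
    img = np.full(shape, float(spec.background_level))
    for lab, inten in intensities.items():
        rr, cc = np.nonzero(labels == lab)
        r0, c0 = rr.mean(), cc.mean()
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        dmax2 = d2.max() if d2.max() > 0 else 1.0
        # smooth radial chromatin profile: bright center, dimmer rim; gives
        # each nucleus one dominant intensity peak for h-maxima seeding
        img[rr, cc] = inten * (1.0 + _RADIAL_CONTRAST * (1.0 - 2.0 * d2 / dmax2))

    # smooth multiplicative shading: one broad Gaussian bump, range [1-A, 1+A]
    if spec.shading_amplitude > 0:
        gr = rng.uniform(0.25, 0.75) * shape[0]
        gc = rng.uniform(0.25, 0.75) * shape[1]
        sigma = 0.6 * max(shape)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        bump = np.exp(-((yy - gr) ** 2 + (xx - gc) ** 2) / (2 * sigma ** 2))
        bump = (bump - bump.min()) / max(bump.max() - bump.min(), 1e-12)
        field_ = 1.0 + spec.shading_amplitude * (2.0 * bump - 1.0)
        img *= field_
    else:
        rng.uniform(0.25, 0.75)  # keep the stream layout stable
        rng.uniform(0.25, 0.75)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    else:
        rng.normal(0.0, 1.0, size=shape)

    # nuclei cap at 254: level 255 is reserved for overstained artifacts
    img = np.clip(np.rint(img), 0, 254).astype(np.uint8)
    img[overstain] = 255

    tumor_mask = np.isin(labels, [l for l, c in classes.items() if c == TUMOR])
    tumor_region = dilation(tumor_mask, disk(5)) if tumor_mask.any() \
        else np.zeros(shape, dtype=bool)

    truth = GroundTruth(label_image=labels, classes=classes, subtypes=subtypes,
                        tumor_region_mask=tumor_region)
    return img, truth
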