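"""Nucleus segmentation: the per-field cell-count denominator.

Segments DNA-dye (Hoechst) stained nuclei with a classical pipeline:
Gaussian smoothing, morphological background subtraction, robust global
thresholding, hole filling, physical area filtering, optional watershed
splitting of touching nuclei seeded at distance-transform maxima, and
optional removal of border-touching objects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_li, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, opening, remove_small_objects
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .config import NucleiParams
from .errors import InputError, ParameterError

__all__ = ["NucleiResult", "correct_illumination", "segment_nuclei"]


@dataclass
class NucleiResult:
    """Labelled nucleus mask with per-nucleus centroids and physical areas.

    Labels are contiguous 1..N; ``count`` equals N; centroids are (row, col)
    in pixel coordinates; areas are in µm².
    """

    label_mask: np.ndarray
    count: int
    centroids: List[Tuple[float, float]]
    areas_um2: List[float]

    def __post_init__(self) -> None:
        labels = np.unique(self.label_mask)
        labels = labels[labels > 0]
        n = len(labels)
        if not (self.count == n == len(self.centroids) == len(self.areas_um2)):
            raise InputError("inconsistent NucleiResult: count/centroids/areas disagree")
        if n and not np.array_equal(labels, np.arange(1, n + 1)):
            raise InputError("labels must be contiguous 1..N")


def correct_illumination(channel: np.ndarray, background_radius_px: float) -> np.ndarray:
    """Subtract a morphological-opening background estimate.

    The background is a grayscale opening with a disk of the given radius
    (computed with a decomposed disk footprint for speed); the radius must
    exceed the radius of the objects of interest so they are removed from
    the background estimate and survive the subtraction.  Output is clipped
    at zero.
    """
    if background_radius_px <= 0:
        raise ParameterError("background_radius_px must be > 0")
    channel = np.asarray(channel, dtype=np.float64)
    footprint = disk(int(round(background_radius_px)), decomposition="sequence")
    background = opening(channel, footprint)
    return np.clip(channel - background, 0.0, None)


def _threshold(corrected: np.ndarray, params: NucleiParams) -> float:
    if params.threshold_method == "otsu":
        base = threshold_otsu(corrected)
    elif params.threshold_method == "li":
        base = threshold_li(corrected)
    else:
        raise ParameterError(f"unknown threshold_method {params.threshold_method!r}")
    med = np.median(corrected)
    mad = np.median(np.abs(corrected - med))
    # robust floor: on structure-free fields Otsu splits the noise itself;
    # requiring the threshold to clear the noise body keeps such fields empty
    return float(max(base, med + 4.0 * mad) + params.threshold_offset * mad)


def _axis_ratio(m: dict) -> float:
    """Major/minor axis ratio of a pixel region from accumulated moments."""
    n = m["n"]
    mr, mc = m["sr"] / n, m["sc"] / n
    crr = m["srr"] / n - mr * mr
    ccc = m["scc"] / n - mc * mc
    crc = m["src"] / n - mr * mc
    tr, det = crr + ccc, crr * ccc - crc * crc
    disc = max(tr * tr / 4.0 - det, 0.0) ** 0.5
    l1, l2 = tr / 2.0 + disc, max(tr / 2.0 - disc, 1e-9)
    return (l1 / l2) ** 0.5


def _split_touching(
    mask: np.ndarray, min_seed_sep_px: float, max_axis_ratio: float
) -> np.ndarray:
    """Watershed split of fused blobs, seeded at distance-transform maxima.

    Candidate seeds are the strict 3x3 local maxima of the Euclidean
    distance transform.  Candidates are accepted greedily, deepest first,
    absorbing any later candidate closer than ``min_seed_sep_px`` to an
    accepted seed (plateau and quantisation duplicates); a watershed on
    the negated distance assigns every mask pixel to its seed.  Finally,
    adjacent fragments are re-merged whenever their union is still as
    round as a single nucleus can be (major/minor axis ratio below
    ``max_axis_ratio``): a noise-deformed single nucleus can carry two
    well-separated distance maxima, but its fragments reunite into a
    compact region, whereas genuinely fused nuclei form an elongated
    union and stay split.  All orderings are fixed, so the result is
    deterministic; ties between equal-distance basins resolve to the
    lower (raster-order) label.
    """
    distance = ndi.distance_transform_edt(mask)
    blob_labels = sk_label(mask, connectivity=2)
    coords = peak_local_max(
        distance,
        footprint=np.ones((3, 3), dtype=bool),
        labels=blob_labels,
        exclude_border=False,
    )
    if len(coords) == 0:
        return blob_labels
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    n = len(coords)
    peak_val = distance[tuple(coords.T)]

    # greedy deepest-first acceptance with minimum seed spacing
    sep2 = float(min_seed_sep_px) ** 2
    accept_order = np.lexsort((coords[:, 1], coords[:, 0], -peak_val))
    assigned = np.zeros(n + 1, dtype=np.int32)  # candidate -> accepted seed
    accepted: list = []
    for idx in accept_order:
        cand = idx + 1
        pc = coords[idx]
        home = 0
        for acc in accepted:
            pa = coords[acc - 1]
            if (pc[0] - pa[0]) ** 2 + (pc[1] - pa[1]) ** 2 < sep2:
                home = acc
                break
        if home == 0:
            accepted.append(cand)
            home = cand
        assigned[cand] = home

    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, n + 1)
    basins = watershed(-distance, markers=markers, mask=mask, connectivity=2)
    labels = assigned[basins]

    # compactness merge of adjacent fragments (moments are additive, so
    # unions are evaluated without touching pixel data again)
    labs = np.unique(labels)
    labs = labs[labs > 0]
    rr, cc = np.nonzero(labels)
    vals = labels[rr, cc]
    moments = {}
    for lab in labs:
        sel = vals == lab
        r, c = rr[sel].astype(np.float64), cc[sel].astype(np.float64)
        moments[int(lab)] = dict(
            n=len(r), sr=r.sum(), sc=c.sum(),
            srr=(r * r).sum(), scc=(c * c).sum(), src=(r * c).sum(),
        )
    adjacent = set()
    for sl_a, sl_b in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
    ):
        la, lb = labels[sl_a], labels[sl_b]
        sel = (la > 0) & (lb > 0) & (la != lb)
        for a, b in zip(la[sel], lb[sel]):
            adjacent.add((int(min(a, b)), int(max(a, b))))

    parent = {int(lab): int(lab) for lab in labs}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    changed = True
    while changed:
        changed = False
        for a, b in sorted(adjacent):
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            union = {k: moments[ra][k] + moments[rb][k] for k in moments[ra]}
            if _axis_ratio(union) < max_axis_ratio:
                lo, hi = min(ra, rb), max(ra, rb)
                parent[hi] = lo
                moments[lo] = union
                changed = True

    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for lab in labs:
        lut[lab] = find(int(lab))
    return lut[labels]


def segment_nuclei(
    channel: np.ndarray,
    params: NucleiParams = NucleiParams(),
    pixel_size_um: float = 0.65,
) -> NucleiResult:
    """Segment nuclei from the DNA-dye channel.

    Pipeline: Gaussian smoothing -> illumination correction -> global
    threshold (Otsu by default, plus an offset in MAD units) -> hole
    filling -> area filtering -> optional watershed splitting of touching
    nuclei -> optional border exclusion -> relabelling 1..N.

    An all-zero (or structure-free) channel yields count 0; NaNs raise.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise InputError("channel must be 2-D")
    if np.isnan(channel).any():
        raise InputError("channel contains NaN")
    if channel.min() < 0:
        raise InputError("channel contains negative intensities")

    empty = NucleiResult(np.zeros(channel.shape, np.int32), 0, [], [])
    if channel.max() == channel.min():
        return empty

    smoothed = (
        gaussian(channel, sigma=params.smoothing_sigma_px, preserve_range=True)
        if params.smoothing_sigma_px > 0
        else channel
    )
    corrected = correct_illumination(smoothed, params.background_radius_px)
    if corrected.max() == 0:
        return empty

    mask = corrected > _threshold(corrected, params)
    mask = ndi.binary_fill_holes(mask)

    # physical area band
    px_area_um2 = pixel_size_um**2
    min_px = max(1, int(math.ceil(params.min_area_um2 / px_area_um2)))
    max_px = int(math.floor(params.max_area_um2 / px_area_um2))
    mask = remove_small_objects(mask, max_size=min_px - 1, connectivity=2)
    lbl = sk_label(mask, connectivity=2)
    sizes = np.bincount(lbl.ravel())
    too_big = np.flatnonzero(sizes > max_px)
    too_big = too_big[too_big > 0]
    if too_big.size:
        mask &= ~np.isin(lbl, too_big)

    if params.split_touching:
        labels = _split_touching(
            mask, params.min_seed_separation_px, params.max_axis_ratio
        )
    else:
        labels = sk_label(mask, connectivity=2)

    if params.exclude_border:
        labels = clear_border(labels)

    # drop fragments below the minimum area that splitting/border removal
    # may have produced, then relabel 1..N
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_px)
    small = small[small > 0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)

    props = regionprops(labels)
    centroids = [tuple(p.centroid) for p in props]
    areas = [float(p.area) * px_area_um2 for p in props]
    return NucleiResult(labels, len(props), centroids, areas)
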