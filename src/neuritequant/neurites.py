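"""Neurite segmentation: ridge enhancement, skeletonization and length.

Neurites are thin curvilinear projections.  They are detected with a
multi-scale Hessian-eigenvalue tubeness (Sato) filter, thresholded with
hysteresis in robust units, restricted to regions outside cell bodies
(nuclei dilated by a soma margin), reduced to a one-pixel-wide skeleton,
pruned of short terminal spurs, and measured with the 8-connected
step-weight convention (1 for orthogonal steps, sqrt(2) for diagonal
steps, each unique adjacent pixel pair counted once).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, sato
from skimage.measure import label as sk_label
from skimage.morphology import closing, dilation, disk, remove_small_objects, skeletonize

from .config import NeuriteParams
from .errors import ContractViolationError, InputError, ParameterError
from .image_io import ImageField
from .nuclei import NucleiResult

__all__ = [
    "NeuriteSkeleton",
    "SkeletonComponent",
    "enhance_ridges",
    "segment_neurites",
    "skeleton_length",
]

SQRT2 = math.sqrt(2.0)

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass
class SkeletonComponent:
    component_id: int
    pixels: np.ndarray  # (k, 2) row/col coordinates
    length_um: float


@dataclass
class NeuriteSkeleton:
    """One-pixel-wide neurite skeleton with branch/endpoint topology."""

    skeleton_mask: np.ndarray
    components: List[SkeletonComponent]
    branch_points: List[Tuple[int, int]]
    endpoints: List[Tuple[int, int]]
    pixel_size_um: float

    @property
    def total_length_um(self) -> float:
        return float(sum(c.length_um for c in self.components))


# ---------------------------------------------------------------------------
# ridge enhancement


def enhance_ridges(channel: np.ndarray, scales_px, polarity: str = "bright_on_dark") -> np.ndarray:
    """Multi-scale tubeness response (per-pixel maximum over scales).

    Responds to curvilinear structures of width comparable to each scale.
    ``dark_on_bright`` computes the response on the inverted channel.
    """
    scales = list(scales_px)
    if len(scales) == 0:
        raise ParameterError("scales_px must be nonempty")
    if any(s <= 0 for s in scales):
        raise ParameterError("all scales must be > 0")
    if polarity not in ("bright_on_dark", "dark_on_bright"):
        raise ParameterError(f"unknown polarity {polarity!r}")
    channel = np.asarray(channel, dtype=np.float64)
    if channel.max() == channel.min():
        return np.zeros_like(channel)
    response = sato(
        channel,
        sigmas=scales,
        black_ridges=(polarity == "dark_on_bright"),
        mode="reflect",
    )
    return np.clip(response, 0.0, None)


# ---------------------------------------------------------------------------
# skeleton utilities


def _neighbor_counts(mask: np.ndarray) -> np.ndarray:
    return ndi.convolve(mask.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def _has_full_2x2(mask: np.ndarray) -> bool:
    m = mask.astype(bool)
    return bool(np.any(m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]))


def _is_simple(nbhd: np.ndarray) -> bool:
    """True when removing the centre of a 3x3 neighbourhood keeps its
    foreground neighbours in a single 8-connected component."""
    n = nbhd.copy()
    n[1, 1] = False
    if not n.any():
        return False
    lab, num = ndi.label(n, structure=np.ones((3, 3), dtype=np.uint8))
    return num == 1


def _enforce_unit_width(mask: np.ndarray) -> np.ndarray:
    """Remove redundant pixels so no 2x2 block is fully set.

    Pixels participating in a full 2x2 block are deleted in raster order
    when deletion is topology-preserving (simple point) — deterministic.
    """
    mask = mask.astype(bool).copy()
    padded = np.pad(mask, 1)
    changed = True
    while changed and _has_full_2x2(mask):
        changed = False
        blocks = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
        rows, cols = np.nonzero(blocks)
        for r, c in zip(rows, cols):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if not mask[rr, cc]:
                    continue
                if not (
                    mask[r : r + 2, c : c + 2].sum() == 4
                ):  # block already broken
                    break
                nbhd = padded[rr : rr + 3, cc : cc + 3]
                if _is_simple(nbhd):
                    mask[rr, cc] = False
                    padded[rr + 1, cc + 1] = False
                    changed = True
                    break
        if not changed:
            break
    return mask


def skeleton_length(skeleton_mask: np.ndarray, pixel_size_um: float):
    """Physical skeleton length under the 8-connected step-weight convention.

    length = sum over unique 8-adjacent skeleton pixel pairs of the step
    weight (1 orthogonal, sqrt(2) diagonal) times the pixel size.  Returns
    ``(total_um, per_component_um)`` with components labelled 8-connected.

    Raises ContractViolationError when the mask is not unit-width (contains
    a fully set 2x2 block).
    """
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be > 0")
    m = np.asarray(skeleton_mask).astype(bool)
    if _has_full_2x2(m):
        raise ContractViolationError("skeleton mask is not unit-width (full 2x2 block)")
    labels = sk_label(m, connectivity=2)
    n = labels.max()
    per = np.zeros(n + 1)
    # orthogonal pairs
    for sl_a, sl_b in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
    ):
        both = m[sl_a] & m[sl_b]
        np.add.at(per, labels[sl_a][both], 1.0)
    # diagonal pairs
    for sl_a, sl_b in (
        ((slice(None, -1), slice(None, -1)), (slice(1, None), slice(1, None))),
        ((slice(None, -1), slice(1, None)), (slice(1, None), slice(None, -1))),
    ):
        both = m[sl_a] & m[sl_b]
        np.add.at(per, labels[sl_a][both], SQRT2)
    per_component = {int(i): float(per[i] * pixel_size_um) for i in range(1, n + 1)}
    total = float(per[1:].sum() * pixel_size_um)
    return total, per_component


def _endpoints_and_branches(mask: np.ndarray):
    counts = _neighbor_counts(mask)
    endpoints = np.argwhere(mask & (counts == 1))
    branches = np.argwhere(mask & (counts >= 3))
    return endpoints, branches


def prune_spurs(mask: np.ndarray, pixel_size_um: float, max_spur_um: float) -> np.ndarray:
    """Iteratively remove terminal spurs shorter than ``max_spur_um``.

    A spur is a path from an endpoint to the first branch point; whole
    isolated components (endpoint-to-endpoint paths) are never pruned here
    — they are handled by the minimum-component-length filter.
    """
    mask = mask.astype(bool).copy()
    if max_spur_um <= 0:
        return mask
    while True:
        counts = _neighbor_counts(mask)
        endpoints = np.argwhere(mask & (counts == 1))
        removed_any = False
        to_remove = []
        junctions = []
        for ep in endpoints:
            path = [tuple(ep)]
            length_um = 0.0
            prev = None
            cur = tuple(ep)
            hit_branch = False
            while True:
                r, c = cur
                nbrs = []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc]:
                            if (rr, cc) != prev:
                                nbrs.append((rr, cc))
                if counts[r, c] >= 3 and prev is not None:
                    hit_branch = True
                    path.pop()  # keep the branch point
                    break
                if len(nbrs) == 0:
                    break  # isolated path end
                if len(nbrs) > 1:
                    # endpoint itself adjacent to several pixels: treat as junction
                    hit_branch = counts[r, c] >= 3
                    break
                nxt = nbrs[0]
                step = SQRT2 if (nxt[0] != r and nxt[1] != c) else 1.0
                length_um += step * pixel_size_um
                if length_um >= max_spur_um:
                    break
                prev, cur = cur, nxt
                path.append(cur)
            if hit_branch and length_um < max_spur_um and path:
                to_remove.extend(path)
                junctions.append(cur)
                removed_any = True
        if not removed_any:
            break
        for r, c in to_remove:
            mask[r, c] = False
        # a pruned spur can leave a redundant bump where it met the main
        # branch: the junction pixel is removed too when its remaining
        # neighbours are already mutually connected (topology preserved)
        padded = np.pad(mask, 1)
        for r, c in junctions:
            if mask[r, c] and _is_simple(padded[r : r + 3, c : c + 3]):
                nbhd = padded[r : r + 3, c : c + 3].copy()
                nbhd[1, 1] = False
                # only drop a genuine bump (neighbours >= 2, all connected)
                if nbhd.sum() >= 2:
                    mask[r, c] = False
                    padded[r + 1, c + 1] = False
        mask = _enforce_unit_width(mask)
    return mask


# ---------------------------------------------------------------------------
# segmentation


def _robust_hysteresis(response: np.ndarray, high_mads: float) -> np.ndarray:
    med = float(np.median(response))
    mad = float(np.median(np.abs(response - med)))
    if mad == 0:
        mad = float(response.std()) or 1.0
    high = med + high_mads * mad
    low = med + 0.5 * high_mads * mad
    if response.max() <= high:
        return np.zeros(response.shape, dtype=bool)
    return apply_hysteresis_threshold(response, low, high)


def segment_neurites(
    field: ImageField,
    nuclei: NucleiResult,
    params: NeuriteParams = NeuriteParams(),
) -> NeuriteSkeleton:
    """Detect neurites in the cell channel and return their skeleton.

    Pipeline: ridge enhancement -> hysteresis threshold of the response ->
    morphological cleanup -> exclusion of soma regions (nuclei dilated by
    ``soma_dilation_um``) so only projections outside cell bodies count ->
    skeletonization to unit width -> iterative spur pruning -> removal of
    short components -> topology extraction.
    """
    if np.asarray(nuclei.label_mask).shape != field.shape:
        raise InputError("nuclei mask dimensions do not match the field")
    px = field.pixel_size_um

    response = enhance_ridges(field.cell_channel, params.scales_px, params.polarity)
    mask = _robust_hysteresis(response, params.response_threshold)
    mask = closing(mask, disk(1))
    mask = remove_small_objects(mask, max_size=4, connectivity=2)

    soma_r_px = int(round(params.soma_dilation_um / px))
    if soma_r_px > 0 and nuclei.count > 0:
        soma = dilation(nuclei.label_mask > 0, disk(soma_r_px))
        mask &= ~soma

    skel = skeletonize(mask)
    skel = _enforce_unit_width(skel)
    skel = prune_spurs(skel, px, params.prune_spur_length_um)

    # component-length filter
    labels = sk_label(skel, connectivity=2)
    _, per = skeleton_length(skel, px)
    keep = {cid for cid, L in per.items() if L >= params.min_component_length_um}
    if len(keep) < len(per):
        skel = np.isin(labels, sorted(keep))
        labels = sk_label(skel, connectivity=2)
        _, per = skeleton_length(skel, px)

    components = []
    for cid in sorted(per):
        pix = np.argwhere(labels == cid)
        components.append(SkeletonComponent(cid, pix, per[cid]))
    endpoints, branches = _endpoints_and_branches(skel)
    return NeuriteSkeleton(
        skeleton_mask=skel.astype(bool),
        components=components,
        branch_points=[tuple(p) for p in branches],
        endpoints=[tuple(p) for p in endpoints],
        pixel_size_um=px,
    )
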