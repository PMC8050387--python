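"""Synthetic two-channel fields with analytic ground truth.

Emulates a live-cell high-content screening field: Gaussian-blurred
ellipsoidal nuclei in a DNA-dye channel; soma blobs and thin constant-width
neurites in the cell channel.  Neurite centerlines are chains of circular
arcs, so every neurite has an exact closed-form arc length — ground truth
is analytic, not estimated.  Noise is Poisson shot noise on the signal
plus Gaussian read noise, calibrated so that
(peak signal - background) / noise SD at peak-signal pixels equals the
requested SNR.  Everything is deterministic given the seed.

Each generated neurite starts on its anchor soma's boundary; the portion
inside the soma-exclusion disk (anchor nucleus radius plus a dilation
margin) is rendered but excluded from the recorded ground-truth length and
mask, mirroring the soma-exclusion rule of the segmentation pipeline.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.filters import gaussian
from skimage.morphology import dilation, disk

from .config import DEFAULT_PIXEL_SIZE_UM
from .errors import GenerationError, ParameterError
from .image_io import ImageField, write_field

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "arc_from_radius_sweep",
    "arc_chain",
    "generate_field",
    "generate_touching_pairs_field",
    "generate_experiment",
    "measure_snr",
]

#: peak object amplitude above background, both channels (arbitrary units)
AMPLITUDE = 1000.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic field.  All physical sizes in µm."""

    field_shape: Tuple[int, int] = (512, 512)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_nuclei: int = 25
    nucleus_radius_um: Tuple[float, float] = (3.5, 5.5)
    allowed_overlap_fraction: float = 0.0
    n_neurites: int = 15
    neurite_length_um: Tuple[float, float] = (40.0, 120.0)
    neurite_width_px: int = 3
    curvature_max: float = 0.05  # rad per µm (minimum bend radius 20 µm)
    soma_radius_um: float = 6.0
    #: soma-exclusion margin: nucleus radius + this margin defines the disk
    #: outside which ground-truth neurite length is recorded (mirrors the
    #: segmentation soma_dilation_um default)
    soma_exclusion_margin_um: float = 5.0
    background_level: float = 100.0
    snr: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.soma_radius_um <= 0:
            raise ParameterError("physical parameters must be > 0")
        if self.nucleus_radius_um[0] <= 0 or self.nucleus_radius_um[1] < self.nucleus_radius_um[0]:
            raise ParameterError("invalid nucleus_radius_um range")
        if not (0 <= self.allowed_overlap_fraction < 0.5):
            raise ParameterError("allowed_overlap_fraction must be in [0, 0.5)")
        if self.snr <= 0:
            raise ParameterError("snr must be > 0")
        if self.n_neurites > 0 and self.n_nuclei < 1:
            raise ParameterError("neurites need at least one nucleus to anchor to")
        if self.neurite_length_um[0] <= 0 or self.neurite_length_um[1] < self.neurite_length_um[0]:
            raise ParameterError("invalid neurite_length_um range")
        if self.curvature_max < 0:
            raise ParameterError("curvature_max must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side record of what was drawn."""

    nuclei_centroids_px: List[Tuple[float, float]]
    nuclei_radii_um: List[float]
    neurite_lengths_um: List[float]  # analytic length outside the exclusion disk
    neurite_anchors: List[int]  # index into the nuclei lists
    nuclei_mask: np.ndarray
    soma_mask: np.ndarray
    neurite_mask: np.ndarray  # clean stroke mask, exclusion region removed
    exclusion_mask: np.ndarray

    @property
    def total_neurite_length_um(self) -> float:
        return float(sum(self.neurite_lengths_um))


# ---------------------------------------------------------------------------
# arc-chain paths


def arc_from_radius_sweep(radius_um: float, sweep_rad: float, turn: int = 1):
    """An arc given as (signed curvature 1/µm, arc length µm).

    Arc length is radius x sweep, exactly.
    """
    if radius_um <= 0 or sweep_rad <= 0:
        raise ParameterError("radius and sweep must be > 0")
    return (turn / radius_um, radius_um * sweep_rad)


def arc_chain(
    start_um: Tuple[float, float],
    heading_rad: float,
    arcs: Sequence[Tuple[float, float]],
    step_um: float = 0.2,
) -> Tuple[np.ndarray, float]:
    """Integrate a chain of circular arcs analytically.

    ``arcs`` is a sequence of (signed curvature in 1/µm, length in µm);
    zero curvature means a straight segment.  Returns a densely sampled
    polyline in (row, col) µm coordinates and the exact total arc length
    (the plain sum of segment lengths).
    """
    r, c = float(start_um[0]), float(start_um[1])
    theta = float(heading_rad)
    pts = [(r, c)]
    total = 0.0
    for kappa, length in arcs:
        if length <= 0:
            raise ParameterError("arc length must be > 0")
        n = max(2, int(math.ceil(length / step_um)) + 1)
        t = np.linspace(0.0, length, n)[1:]
        if abs(kappa) < 1e-12:
            rr = r + t * math.sin(theta)
            cc = c + t * math.cos(theta)
            theta_end = theta
        else:
            rr = r + (np.cos(theta) - np.cos(theta + kappa * t)) / kappa
            cc = c + (np.sin(theta + kappa * t) - np.sin(theta)) / kappa
            theta_end = theta + kappa * length
        pts.extend(zip(rr.tolist(), cc.tolist()))
        r, c = float(rr[-1]), float(cc[-1])
        theta = theta_end
        total += float(length)
    return np.asarray(pts), total


# ---------------------------------------------------------------------------
# rendering helpers


def _render_ellipses(shape, centers_px, radii_px, eccs, angles, amplitude) -> Tuple[np.ndarray, np.ndarray]:
    img = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    for (cr, cc), r_px, e, ang in zip(centers_px, radii_px, eccs, angles):
        a, b = r_px * (1.0 + e), r_px / (1.0 + e)
        half = int(math.ceil(a)) + 2
        r0, r1 = max(0, int(cr) - half), min(shape[0], int(cr) + half + 1)
        c0, c1 = max(0, int(cc) - half), min(shape[1], int(cc) + half + 1)
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        dr, dc = rr - cr, cc_ - cc
        u = dr * math.cos(ang) + dc * math.sin(ang)
        v = -dr * math.sin(ang) + dc * math.cos(ang)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[r0:r1, c0:c1][inside] = amplitude
        mask[r0:r1, c0:c1][inside] = True
    return img, mask


def _rasterize_polyline(shape, points_px: np.ndarray, width_px: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    ij = np.rint(points_px).astype(int)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < shape[0]) & (ij[:, 1] >= 0) & (ij[:, 1] < shape[1])
    ij = ij[ok]
    mask[ij[:, 0], ij[:, 1]] = True
    half = max(0, (width_px - 1) // 2)
    if half:
        mask = dilation(mask, disk(half))
    return mask


def _add_noise(clean: np.ndarray, background: float, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot + Gaussian read noise, calibrated against AMPLITUDE.

    Shot and read noise each contribute half the target variance at
    peak-signal pixels, so the noise SD there is AMPLITUDE / snr.
    """
    peak = background + AMPLITUDE
    gain = 2.0 * snr**2 * peak / AMPLITUDE**2  # photons per intensity unit
    sigma_read = AMPLITUDE / (snr * math.sqrt(2.0))
    noisy = rng.poisson(clean * gain).astype(np.float64) / gain
    noisy += rng.normal(0.0, sigma_read, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def measure_snr(clean: np.ndarray, noisy: np.ndarray, background: float) -> float:
    """Estimate the realised SNR from a clean/noisy pair.

    Noise SD is taken over near-peak pixels (clean within 10% of the full
    signal range above background), matching the calibration point.
    """
    peak = float(clean.max())
    amp = peak - background
    if amp <= 0:
        raise ParameterError("clean image has no signal above background")
    sel = clean >= background + 0.9 * amp
    resid = (noisy - clean)[sel]
    return amp / float(resid.std())


# ---------------------------------------------------------------------------
# field generation


def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator):
    shape = spec.field_shape
    px = spec.pixel_size_um
    radii_um = rng.uniform(*spec.nucleus_radius_um, size=spec.n_nuclei)
    centers: List[Tuple[float, float]] = []
    max_tries = 300 * max(1, spec.n_nuclei)
    tries = 0
    margin_extra = spec.soma_radius_um / px + 3
    i = 0
    while i < spec.n_nuclei:
        if tries >= max_tries:
            raise GenerationError(
                "cannot place nuclei: overlap constraint "
                f"(allowed_overlap_fraction={spec.allowed_overlap_fraction}) "
                "unsatisfiable after bounded retries"
            )
        tries += 1
        r_px = radii_um[i] / px
        m = r_px + margin_extra
        cand = (rng.uniform(m, shape[0] - m), rng.uniform(m, shape[1] - m))
        ok = True
        for j, (cr, cc) in enumerate(centers):
            min_d = (radii_um[i] + radii_um[j]) / px * (1.0 - spec.allowed_overlap_fraction)
            if math.hypot(cand[0] - cr, cand[1] - cc) < min_d:
                ok = False
                break
        if ok:
            centers.append(cand)
            i += 1
    return centers, radii_um


def _make_neurite(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    centers_px: List[Tuple[float, float]],
    radii_um: np.ndarray,
):
    """One arc-chain neurite anchored on a soma's exclusion boundary.

    The anchor nucleus is redrawn on every attempt so a single awkwardly
    placed soma cannot exhaust the retry budget.  Returns (polyline_px of
    the measured part, stem_polyline_px, exact length µm, anchor index)
    or None when no placement satisfies the constraints.
    """
    px = spec.pixel_size_um
    shape = spec.field_shape
    border_um = (spec.neurite_width_px + 2) * px

    for _ in range(200):
        anchor = int(rng.integers(0, len(centers_px)))
        cr, cc = centers_px[anchor]
        r_ex = radii_um[anchor] + spec.soma_exclusion_margin_um  # µm
        phi = rng.uniform(0, 2 * math.pi)
        heading = phi + rng.uniform(-0.4, 0.4)
        total = rng.uniform(*spec.neurite_length_um)
        w = rng.uniform(0.5, 1.0, size=3)
        seg_lengths = total * w / w.sum()
        kappas = rng.uniform(-spec.curvature_max, spec.curvature_max, size=3)
        start_um = (
            cr * px + r_ex * math.sin(phi),
            cc * px + r_ex * math.cos(phi),
        )
        pts_um, exact = arc_chain(start_um, heading, list(zip(kappas, seg_lengths)))
        # stay inside the field
        if (
            pts_um[:, 0].min() < border_um
            or pts_um[:, 1].min() < border_um
            or pts_um[:, 0].max() > shape[0] * px - border_um
            or pts_um[:, 1].max() > shape[1] * px - border_um
        ):
            continue
        # stay outside every exclusion disk (0.5 µm slack at the anchor
        # where the path starts exactly on the boundary)
        ok = True
        for j, (jr, jc) in enumerate(centers_px):
            r_ex_j = radii_um[j] + spec.soma_exclusion_margin_um
            d = float(np.hypot(pts_um[:, 0] - jr * px, pts_um[:, 1] - jc * px).min())
            if j == anchor:
                if d < r_ex_j - 0.5:  # path starts on this boundary
                    ok = False
                    break
            elif d < r_ex_j + 1.0:  # other somata need clearance
                ok = False
                break
        if not ok:
            continue
        # straight stem from the soma boundary to the path start (rendered
        # only; lies inside the exclusion disk along the radial direction)
        stem_um, _ = arc_chain(
            (cr * px + spec.soma_radius_um * math.sin(phi), cc * px + spec.soma_radius_um * math.cos(phi)),
            phi,
            [(0.0, max(r_ex - spec.soma_radius_um, 0.5))],
        )
        return pts_um / px, stem_um / px, exact, anchor
    return None


def generate_field(spec: SyntheticSpec) -> Tuple[ImageField, GroundTruth]:
    """Generate one two-channel field and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.field_shape
    px = spec.pixel_size_um

    centers, radii_um = (
        _place_nuclei(spec, rng) if spec.n_nuclei > 0 else ([], np.zeros(0))
    )
    eccs = rng.uniform(0.0, 0.15, size=spec.n_nuclei)
    angles = rng.uniform(0.0, math.pi, size=spec.n_nuclei)
    radii_px = np.asarray(radii_um) / px

    nuclei_signal, nuclei_mask = _render_ellipses(shape, centers, radii_px, eccs, angles, AMPLITUDE)
    nuclei_clean = spec.background_level + gaussian(nuclei_signal, sigma=1.2, preserve_range=True)

    # somata: one blob per nucleus
    soma_r_px = spec.soma_radius_um / px
    soma_signal, soma_mask = _render_ellipses(
        shape, centers, [soma_r_px] * len(centers), np.zeros(len(centers)), np.zeros(len(centers)), AMPLITUDE
    )

    exclusion = np.zeros(shape, dtype=bool)
    if centers:
        ex_signal, exclusion = _render_ellipses(
            shape,
            centers,
            (np.asarray(radii_um) + spec.soma_exclusion_margin_um) / px,
            np.zeros(len(centers)),
            np.zeros(len(centers)),
            1.0,
        )

    lengths: List[float] = []
    anchors: List[int] = []
    neurite_mask = np.zeros(shape, dtype=bool)
    stroke = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_neurites):
        made = _make_neurite(spec, rng, centers, np.asarray(radii_um))
        if made is None:
            raise GenerationError(
                "cannot place neurite: field/exclusion constraints unsatisfiable "
                "after bounded retries"
            )
        pts_px, stem_px, exact, anchor = made
        body = _rasterize_polyline(shape, pts_px, spec.neurite_width_px)
        stem = _rasterize_polyline(shape, stem_px, spec.neurite_width_px)
        stroke |= body | stem
        neurite_mask |= body & ~exclusion
        lengths.append(exact)
        anchors.append(anchor)

    cell_signal = np.maximum(soma_signal, np.where(stroke, AMPLITUDE, 0.0))
    cell_clean = spec.background_level + gaussian(cell_signal, sigma=0.7, preserve_range=True)

    field = ImageField(
        field_id=f"synthetic-{spec.seed}",
        condition="",
        nuclei_channel=_add_noise(nuclei_clean, spec.background_level, spec.snr, rng),
        cell_channel=_add_noise(cell_clean, spec.background_level, spec.snr, rng),
        pixel_size_um=px,
    )
    truth = GroundTruth(
        nuclei_centroids_px=[(float(r), float(c)) for r, c in centers],
        nuclei_radii_um=[float(r) for r in radii_um],
        neurite_lengths_um=lengths,
        neurite_anchors=anchors,
        nuclei_mask=nuclei_mask,
        soma_mask=soma_mask,
        neurite_mask=neurite_mask,
        exclusion_mask=exclusion,
    )
    return field, truth


def generate_touching_pairs_field(
    n_pairs: int = 5,
    overlap_fraction: float = 0.3,
    spec: Optional[SyntheticSpec] = None,
) -> Tuple[ImageField, GroundTruth]:
    """Field of isolated nucleus *pairs* at a prescribed overlap.

    Pair centres are laid out on a grid; within each pair the two nuclei
    are placed at centre distance (r1 + r2) x (1 - overlap_fraction), at a
    random orientation.  True count = 2 x n_pairs.
    """
    if not (0 <= overlap_fraction < 0.5):
        raise ParameterError("overlap_fraction must be in [0, 0.5)")
    spec = spec or SyntheticSpec()
    spec = dataclasses.replace(spec, n_neurites=0)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, px = spec.field_shape, spec.pixel_size_um

    side = int(math.ceil(math.sqrt(n_pairs)))
    cell_h, cell_w = shape[0] / side, shape[1] / side
    centers: List[Tuple[float, float]] = []
    radii_um_list: List[float] = []
    for k in range(n_pairs):
        gi, gj = divmod(k, side)
        base = ((gi + 0.5) * cell_h, (gj + 0.5) * cell_w)
        r1, r2 = rng.uniform(*spec.nucleus_radius_um, size=2)
        d_px = (r1 + r2) * (1.0 - overlap_fraction) / px
        ang = rng.uniform(0, math.pi)
        off = (d_px / 2 * math.sin(ang), d_px / 2 * math.cos(ang))
        centers.append((base[0] - off[0], base[1] - off[1]))
        centers.append((base[0] + off[0], base[1] + off[1]))
        radii_um_list.extend([r1, r2])

    radii_px = np.asarray(radii_um_list) / px
    n = len(centers)
    signal, mask = _render_ellipses(shape, centers, radii_px, np.zeros(n), np.zeros(n), AMPLITUDE)
    clean = spec.background_level + gaussian(signal, sigma=1.2, preserve_range=True)
    field = ImageField(
        field_id=f"pairs-{spec.seed}",
        condition="",
        nuclei_channel=_add_noise(clean, spec.background_level, spec.snr, rng),
        cell_channel=np.full(shape, spec.background_level),
        pixel_size_um=px,
    )
    truth = GroundTruth(
        nuclei_centroids_px=[(float(r), float(c)) for r, c in centers],
        nuclei_radii_um=radii_um_list,
        neurite_lengths_um=[],
        neurite_anchors=[],
        nuclei_mask=mask,
        soma_mask=np.zeros(shape, dtype=bool),
        neurite_mask=np.zeros(shape, dtype=bool),
        exclusion_mask=np.zeros(shape, dtype=bool),
    )
    return field, truth


# ---------------------------------------------------------------------------
# experiments


def field_seed(master_seed: int, condition_index: int, field_index: int) -> int:
    """Deterministic per-field seed derived from the master seed."""
    ss = np.random.SeedSequence((master_seed, condition_index, field_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


GROUND_TRUTH_COLUMNS = [
    "field_id",
    "condition",
    "seed",
    "n_nuclei",
    "n_neurites",
    "total_neurite_length_um",
]


def generate_experiment(
    condition_specs: Mapping[str, Tuple[SyntheticSpec, int]],
    out_dir,
    master_seed: int = 0,
    overwrite: bool = False,
) -> Tuple[Path, Path]:
    """Simulate a multi-condition experiment on disk.

    Writes one two-page TIFF per field, a manifest CSV and a ground-truth
    CSV aligned by field_id.  Per-field seeds derive deterministically from
    the master seed.  Returns (manifest_path, ground_truth_path).
    """
    if len(condition_specs) < 1:
        raise ParameterError("need at least one condition")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise OSError(f"output directory {out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    manifest_rows, truth_rows = [], []
    for ci, (cond, (spec, n_fields)) in enumerate(condition_specs.items()):
        if n_fields < 1:
            raise ParameterError(f"condition {cond!r}: n_fields must be >= 1")
        for fi in range(n_fields):
            seed = field_seed(master_seed, ci, fi)
            fspec = dataclasses.replace(spec, seed=seed)
            field, truth = generate_field(fspec)
            field_id = f"{cond}_{fi:03d}"
            fname = f"{field_id}.tif"
            field.field_id = field_id
            field.condition = cond
            write_field(field, out / fname)
            manifest_rows.append(
                {
                    "field_id": field_id,
                    "condition": cond,
                    "file": fname,
                    "nuclei_page": 0,
                    "cell_page": 1,
                    "pixel_size_um": spec.pixel_size_um,
                }
            )
            truth_rows.append(
                {
                    "field_id": field_id,
                    "condition": cond,
                    "seed": seed,
                    "n_nuclei": len(truth.nuclei_centroids_px),
                    "n_neurites": len(truth.neurite_lengths_um),
                    "total_neurite_length_um": truth.total_neurite_length_um,
                }
            )
    manifest_path = out / "manifest.csv"
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS).to_csv(truth_path, index=False)
    return manifest_path, truth_path
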