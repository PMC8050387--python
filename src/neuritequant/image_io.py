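"""Reading and writing of image fields, manifests, overlays and metric tables.

A *field* is one microscope position: two co-registered grayscale channels
(a DNA-dye nuclei channel and a cell/neurite channel) plus the physical
pixel size.  Supported container dialects are deliberately narrow:
grayscale single-sample TIFF, either one file per channel or a two-page
stack, with the channel order declared in the manifest and never inferred.
Intensities are stored exactly as read; downstream operations normalise
internally.  Coordinates are (row, col), 0-based, shared by channels and
masks everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

from .config import DEFAULT_PIXEL_SIZE_UM
from .errors import FormatError, InputError

__all__ = [
    "ImageField",
    "read_field",
    "write_field",
    "read_manifest",
    "load_fields",
    "write_overlay",
    "write_metrics",
    "read_metrics",
    "METRICS_COLUMNS",
]

_ALLOWED_DTYPES = ("uint8", "uint16", "int16", "int32", "float32", "float64")


@dataclass
class ImageField:
    """One two-channel microscopy field with physical calibration."""

    field_id: str
    condition: str
    nuclei_channel: np.ndarray
    cell_channel: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.nuclei_channel = np.asarray(self.nuclei_channel, dtype=np.float64)
        self.cell_channel = np.asarray(self.cell_channel, dtype=np.float64)
        if self.nuclei_channel.ndim != 2 or self.cell_channel.ndim != 2:
            raise FormatError("channels must be 2-D grayscale arrays")
        if self.nuclei_channel.shape != self.cell_channel.shape:
            raise FormatError(
                f"channel dimension mismatch: {self.nuclei_channel.shape} "
                f"vs {self.cell_channel.shape}"
            )
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be > 0")
        for name, ch in (("nuclei", self.nuclei_channel), ("cell", self.cell_channel)):
            if not np.all(np.isfinite(ch)):
                raise InputError(f"{name} channel contains non-finite values")
            if ch.min() < 0:
                raise InputError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple:
        return self.nuclei_channel.shape


def _read_page(path: Path, page: Optional[int]) -> np.ndarray:
    if not path.exists():
        raise InputError(f"image file does not exist: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            if page is None:
                arr = tf.asarray()
            else:
                if page >= len(tf.pages):
                    raise FormatError(f"{path} has no page {page}")
                arr = tf.pages[page].asarray()
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.dtype.name not in _ALLOWED_DTYPES:
        raise FormatError(f"unsupported bit depth/dtype {arr.dtype} in {path}")
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale page in {path}, got shape {arr.shape}")
    return arr


def read_field(
    paths: Union[str, Path, Mapping[str, Union[str, Path]]],
    channel_map: Mapping[str, int],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    field_id: str = "",
    condition: str = "",
) -> ImageField:
    """Read one field from TIFF file(s).

    Parameters
    ----------
    paths
        Either a single multi-page TIFF path (``channel_map`` then maps the
        role names ``"nuclei"`` and ``"cell"`` to page indices) or a mapping
        ``{"nuclei": path, "cell": path}`` of one single-page file per
        channel (``channel_map`` is then ignored and may map roles to 0).
    channel_map
        Must name exactly the two roles ``nuclei`` and ``cell``.
    """
    if set(channel_map) != {"nuclei", "cell"}:
        raise InputError("channel_map must name exactly 'nuclei' and 'cell'")
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        nuclei = _read_page(p, int(channel_map["nuclei"]))
        cell = _read_page(p, int(channel_map["cell"]))
    else:
        nuclei = _read_page(Path(paths["nuclei"]), None)
        cell = _read_page(Path(paths["cell"]), None)
    if nuclei.shape != cell.shape:
        raise FormatError(
            f"channel dimension mismatch: {nuclei.shape} vs {cell.shape}"
        )
    if not field_id:
        first = paths if isinstance(paths, (str, Path)) else paths["nuclei"]
        field_id = Path(first).stem
    return ImageField(
        field_id=field_id,
        condition=condition,
        nuclei_channel=nuclei,
        cell_channel=cell,
        pixel_size_um=float(pixel_size_um),
    )


def write_field(field: ImageField, path: Union[str, Path], dtype=np.uint16) -> Path:
    """Write a field as a two-page grayscale TIFF (nuclei page 0, cell page 1)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    info = np.iinfo(dtype)
    stack = np.stack(
        [
            np.clip(np.rint(field.nuclei_channel), info.min, info.max).astype(dtype),
            np.clip(np.rint(field.cell_channel), info.min, info.max).astype(dtype),
        ]
    )
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = [
    "field_id",
    "condition",
    "file",
    "nuclei_page",
    "cell_page",
    "pixel_size_um",
]


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a plate/condition manifest CSV.

    Required columns: field_id, condition, file, nuclei_page, cell_page.
    Optional: pixel_size_um (falls back to the package default when absent).
    File paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest does not exist: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise InputError(f"unreadable manifest {path}: {exc}") from exc
    required = {"field_id", "condition", "file", "nuclei_page", "cell_page"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"manifest missing columns: {sorted(missing)}")
    if df["field_id"].duplicated().any():
        dup = df.loc[df["field_id"].duplicated(), "field_id"].iloc[0]
        raise InputError(f"duplicate field_id in manifest: {dup!r}")
    if "pixel_size_um" not in df.columns:
        df["pixel_size_um"] = DEFAULT_PIXEL_SIZE_UM
    base = path.parent
    resolved = [str((base / f)) if not Path(f).is_absolute() else str(f) for f in df["file"]]
    df = df.assign(file=resolved)
    for f in df["file"]:
        if not Path(f).exists():
            raise InputError(f"manifest references missing file: {f}")
    return df.reset_index(drop=True)


def load_fields(manifest: pd.DataFrame):
    """Yield ImageField objects for every manifest row, in row order."""
    for row in manifest.itertuples(index=False):
        yield read_field(
            row.file,
            {"nuclei": int(row.nuclei_page), "cell": int(row.cell_page)},
            pixel_size_um=float(row.pixel_size_um),
            field_id=str(row.field_id),
            condition=str(row.condition),
        )


# ---------------------------------------------------------------------------
# overlays

CYAN = (0, 255, 255)
WHITE = (255, 255, 255)


def write_overlay(field: ImageField, nuclei, skeleton, path: Union[str, Path]) -> Path:
    """Render a segmentation overlay: cell channel grayscale background,
    nucleus pixels cyan, skeleton pixels white (white takes precedence
    where the two overlap), and write it as an RGB PNG/TIFF.
    """
    nuclei_mask = np.asarray(nuclei.label_mask) > 0 if hasattr(nuclei, "label_mask") else np.asarray(nuclei) > 0
    skel_mask = (
        np.asarray(skeleton.skeleton_mask).astype(bool)
        if hasattr(skeleton, "skeleton_mask")
        else np.asarray(skeleton).astype(bool)
    )
    if nuclei_mask.shape != field.shape or skel_mask.shape != field.shape:
        raise InputError("mask dimensions do not match the field")
    ch = field.cell_channel
    lo, hi = float(ch.min()), float(ch.max())
    gray = np.zeros(ch.shape, dtype=np.uint8) if hi == lo else np.clip(
        np.rint((ch - lo) / (hi - lo) * 255.0), 0, 255
    ).astype(np.uint8)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    rgb[nuclei_mask] = CYAN
    rgb[skel_mask] = WHITE  # white precedence over cyan
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path


# ---------------------------------------------------------------------------
# metric tables

#: fixed, documented column order of the per-field metrics CSV
METRICS_COLUMNS = [
    "field_id",
    "condition",
    "nuclei_count",
    "total_neurite_length_um",
    "neurite_length_per_cell_um",
    "neurite_component_count",
    "branch_point_count",
    "neurite_positive_cell_fraction",
    "excluded",
    "pixel_size_um",
]


def write_metrics(metrics: Sequence, path: Union[str, Path]) -> Path:
    """Write per-field metrics to CSV, one row per field, fixed column order."""
    if len(metrics) == 0:
        raise InputError("metrics list is empty")
    rows = []
    for m in metrics:
        d = m.to_dict() if hasattr(m, "to_dict") else dict(m)
        rows.append({c: d.get(c) for c in METRICS_COLUMNS})
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
    except OSError as exc:
        raise InputError(f"cannot write metrics CSV to {path}: {exc}") from exc
    return path


def read_metrics(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"metrics CSV does not exist: {path}")
    return pd.read_csv(path)
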