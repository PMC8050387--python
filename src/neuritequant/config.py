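"""Parameter blocks and run configuration.

Every tunable of the pipeline lives in one of the dataclasses below, each
with a documented default.  A fully resolved configuration is written next
to every output directory so results are auditable.  YAML is used for the
on-disk representation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ParameterError

#: Default physical calibration (µm per pixel), a typical 10x sCMOS scale.
#: This is a configurable assumption, not a measured value; it is echoed in
#: all output metadata.
DEFAULT_PIXEL_SIZE_UM = 0.65


@dataclass
class NucleiParams:
    """Nucleus segmentation parameters.

    threshold_offset is expressed in robust units (multiples of the median
    absolute deviation of the corrected channel) so it transfers across bit
    depths.  Areas are physical (µm²); defaults are plausible for SH-SY5Y
    nuclei imaged at 10x.
    """

    smoothing_sigma_px: float = 2.0
    background_radius_px: float = 25.0
    threshold_method: str = "otsu"  # "otsu" or "li"
    threshold_offset: float = 0.0  # in MADs of the corrected channel
    min_area_um2: float = 30.0
    max_area_um2: float = 500.0
    split_touching: bool = True
    exclude_border: bool = True
    #: watershed seeds closer than this merge into one nucleus (plateau
    #: and quantisation duplicates of the distance transform)
    min_seed_separation_px: float = 5.0
    #: watershed fragments whose union is rounder than this major/minor
    #: axis ratio are re-merged: a single nucleus stays one object even
    #: when boundary noise gives it two distance maxima
    max_axis_ratio: float = 1.45


@dataclass
class NeuriteParams:
    """Neurite segmentation parameters.

    The ridge response is thresholded with hysteresis in robust units:
    ``response_threshold`` is the high threshold in MADs above the median
    response; the low threshold is half of it.  Lengths are physical (µm).
    """

    scales_px: Sequence[float] = (1.0, 2.0, 4.0)
    response_threshold: float = 8.0  # high hysteresis threshold, in MADs
    polarity: str = "bright_on_dark"  # or "dark_on_bright"
    soma_dilation_um: float = 5.0
    prune_spur_length_um: float = 5.0
    min_component_length_um: float = 10.0


@dataclass
class QuantParams:
    #: a cell is neurite-positive when its assigned skeleton length reaches
    #: this threshold (~ one to two SH-SY5Y soma diameters)
    min_neurite_length_um: float = 20.0


@dataclass
class StatsParams:
    alpha: float = 0.05
    n_boot: int = 10_000
    equal_var: bool = False  # Welch t by default
    control: Optional[str] = None
    metrics: Sequence[str] = (
        "neurite_length_per_cell_um",
        "total_neurite_length_um",
        "neurite_positive_cell_fraction",
    )


@dataclass
class RunConfig:
    """All module parameter blocks plus the master seed and calibration."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    neurite: NeuriteParams = field(default_factory=NeuriteParams)
    quant: QuantParams = field(default_factory=QuantParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("nuclei", NucleiParams),
            ("neurite", NeuriteParams),
            ("quant", QuantParams),
            ("stats", StatsParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    serializable = config.to_dict()
    # tuples -> lists for clean YAML
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(serializable, fh, default_flow_style=False, sort_keys=False)
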