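"""Per-field neurite-outgrowth morphometrics.

Combines the nucleus segmentation (cell-count denominator) with the
neurite skeleton into one record per field: counts, total and per-cell
skeleton length, and the neurite-positive cell fraction.  The statistical
unit downstream is the field; fields without nuclei are flagged and
excluded from statistics rather than imputed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .config import QuantParams
from .errors import AssignmentError
from .neurites import NeuriteSkeleton
from .nuclei import NucleiResult

__all__ = ["FieldMetrics", "assign_components_to_cells", "quantify_field"]


@dataclass
class FieldMetrics:
    """Morphometric record for one field."""

    field_id: str
    condition: str
    nuclei_count: int
    total_neurite_length_um: float
    neurite_length_per_cell_um: float  # NaN when nuclei_count == 0
    neurite_component_count: int
    branch_point_count: int
    neurite_positive_cell_fraction: float  # NaN when nuclei_count == 0
    excluded: bool = False  # True when the field cannot enter statistics
    pixel_size_um: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "field_id": self.field_id,
            "condition": self.condition,
            "nuclei_count": self.nuclei_count,
            "total_neurite_length_um": self.total_neurite_length_um,
            "neurite_length_per_cell_um": self.neurite_length_per_cell_um,
            "neurite_component_count": self.neurite_component_count,
            "branch_point_count": self.branch_point_count,
            "neurite_positive_cell_fraction": self.neurite_positive_cell_fraction,
            "excluded": self.excluded,
            "pixel_size_um": self.pixel_size_um,
        }


def assign_components_to_cells(
    skeleton: NeuriteSkeleton, nuclei: NucleiResult
) -> Dict[int, int]:
    """Assign every skeleton component to a nucleus label.

    A component goes to the nucleus whose centroid is nearest to the
    component's closest pixel; exact ties go to the lower nucleus label.
    Deterministic.
    """
    if nuclei.count < 1:
        raise AssignmentError("cannot assign components: zero nuclei")
    centroids = np.asarray(nuclei.centroids, dtype=np.float64)  # (N, 2)
    mapping: Dict[int, int] = {}
    for comp in skeleton.components:
        pix = comp.pixels.astype(np.float64)  # (k, 2)
        # distance from each nucleus centroid to its closest component pixel
        d = np.sqrt(((pix[None, :, :] - centroids[:, None, :]) ** 2).sum(axis=2)).min(axis=1)
        best = int(np.flatnonzero(d == d.min()).min())  # lower label on ties
        mapping[comp.component_id] = best + 1
    return mapping


def quantify_field(
    nuclei: NucleiResult,
    skeleton: NeuriteSkeleton,
    params: QuantParams = QuantParams(),
    field_id: str = "",
    condition: str = "",
) -> FieldMetrics:
    """Compute the per-field morphometric record.

    A cell is neurite-positive when the summed length of its assigned
    components reaches ``min_neurite_length_um``.  When the field has no
    nuclei the per-cell quantities are undefined (NaN) and the field is
    marked excluded from statistics.
    """
    total = skeleton.total_length_um
    n_comp = len(skeleton.components)
    n_branch = len(skeleton.branch_points)
    if nuclei.count == 0:
        return FieldMetrics(
            field_id=field_id,
            condition=condition,
            nuclei_count=0,
            total_neurite_length_um=total,
            neurite_length_per_cell_um=math.nan,
            neurite_component_count=n_comp,
            branch_point_count=n_branch,
            neurite_positive_cell_fraction=math.nan,
            excluded=True,
            pixel_size_um=skeleton.pixel_size_um,
        )
    per_cell_length = np.zeros(nuclei.count)
    if n_comp:
        mapping = assign_components_to_cells(skeleton, nuclei)
        for comp in skeleton.components:
            per_cell_length[mapping[comp.component_id] - 1] += comp.length_um
    positive = int((per_cell_length >= params.min_neurite_length_um).sum())
    return FieldMetrics(
        field_id=field_id,
        condition=condition,
        nuclei_count=nuclei.count,
        total_neurite_length_um=total,
        neurite_length_per_cell_um=total / nuclei.count,
        neurite_component_count=n_comp,
        branch_point_count=n_branch,
        neurite_positive_cell_fraction=positive / nuclei.count,
        excluded=False,
        pixel_size_um=skeleton.pixel_size_um,
    )
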