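"""Vesselness thresholding, connected-component size filtering, and
PVS volume/ratio quantification.

The segmentation rule is deliberately simple: voxels inside the
white-matter mask with vesselness above a fixed threshold (0.05) are
candidates; connected components (26-connectivity by default) smaller
than 5 voxels are discarded as noise islands and components larger than
150 voxels are discarded as non-PVS hypointensities (ventriculostomy
catheters, leukoencephalopathy). The retained mask is quantified as a
volume in cm^3 and as a ratio in permil of the white-matter volume.

Size bounds are interpreted in voxels on the native grid (the method
was defined on a 1 mm isotropic grid); a warning is emitted for other
spacings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import BinaryMask3D, check_same_grid
from .vesselness import VesselnessMap

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationParams:
    """Threshold and size-filter settings.

    ``threshold`` is a strict cutoff (vesselness > threshold);
    components with fewer than ``min_size_voxels`` or more than
    ``max_size_voxels`` voxels are removed whole.
    """

    threshold: float = 0.05
    min_size_voxels: int = 5
    max_size_voxels: int = 150
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if not (0 < self.min_size_voxels <= self.max_size_voxels):
            raise ValueError(
                "size bounds must satisfy 0 < min <= max, got "
                f"{self.min_size_voxels}/{self.max_size_voxels}"
            )
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {tuple(_CONNECTIVITY_RANK)}")


@dataclass
class PVSMeasurement:
    """Per-exam PVS quantification."""

    pvs_volume_cm3: float
    wm_volume_cm3: float
    pvs_ratio_permil: float
    n_components: int


def segment_pvs(
    vesselness: VesselnessMap,
    wm_mask: BinaryMask3D,
    params: SegmentationParams | None = None,
) -> tuple[BinaryMask3D, pd.DataFrame]:
    """Threshold a vesselness map and size-filter its components.

    Returns the retained PVS mask and a component table with one row
    per candidate component: label, voxel count, size in mm^3,
    centroid, retained flag and rejection reason (``below_min``,
    ``above_max`` or ``none``). Labels are assigned in lexicographic
    order of each component's first voxel index, so the table is
    deterministic.
    """
    params = params or SegmentationParams()
    vol = vesselness.as_volume()
    check_same_grid(vol, wm_mask)
    spacing = wm_mask.voxel_size_mm
    if not np.allclose(spacing, 1.0, atol=1e-6):
        warnings.warn(
            f"size bounds are applied in voxels on a non-1mm grid (spacing {spacing})",
            stacklevel=2,
        )

    candidates = (vesselness.data > params.threshold) & wm_mask.data
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[params.connectivity]
    )
    labels, n = ndimage.label(candidates, structure=structure)

    rows = []
    keep = np.zeros_like(candidates)
    if n > 0:
        counts = np.bincount(labels.reshape(-1))[1:]  # skip background
        centroids = ndimage.center_of_mass(candidates, labels, range(1, n + 1))
        voxel_mm3 = wm_mask.voxel_volume_mm3
        retained_labels = []
        for lab in range(1, n + 1):
            size = int(counts[lab - 1])
            if size < params.min_size_voxels:
                reason = "below_min"
            elif size > params.max_size_voxels:
                reason = "above_max"
            else:
                reason = "none"
                retained_labels.append(lab)
            cz = centroids[lab - 1]
            rows.append(
                {
                    "label": lab,
                    "voxel_count": size,
                    "size_mm3": size * voxel_mm3,
                    "centroid_i": cz[0],
                    "centroid_j": cz[1],
                    "centroid_k": cz[2],
                    "retained": reason == "none",
                    "rejection_reason": reason,
                }
            )
        if retained_labels:
            keep = np.isin(labels, retained_labels)

    table = pd.DataFrame(
        rows,
        columns=[
            "label",
            "voxel_count",
            "size_mm3",
            "centroid_i",
            "centroid_j",
            "centroid_k",
            "retained",
            "rejection_reason",
        ],
    )
    return BinaryMask3D(keep, wm_mask.affine), table


def quantify(pvs_mask: BinaryMask3D, wm_mask: BinaryMask3D) -> PVSMeasurement:
    """PVS volume (cm^3) and ratio (permil of WM volume) from masks.

    ``pvs_mask`` must be contained in ``wm_mask``.
    """
    check_same_grid(pvs_mask, wm_mask)
    outside = int((pvs_mask.data & ~wm_mask.data).sum())
    if outside:
        raise ValueError(
            f"pvs_mask has {outside} voxels outside the white-matter mask"
        )
    if wm_mask.n_voxels == 0:
        raise ZeroDivisionError("white-matter mask is empty")
    voxel_cm3 = wm_mask.voxel_volume_mm3 / 1000.0
    pvs_cm3 = pvs_mask.n_voxels * voxel_cm3
    wm_cm3 = wm_mask.n_voxels * voxel_cm3
    structure = ndimage.generate_binary_structure(3, 3)
    _, n_comp = ndimage.label(pvs_mask.data, structure=structure)
    return PVSMeasurement(
        pvs_volume_cm3=pvs_cm3,
        wm_volume_cm3=wm_cm3,
        pvs_ratio_permil=1000.0 * pvs_cm3 / wm_cm3,
        n_components=int(n_comp),
    )
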