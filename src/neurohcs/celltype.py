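"""Cell-type composition and marker-overlay metrics.

MAP2 (neuronal) and GFAP (astrocytic) thresholded pixel areas, their ratio,
the percentage of neurons among all cells, GLUT4 overlay intensities inside
each cell-type mask, and per-cell intensity metrics for vGluT1, synapsin I
and calcein.  Where the MAP2 and GFAP masks overlap, a pixel contributes to
both overlays: the two masks are independent ROIs, not a partition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import SiteImage
from .segmentation import ThresholdSet, channel_area_mask
from .drebrin import integrated_intensity

__all__ = [
    "CellTypeAreas",
    "celltype_areas",
    "overlay_intensity",
    "per_cell_intensity",
    "neuron_percentage",
]


@dataclass
class CellTypeAreas:
    map2_mask: np.ndarray
    map2_area: int
    gfap_mask: np.ndarray
    gfap_area: int
    map2_gfap_ratio: float  # NaN (flagged missing) when gfap_area == 0

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.map2_gfap_ratio)


def celltype_areas(image: SiteImage, thresholds: ThresholdSet) -> CellTypeAreas:
    """Total MAP2 and GFAP thresholded pixel areas and their ratio.

    A zero GFAP area flags the ratio as missing (NaN), never infinity.
    """
    map2_mask, map2_area = channel_area_mask(image, "map2", thresholds["map2"])
    gfap_mask, gfap_area = channel_area_mask(image, "gfap", thresholds["gfap"])
    ratio = map2_area / gfap_area if gfap_area > 0 else math.nan
    return CellTypeAreas(map2_mask, map2_area, gfap_mask, gfap_area, ratio)


def overlay_intensity(
    image: SiteImage, target_role: str, mask: np.ndarray
) -> tuple[int, float]:
    """Integrated intensity of ``target_role`` inside ``mask`` and the
    per-pixel-area value (intensity / mask area; NaN for an empty mask)."""
    total = integrated_intensity(image.channel(target_role), mask)
    area = int(np.asarray(mask, dtype=bool).sum())
    per_px = total / area if area > 0 else math.nan
    return total, per_px


def per_cell_intensity(
    image: SiteImage, role: str, threshold: int, nuclei_count: int
) -> float:
    """Thresholded integrated intensity normalised per cell (grey/cell).

    Pixels below ``threshold`` are zeroed before integration; the remainder
    is divided by the DAPI nucleus count.  A site with zero nuclei yields
    NaN and is excluded downstream.
    """
    if nuclei_count < 0:
        raise ValueError("nuclei_count must be >= 0")
    if nuclei_count == 0:
        return math.nan
    channel = image.channel(role)
    total = integrated_intensity(channel, channel >= threshold)
    return total / nuclei_count


def neuron_percentage(map2_positive: int, total: int) -> tuple[float, float]:
    """Percentage of MAP2-positive cells (neurons) and its complement
    (other cell types); the two always sum to 100."""
    if total <= 0:
        raise ValueError("total cell count must be > 0")
    if not (0 <= map2_positive <= total):
        raise ValueError("0 <= map2_positive <= total violated")
    pct = 100.0 * map2_positive / total
    return pct, 100.0 - pct
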