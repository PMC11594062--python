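"""Threshold calibration, nuclei detection, ROI dilation and channel-area masks.

The geometric core of the quantification macro: per-culture grey-level
thresholds are calibrated once on a random sample of sites, nuclei are
detected in the DAPI channel as size/shape-filtered connected components,
and each nucleus label is dilated into a soma-ROI.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .model import MAX_GREY, SiteImage

__all__ = [
    "LabelMap",
    "ThresholdSet",
    "otsu_threshold",
    "estimate_culture_thresholds",
    "detect_nuclei",
    "dilate_labels",
    "dilate_labels_sequential",
    "channel_area_mask",
]


@dataclass
class LabelMap:
    """Integer raster on the image grid: 0 = background, k >= 1 = cell k.

    Labels are contiguous ``1..label_count``; each label's pixel set is
    8-connected (constructors enforce this).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        self.labels = self.labels.astype(np.int32, copy=False)

    @property
    def label_count(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def areas(self) -> np.ndarray:
        """Pixel area per label, index 0 -> label 1."""
        return np.bincount(self.labels.ravel(), minlength=self.label_count + 1)[1:]


@dataclass
class ThresholdSet:
    """Per-channel-role grey-level thresholds with calibration provenance."""

    values: dict[str, int]
    method: str = "otsu"
    sample_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for role, v in self.values.items():
            if not (0 <= v <= MAX_GREY):
                raise ValueError(f"threshold for {role!r} outside [0, {MAX_GREY}]")

    def __getitem__(self, role: str) -> int:
        return self.values[role]


def otsu_threshold(hist: np.ndarray) -> int:
    """Exhaustive Otsu scan over a full grey-level histogram.

    Maximises the between-class variance of the split {v < t} vs {v >= t}
    over every candidate level t; ties resolve to the lowest t.  Foreground
    is everywhere defined as ``pixel >= t``.

    Raises ``ValueError`` on a constant histogram (single occupied level).
    """
    counts = np.asarray(hist, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array of level counts")
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise ValueError("empty histogram")
    if nz.size == 1:
        raise ValueError("constant histogram: no separable classes")
    levels = np.arange(counts.size, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]          # weight of class {v < t} for t = 1..L-1
    s0 = np.cumsum(counts * levels)[:-1]
    total = w0[-1] + counts[-1]
    stotal = s0[-1] + counts[-1] * levels[-1]
    w1 = total - w0
    s1 = stotal - s0
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.full(w0.shape, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = s0 / w0 - s1 / w1
    bcv[valid] = (w0 * w1)[valid] * diff[valid] ** 2
    return int(np.argmax(bcv)) + 1       # argmax takes the first (lowest) tie


def estimate_culture_thresholds(
    sample_images: list[SiteImage],
    sample_size: int,
    method: str = "otsu",
    seed: int | np.random.Generator = 0,
    roles: tuple[str, ...] | None = None,
    fixed_values: dict[str, int] | None = None,
) -> ThresholdSet:
    """Calibrate one threshold per channel role for a whole culture.

    Draws a seeded random sample of ``sample_size`` images, pools their
    per-role pixel histograms, and applies Otsu's criterion to each pooled
    histogram (method "otsu"), or echoes configured values (method "fixed").
    Deterministic given the seed.  A constant pooled histogram yields the
    maximum observed grey level with a warning.
    """
    if method == "fixed":
        if not fixed_values:
            raise ValueError("method 'fixed' requires fixed_values")
        return ThresholdSet(dict(fixed_values), method="fixed")
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if not sample_images:
        raise ValueError("empty sample: no images to calibrate on")
    if sample_size > len(sample_images):
        raise ValueError("sample_size exceeds available images")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(sample_images), size=sample_size, replace=False)
    sample = [sample_images[i] for i in sorted(picks)]

    if roles is None:
        roles = tuple(sample[0].channel_map.roles)
    values: dict[str, int] = {}
    for role in roles:
        hist = np.zeros(MAX_GREY + 1, dtype=np.int64)
        for img in sample:
            hist += np.bincount(img.channel(role).ravel(), minlength=MAX_GREY + 1)
        try:
            values[role] = otsu_threshold(hist)
        except ValueError:
            level = int(np.flatnonzero(hist)[-1])
            warnings.warn(
                f"constant histogram for role {role!r}; threshold set to the "
                f"maximum observed grey level {level}",
                stacklevel=2,
            )
            values[role] = level
    ids = tuple(f"{im.ids.group}/w{im.ids.well}/s{im.ids.site}" for im in sample)
    return ThresholdSet(values, method="otsu", sample_ids=ids)


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0  # single pixel / degenerate outline: treat as round
    return 4.0 * np.pi * area / perimeter**2


def detect_nuclei(
    image: SiteImage,
    threshold: int,
    min_area: int = 30,
    max_area: int = 500,
    min_circularity: float = 0.3,
) -> LabelMap:
    """Detect and count nuclei in the DAPI channel (particle analysis).

    Binarises DAPI at ``threshold``, labels 8-connected components, discards
    components outside [min_area, max_area] px or below ``min_circularity``
    (4*pi*A/P^2), and relabels the survivors contiguously in scan order.
    ``label_count`` is the reported cell count.
    """
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    binary = image.channel("nuclei") >= threshold
    raw = measure.label(binary, connectivity=2)
    if raw.max() == 0:
        return LabelMap(np.zeros_like(raw, dtype=np.int32))
    keep = []
    for prop in measure.regionprops(raw):
        if not (min_area <= prop.area <= max_area):
            continue
        if _circularity(prop.area, prop.perimeter) < min_circularity:
            continue
        keep.append(prop.label)
    out = np.zeros_like(raw, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[raw == old] = new
    return LabelMap(out)


def dilate_labels(labels: LabelMap, radius: int) -> LabelMap:
    """Grow every label by a disk of ``radius`` px into a soma-ROI map.

    Where dilations collide, each contested pixel is assigned to the nearest
    original label (Euclidean distance to the label's pixel set); exact ties
    go to the lower label id.  The rule is order-independent, unlike the
    sequential macro it stands in for (see ``dilate_labels_sequential``).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    lab = labels.labels
    if radius == 0 or labels.label_count == 0:
        return LabelMap(lab.copy())
    out = np.zeros_like(lab)
    best = np.full(lab.shape, np.inf)
    for k in range(1, labels.label_count + 1):
        dist = ndi.distance_transform_edt(lab != k)
        take = (dist <= radius) & (dist < best)  # strict <: ties keep lower id
        out[take] = k
        best[take] = dist[take]
    return LabelMap(out)


def dilate_labels_sequential(labels: LabelMap, radius: int) -> list[tuple[int, np.ndarray]]:
    """Fidelity mode: dilate each label independently, allowing overlaps.

    Mirrors the sequential ImageJ-order behaviour of the original macro;
    returns (label, boolean mask) pairs in ascending label order.  Overlap
    resolution is left to the measurement step's sequential deletion.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    foot = morphology.disk(radius) if radius > 0 else None
    rois = []
    for k in range(1, labels.label_count + 1):
        m = labels.mask(k)
        if foot is not None:
            m = ndi.binary_dilation(m, structure=foot)
        rois.append((k, m))
    return rois


def channel_area_mask(
    image: SiteImage, role: str, threshold: int
) -> tuple[np.ndarray, int]:
    """Thresholded-area ROI for a whole channel: (mask, pixel area)."""
    mask = image.channel(role) >= threshold
    return mask, int(mask.sum())
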