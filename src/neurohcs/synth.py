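"""Synthetic plates, qPCR tables and plate-reader tables with planted truth.

The generator emulates the statistical structure the analysis assumes rather
than photorealistic microscopy: nuclei are disks, neuron somata are dilated
nuclei, neurites are random-walk polylines 1-3 px wide, astrocytes are
irregular multi-lobed blobs, and "other" cells carry DAPI only (the
MAP2-negative, GFAP-negative population).  Structures are painted additively
on a flat background, then blurred (Gaussian PSF), then degraded with
Poisson shot noise plus additive Gaussian read noise, then clipped to the
16-bit range.  The ground truth records the pre-noise scene, so every
downstream measurement has an exact oracle.

Region defaults follow the observed culture composition: hippocampal plates
have fewer neurons than other cell types (neuron fraction 0.35), cortical
plates the opposite (0.60).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .model import (
    MAX_GREY,
    VEHICLE_LABEL,
    ChannelMap,
    PlacementError,
    PlateLayout,
    SiteIds,
    SiteImage,
)

__all__ = [
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "EffectModel",
    "generate_site_image",
    "generate_plate",
    "add_debris",
    "generate_cq_table",
    "generate_amplification_curve",
    "generate_absorbance_table",
    "hippocampal_spec",
    "cortical_spec",
]

REFERENCE_GENES = ("Actb", "Rplp0", "Rpl19")
TARGET_GENES = ("Dbn1", "Gfap", "Glut1", "Glut3", "Glut4", "Lnpep", "Map2")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic site.

    Intensities are per-pixel grey levels painted additively onto the
    ``background``; all are integers so that the zero-noise scene is exactly
    integer-valued and pixel-sum bookkeeping is exact.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 40
    neuron_fraction: float = 0.35
    astrocyte_fraction: float = 0.25
    nucleus_radius: tuple[int, int] = (4, 6)
    #: soma mask = morphological dilation of the nucleus mask by this disk
    #: radius; a pipeline run with the same dilation radius reproduces the
    #: soma-ROI exactly.
    soma_dilation_px: int = 4
    neurites_per_neuron: tuple[int, int] = (2, 4)
    neurite_length: tuple[int, int] = (20, 50)
    neurite_width: tuple[int, int] = (1, 3)
    dapi_nucleus: int = 3000
    primary_soma: int = 1200
    primary_neurite: int = 800
    primary_astrocyte: int = 0
    primary_other: int = 0
    map2_soma: int = 1500
    map2_neurite: int = 900
    gfap_astrocyte: int = 1400
    astro_radius: tuple[int, int] = (8, 12)
    astro_lobes: int = 3
    background: int = 100
    poisson_noise: bool = True
    gaussian_noise_sd: float = 50.0
    blur_sigma: float = 1.0
    min_separation: int = 22
    max_place_tries: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.neuron_fraction <= 1 and 0 <= self.astrocyte_fraction <= 1):
            raise ValueError("cell-type fractions must lie in [0, 1]")
        if self.neuron_fraction + self.astrocyte_fraction > 1 + 1e-12:
            raise ValueError("neuron_fraction + astrocyte_fraction must be <= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("dapi_nucleus", "primary_soma", "primary_neurite",
                     "primary_astrocyte", "primary_other", "map2_soma",
                     "map2_neurite", "gfap_astrocyte", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "SceneSpec":
        return replace(self, poisson_noise=False, gaussian_noise_sd=0.0,
                       blur_sigma=0.0)

    def type_counts(self) -> tuple[int, int, int]:
        """Deterministic (neurons, astrocytes, other) counts from fractions."""
        n_neu = int(round(self.neuron_fraction * self.n_cells))
        n_ast = int(round(self.astrocyte_fraction * self.n_cells))
        if n_neu + n_ast > self.n_cells:
            n_ast = self.n_cells - n_neu
        return n_neu, n_ast, self.n_cells - n_neu - n_ast


def hippocampal_spec(**overrides) -> SceneSpec:
    """Default hippocampal composition: neurons < other cell types."""
    return replace(SceneSpec(neuron_fraction=0.35, astrocyte_fraction=0.25),
                   **overrides)


def cortical_spec(**overrides) -> SceneSpec:
    """Default cortical composition: neurons > other cell types."""
    return replace(SceneSpec(neuron_fraction=0.60, astrocyte_fraction=0.15),
                   **overrides)


@dataclass
class CellTruth:
    cell_id: int
    cell_type: str  # neuron | astrocyte | other
    center: tuple[int, int]
    nucleus_mask: np.ndarray
    soma_mask: np.ndarray | None = None
    neurite_mask: np.ndarray | None = None
    body_mask: np.ndarray | None = None  # astrocyte body
    #: noiseless integrated intensity painted per (role, structure)
    contributions: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def nucleus_area(self) -> int:
        return int(self.nucleus_mask.sum())


@dataclass
class GroundTruth:
    """Planted scene record for one synthetic site (pre-noise/pre-blur)."""

    spec: SceneSpec
    cells: list[CellTruth]
    #: per role: pixel count where any structure was painted
    channel_foreground_area: dict[str, int]
    #: per role: noiseless channel sum including background
    channel_total: dict[str, int]
    #: per role: noiseless integrated intensity over the union of true soma
    #: masks (what an exact soma-ROI measurement of this scene would read,
    #: background and crossing neurites included)
    soma_roi_noiseless: dict[str, int]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def count(self, cell_type: str) -> int:
        return sum(1 for c in self.cells if c.cell_type == cell_type)

    def contribution_sum(self, role: str, structure: str) -> int:
        return sum(c.contributions.get(role, {}).get(structure, 0)
                   for c in self.cells)


@dataclass(frozen=True)
class EffectModel:
    """Per-group multiplicative factors on scene parameters.

    ``factors`` maps a treatment-group label to ``{SceneSpec field: factor}``.
    All factors must be > 0 and any vehicle entry must be exactly 1: the
    vehicle scene *is* the base scene.
    """

    factors: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, fs in self.factors.items():
            for name, fac in fs.items():
                if fac <= 0:
                    raise ValueError(f"factor {name}={fac} for {label!r} must be > 0")
                if label == VEHICLE_LABEL and fac != 1:
                    raise ValueError("vehicle factors must equal 1")

    def spec_for(self, base: SceneSpec, group_label: str) -> SceneSpec:
        fs = self.factors.get(group_label, {})
        changes = {}
        for name, fac in fs.items():
            value = getattr(base, name)
            scaled = value * fac
            if isinstance(value, int):
                scaled = int(round(scaled))
            changes[name] = scaled
        return replace(base, **changes) if changes else base


def _disk_mask(shape: tuple[int, int], center: tuple[int, int],
               radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    h, w = spec.shape
    margin = spec.nucleus_radius[1] + spec.soma_dilation_px + 1
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        if spec.n_cells > 0:
            raise PlacementError("image too small for the requested cells")
        return []
    centers: list[tuple[int, int]] = []
    min_d2 = spec.min_separation**2
    for _ in range(spec.n_cells):
        for _try in range(spec.max_place_tries):
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1}/{spec.n_cells} at "
                f"separation {spec.min_separation}px after "
                f"{spec.max_place_tries} tries"
            )
    return centers


def _neurite_mask(spec: SceneSpec, start: tuple[float, float], heading: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Random-walk polyline from the soma edge, 1-3 px wide."""
    h, w = spec.shape
    length = int(rng.integers(spec.neurite_length[0], spec.neurite_length[1] + 1))
    width = int(rng.integers(spec.neurite_width[0], spec.neurite_width[1] + 1))
    mask = np.zeros(spec.shape, dtype=bool)
    r, c = start
    for _ in range(length):
        heading += rng.normal(0.0, 0.25)
        r += np.sin(heading)
        c += np.cos(heading)
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w:
            mask[ri, ci] = True
        else:
            break
    if width == 2:
        mask = ndi.binary_dilation(mask, structure=np.ones((2, 2), bool))
    elif width >= 3:
        mask = ndi.binary_dilation(mask, structure=morphology.disk(1))
    return mask


def _astro_body(spec: SceneSpec, center: tuple[int, int],
                rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(max(1, spec.astro_lobes)):
        rad = int(rng.integers(spec.astro_radius[0], spec.astro_radius[1] + 1))
        dr = int(rng.integers(-rad // 2, rad // 2 + 1))
        dc = int(rng.integers(-rad // 2, rad // 2 + 1))
        mask |= _disk_mask(spec.shape, (center[0] + dr, center[1] + dc), rad)
    return mask


def generate_site_image(
    spec: SceneSpec,
    channel_map: ChannelMap,
    seed: int | np.random.SeedSequence | np.random.Generator,
    ids: SiteIds | None = None,
) -> tuple[SiteImage, GroundTruth]:
    """Render one synthetic site and its exact pre-noise ground truth.

    Deterministic given the seed.  With blur and noise disabled, every
    channel's pixel sum equals the truth contributions plus
    ``background * height * width`` exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = ids or SiteIds("synthetic", VEHICLE_LABEL, 0, 0)
    h, w = spec.shape
    n_ch = channel_map.n_channels
    scene = np.zeros((n_ch, h, w), dtype=np.int64)  # painted structures only

    n_neu, n_ast, n_oth = spec.type_counts()
    types = ["neuron"] * n_neu + ["astrocyte"] * n_ast + ["other"] * n_oth
    centers = _place_centers(spec, rng)

    # nuclei first, so later structures can be kept off other cells' nuclei
    radii = [int(rng.integers(spec.nucleus_radius[0], spec.nucleus_radius[1] + 1))
             for _ in centers]
    nucleus_masks = [_disk_mask(spec.shape, ctr, rad)
                     for ctr, rad in zip(centers, radii)]
    nuclei_union = np.zeros(spec.shape, dtype=bool)
    for m in nucleus_masks:
        nuclei_union |= m

    soma_foot = (morphology.disk(spec.soma_dilation_px)
                 if spec.soma_dilation_px > 0 else None)
    cells: list[CellTruth] = []
    soma_union = np.zeros(spec.shape, dtype=bool)

    def paint(role: str, mask: np.ndarray, level: int,
              cell: CellTruth, structure: str) -> None:
        if level <= 0 or not channel_map.has(role):
            return
        ch = channel_map.index(role)
        scene[ch][mask] += level
        cell.contributions.setdefault(role, {})[structure] = int(level * mask.sum())

    for i, (ctr, ctype, nmask) in enumerate(zip(centers, types, nucleus_masks)):
        cell = CellTruth(cell_id=i + 1, cell_type=ctype, center=ctr,
                         nucleus_mask=nmask)
        others_nuclei = nuclei_union & ~nmask
        paint("nuclei", nmask, spec.dapi_nucleus, cell, "nucleus")
        if ctype == "neuron":
            soma = (ndi.binary_dilation(nmask, structure=soma_foot)
                    if soma_foot is not None else nmask.copy())
            cell.soma_mask = soma
            soma_union |= soma
            paint("primary_marker", soma, spec.primary_soma, cell, "soma")
            paint("map2", soma, spec.map2_soma, cell, "soma")
            n_neur = int(rng.integers(spec.neurites_per_neuron[0],
                                      spec.neurites_per_neuron[1] + 1))
            neurite = np.zeros(spec.shape, dtype=bool)
            reach = radii[i] + spec.soma_dilation_px + 1
            for _ in range(n_neur):
                theta = rng.uniform(0, 2 * np.pi)
                start = (ctr[0] + reach * np.sin(theta),
                         ctr[1] + reach * np.cos(theta))
                neurite |= _neurite_mask(spec, start, theta, rng)
            neurite &= ~soma
            neurite &= ~others_nuclei
            cell.neurite_mask = neurite
            paint("primary_marker", neurite, spec.primary_neurite, cell, "neurite")
            paint("map2", neurite, spec.map2_neurite, cell, "neurite")
        elif ctype == "astrocyte":
            body = _astro_body(spec, ctr, rng) & ~others_nuclei
            cell.body_mask = body
            paint("gfap", body, spec.gfap_astrocyte, cell, "body")
            paint("primary_marker", body, spec.primary_astrocyte, cell, "body")
        else:
            paint("primary_marker", nmask, spec.primary_other, cell, "nucleus")
        cells.append(cell)

    foreground_area = {role: int((scene[ch] > 0).sum())
                       for role, ch in channel_map.roles.items()}
    noiseless = scene + spec.background
    channel_total = {role: int(noiseless[ch].sum())
                     for role, ch in channel_map.roles.items()}
    soma_roi = {role: int(noiseless[ch][soma_union].sum())
                for role, ch in channel_map.roles.items()}
    truth = GroundTruth(spec=spec, cells=cells,
                        channel_foreground_area=foreground_area,
                        channel_total=channel_total,
                        soma_roi_noiseless=soma_roi)

    img = noiseless.astype(np.float64)
    if spec.blur_sigma > 0:
        for ch in range(n_ch):
            img[ch] = ndi.gaussian_filter(img[ch], spec.blur_sigma)
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, MAX_GREY).astype(np.uint16)
    return SiteImage(pixels, channel_map, ids), truth


def generate_plate(
    layout: PlateLayout,
    spec: SceneSpec,
    channel_map: ChannelMap,
    effect: EffectModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[SiteImage], list[GroundTruth]]:
    """One SiteImage per (group, well, site) with effect-scaled scene specs.

    Site seeds are spawned deterministically from the master seed, so any
    single site can be regenerated in isolation.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(layout.n_sites)
    effect = effect or EffectModel()
    images: list[SiteImage] = []
    truths: list[GroundTruth] = []
    for child, (group, well, site) in zip(children, layout.iter_sites()):
        gspec = effect.spec_for(spec, group.label)
        ids = SiteIds(layout.culture_id, group.label, well, site)
        img, truth = generate_site_image(gspec, channel_map, child, ids=ids)
        images.append(img)
        truths.append(truth)
    return images, truths


def add_debris(image: SiteImage, fraction: float = 0.85, level: int = 20000,
               seed: int = 0) -> SiteImage:
    """Plant an oversized bright blob covering ``fraction`` of every channel
    (a QC test article, not part of the scene model)."""
    rng = np.random.default_rng(seed)
    h, w = image.shape
    radius = int(np.sqrt(fraction * h * w / np.pi)) + 1
    ctr = (int(rng.integers(h // 3, 2 * h // 3)), int(rng.integers(w // 3, 2 * w // 3)))
    blob = _disk_mask((h, w), ctr, radius)
    pixels = image.pixels.astype(np.int64).copy()
    pixels[:, blob] += level
    pixels = np.clip(pixels, 0, MAX_GREY).astype(np.uint16)
    return SiteImage(pixels, image.channel_map, image.ids, image.qc_flags)


# --------------------------------------------------------------------------
# qPCR and plate-reader generators
# --------------------------------------------------------------------------

def generate_cq_table(
    group_labels: Sequence[str],
    fold_changes: Mapping[str, Mapping[str, float]],
    efficiencies: Mapping[str, float] | None = None,
    target_genes: Sequence[str] = TARGET_GENES,
    reference_genes: Sequence[str] = REFERENCE_GENES,
    n_cultures: int = 3,
    replicates: int = 2,
    noise_sd_cq: float = 0.0,
    control_label: str = VEHICLE_LABEL,
    culture_shift_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Long-format Cq table with planted per-gene fold changes.

    ``fold_changes[gene][group]`` is the true abundance of ``gene`` in
    ``group`` relative to the control group; missing entries, the control
    group and all reference genes are fold 1.  The model is

        Cq = baseline(gene) + shift(culture, group) - log_E(fold) + noise,

    where ``shift`` is a per-sample global offset (pipetting / input amount)
    applied to *all* genes of that sample, so normalized quantities are
    invariant to it.  Efficiencies are fold-amplification per cycle in
    (1, 2]; default 2.0 (perfect doubling).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    eff = {g: 2.0 for g in (*target_genes, *reference_genes)}
    if efficiencies:
        eff.update(efficiencies)
    for g, e in eff.items():
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {g} must be in (1, 2], got {e}")
    for gene, per_group in fold_changes.items():
        for grp, f in per_group.items():
            if f <= 0:
                raise ValueError(f"fold change {f} for {gene}/{grp} must be > 0")
    rng = np.random.default_rng(seed)
    baselines = {g: 22.0 for g in target_genes}
    baselines.update({g: 18.0 for g in reference_genes})
    rows = []
    for ci in range(n_cultures):
        culture = f"culture{ci + 1}"
        for grp in group_labels:
            shift = rng.normal(0.0, culture_shift_sd) if culture_shift_sd > 0 else 0.0
            for gene in (*target_genes, *reference_genes):
                fold = 1.0
                if gene in fold_changes and grp != control_label:
                    fold = fold_changes[gene].get(grp, 1.0)
                if gene in reference_genes:
                    fold = 1.0
                cq0 = baselines[gene] + shift - np.log(fold) / np.log(eff[gene])
                for rep in range(1, replicates + 1):
                    noise = rng.normal(0.0, noise_sd_cq) if noise_sd_cq > 0 else 0.0
                    rows.append({
                        "culture": culture, "group": grp, "gene": gene,
                        "replicate": rep, "cq": cq0 + noise,
                    })
    return pd.DataFrame(rows)


def generate_amplification_curve(
    efficiency: float,
    n_cycles: int = 40,
    f0: float = 1e-4,
    plateau: float = 1.0,
    baseline: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Raw qPCR fluorescence readings: exponential phase saturating to a
    plateau on a constant baseline, optionally with Gaussian noise."""
    if not (1.0 < efficiency <= 2.2):
        raise ValueError("efficiency must be in (1, 2.2]")
    if n_cycles < 10:
        raise ValueError("need >= 10 cycles")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1, dtype=np.float64)
    exp = f0 * efficiency**cycles
    fluor = plateau * exp / (plateau + exp) + baseline
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, fluor.shape)
    return np.clip(fluor, 0.0, None)


def generate_absorbance_table(
    group_labels: Sequence[str],
    true_relative_levels: Mapping[str, float],
    assay: str = "mtt",
    n_cultures: int = 3,
    wells_per_group: int = 3,
    scale: float = 1.0,
    blank_level: float = 0.05,
    noise_sd: float = 0.0,
    triton_level: float | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Plate-reader table: absorbance = blank + level*scale + noise.

    Includes Triton-X 100 control wells (group label "triton_x"): near-zero
    signal for the MTT assay (dead cells metabolise nothing) and a high
    signal for LDH (full lysis releases all LDH).
    """
    from .assays import ASSAY_WAVELENGTH_NM  # local import avoids a cycle

    if assay not in ASSAY_WAVELENGTH_NM:
        raise ValueError(f"assay must be one of {tuple(ASSAY_WAVELENGTH_NM)}")
    for grp, level in true_relative_levels.items():
        if level <= 0:
            raise ValueError(f"level for {grp!r} must be > 0")
    if triton_level is None:
        triton_level = 0.02 if assay == "mtt" else 3.0
    wavelength = ASSAY_WAVELENGTH_NM[assay]
    rng = np.random.default_rng(seed)
    rows = []
    for ci in range(n_cultures):
        culture = f"culture{ci + 1}"
        for grp in (*group_labels, "triton_x"):
            level = triton_level if grp == "triton_x" else true_relative_levels.get(grp, 1.0)
            for well in range(1, wells_per_group + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({
                    "culture": culture, "group": grp, "well": well,
                    "wavelength": wavelength,
                    "absorbance": max(blank_level + level * scale + noise, 0.0),
                })
    return pd.DataFrame(rows)
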