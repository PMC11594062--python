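"""Orchestration: generate -> quantify -> aggregate -> test.

The pipeline order follows the quantification macro: detect and count
nuclei, dilate each cell-ROI into a soma-ROI, gate out MAP2-negative cells,
measure the marker partition, then the channel-area and overlay metrics.
Every run writes an audit manifest (thresholds, seeds, parameters) from
which all output numbers are reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import normalize_assay
from .celltype import celltype_areas, neuron_percentage, overlay_intensity, per_cell_intensity
from .drebrin import gate_map2_positive, measure_soma_axon
from .io import qc_flag_image, write_site_image
from .model import (
    DegenerateDataError,
    PlateLayout,
    SiteImage,
    VEHICLE_LABEL,
    default_channel_map,
    standard_groups,
)
from .qpcr import analyze_cq_table
from .segmentation import (
    ThresholdSet,
    detect_nuclei,
    dilate_labels,
    estimate_culture_thresholds,
)
from .stats import aggregate_sites, dunnett, significance_stars, two_way_anova
from .synth import EffectModel, SceneSpec, generate_plate, hippocampal_spec, cortical_spec

__all__ = ["QuantParams", "RunConfig", "quantify_site", "quantify_plate",
           "run_quantify", "run_stats", "run_demo"]


@dataclass(frozen=True)
class QuantParams:
    """Free parameters of the quantification macro (all config-exposed)."""

    dilation_radius: int = 8       # soma-ROI growth, px
    min_area: int = 30             # nucleus size filter, px
    max_area: int = 500
    min_circularity: float = 0.3   # 4*pi*A/P^2
    positivity_fraction: float = 0.25  # MAP2-positive gate
    saturation_fraction_max: float = 0.01
    foreground_fraction_max: float = 0.8
    threshold_method: str = "otsu"
    threshold_sample_size: int = 4
    fixed_thresholds: dict | None = None


@dataclass
class RunConfig:
    """Schema-validated configuration of one synthetic experiment run."""

    seed: int = 0
    region: str = "hippocampal"
    n_cultures: int = 2
    wells_per_group: int = 1
    sites_per_well: int = 3
    marker: str = "drebrin"
    scene: SceneSpec | None = None
    effect: EffectModel | None = None
    quant: QuantParams = field(default_factory=QuantParams)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.region not in ("hippocampal", "cortical"):
            raise ValueError("region must be 'hippocampal' or 'cortical'")
        if self.n_cultures < 1:
            raise ValueError("n_cultures must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.scene is None:
            base = hippocampal_spec() if self.region == "hippocampal" else cortical_spec()
            self.scene = base

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "scene" in kwargs and kwargs["scene"] is not None:
            scene = dict(kwargs["scene"])
            for key in ("shape", "nucleus_radius", "neurites_per_neuron",
                        "neurite_length", "neurite_width", "astro_radius"):
                if key in scene and scene[key] is not None:
                    scene[key] = tuple(scene[key])
            kwargs["scene"] = SceneSpec(**scene)
        if "effect" in kwargs and kwargs["effect"] is not None:
            kwargs["effect"] = EffectModel(kwargs["effect"])
        if "quant" in kwargs and kwargs["quant"] is not None:
            kwargs["quant"] = QuantParams(**kwargs["quant"])
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        return {
            "package_version": __version__,
            "seed": self.seed,
            "region": self.region,
            "n_cultures": self.n_cultures,
            "wells_per_group": self.wells_per_group,
            "sites_per_well": self.sites_per_well,
            "marker": self.marker,
            "scene": enc(self.scene),
            "effect": enc(self.effect.factors) if self.effect else None,
            "quant": enc(self.quant),
            "alpha": self.alpha,
        }

    def layout(self, culture_id: str) -> PlateLayout:
        return PlateLayout(culture_id=culture_id, region=self.region,
                           groups=standard_groups(),
                           wells_per_group=self.wells_per_group,
                           sites_per_well=self.sites_per_well)


def quantify_site(image: SiteImage, thresholds: ThresholdSet,
                  params: QuantParams) -> dict:
    """All metric families for one site, keyed by metric name.

    Which metrics appear depends on the mapped roles and the primary marker:
    drebrin sites get the soma/axon partition, GLUT4 sites the cell-type
    overlays, and the DAPI-plus-marker rounds (vGluT1, synapsin I, calcein)
    the thresholded per-cell intensity.
    """
    cm = image.channel_map
    marker = cm.primary_marker_name
    row: dict = {
        "culture": image.ids.culture, "group": image.ids.group,
        "well": image.ids.well, "site": image.ids.site,
        "qc_flags": ";".join(sorted(image.qc_flags)),
    }
    nuclei = detect_nuclei(image, thresholds["nuclei"], params.min_area,
                           params.max_area, params.min_circularity)
    row["total_cells"] = nuclei.label_count
    soma = dilate_labels(nuclei, params.dilation_radius)

    if cm.has("map2"):
        gate = gate_map2_positive(nuclei, soma, image, thresholds["map2"],
                                  params.positivity_fraction)
        row["map2_positive_cells"] = gate.positive_cells
        if gate.total_cells > 0:
            pct, other = neuron_percentage(gate.positive_cells, gate.total_cells)
            row["neuron_pct"], row["other_pct"] = pct, other
        else:
            row["neuron_pct"] = row["other_pct"] = math.nan
        if cm.has("gfap"):
            areas = celltype_areas(image, thresholds)
            row["map2_area"] = areas.map2_area
            row["gfap_area"] = areas.gfap_area
            row["map2_gfap_ratio"] = areas.map2_gfap_ratio
        if marker == "drebrin":
            metrics = measure_soma_axon(image, gate.soma,
                                        total_cells=gate.total_cells,
                                        map2_positive_cells=gate.positive_cells)
            row["total_drebrin"] = metrics.total_drebrin
            row["soma_drebrin"] = metrics.soma_drebrin
            row["axonal_drebrin"] = metrics.axonal_drebrin
        elif marker == "glut4" and cm.has("gfap"):
            areas = celltype_areas(image, thresholds)
            glut4_total = int(image.channel("primary_marker").sum(dtype=np.int64))
            in_map2, per_map2 = overlay_intensity(image, "primary_marker",
                                                  areas.map2_mask)
            in_gfap, per_gfap = overlay_intensity(image, "primary_marker",
                                                  areas.gfap_mask)
            row.update(glut4_total=glut4_total, glut4_in_map2=in_map2,
                       glut4_in_gfap=in_gfap, glut4_per_map2_px=per_map2,
                       glut4_per_gfap_px=per_gfap)
    if marker in ("vglut1", "synapsin1", "calcein"):
        row[f"{marker}_per_cell"] = per_cell_intensity(
            image, "primary_marker", thresholds["primary_marker"],
            nuclei.label_count)
    return row


def quantify_plate(images: list[SiteImage], params: QuantParams,
                   seed: int = 0) -> tuple[pd.DataFrame, ThresholdSet]:
    """QC, per-culture threshold calibration and site quantification for one
    plate.  Flagged sites keep their row (flag recorded) but are excluded
    from aggregation downstream."""
    flagged = [qc_flag_image(im, params.saturation_fraction_max,
                             params.foreground_fraction_max) for im in images]
    clean = [im for im in flagged if not im.qc_flags]
    if not clean:
        raise DegenerateDataError("every site was QC-flagged; empty plate")
    thresholds = estimate_culture_thresholds(
        clean, min(params.threshold_sample_size, len(clean)),
        method=params.threshold_method, seed=seed,
        fixed_values=params.fixed_thresholds,
    )
    rows = [quantify_site(im, thresholds, params) for im in flagged]
    return pd.DataFrame(rows), thresholds


def run_quantify(config: RunConfig, outdir: str | Path,
                 write_images: bool = False) -> Path:
    """Synthesize every culture's plate, quantify it and write per-site and
    per-culture CSVs plus the audit manifest.  Deterministic given the
    config seed: reruns produce byte-identical outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    culture_seeds = master.spawn(config.n_cultures)
    cm = default_channel_map(config.marker)
    all_sites = []
    thresholds_log = {}
    for ci, cseed in enumerate(culture_seeds):
        culture_id = f"{config.region[:4]}{ci + 1}"
        layout = config.layout(culture_id)
        gen_seed, thr_seed = cseed.spawn(2)
        images, _truths = generate_plate(layout, config.scene, cm,
                                         effect=config.effect, seed=gen_seed)
        site_df, thresholds = quantify_plate(
            images, config.quant, seed=int(thr_seed.generate_state(1)[0] % 2**31))
        if write_images:
            img_dir = outdir / "images" / culture_id
            img_dir.mkdir(parents=True, exist_ok=True)
            for im in images:
                name = f"{im.ids.group}_w{im.ids.well}_s{im.ids.site}.tif"
                write_site_image(im, img_dir / name)
        all_sites.append(site_df)
        thresholds_log[culture_id] = dict(thresholds.values)
    sites = pd.concat(all_sites, ignore_index=True)
    sites.to_csv(outdir / "site_metrics.csv", index=False)
    aggregates = aggregate_sites(sites)
    aggregates.to_csv(outdir / "culture_metrics.csv", index=False)
    manifest = config.to_manifest()
    manifest["thresholds"] = thresholds_log
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def run_stats(metrics: pd.DataFrame | str | Path, config: RunConfig,
              outdir: str | Path | None = None) -> pd.DataFrame:
    """Two-way ANOVA + Dunnett-vs-vehicle per metric, with star annotations.

    Input is the long per-culture table written by ``run_quantify``.  Raises
    on insufficient replication (< 2 complete cultures).
    """
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.read_csv(Path(metrics) / "culture_metrics.csv"
                              if Path(metrics).is_dir() else metrics)
    rows = []
    for metric, sub in metrics.groupby("metric"):
        sub = sub.dropna(subset=["value"])
        try:
            anova = two_way_anova(sub)
        except DegenerateDataError:
            raise
        rows.append({
            "metric": metric, "group": "(overall)", "estimate": np.nan,
            "F": anova.treatment_f, "p": anova.treatment_p,
            "p_adjusted": np.nan,
            "stars": significance_stars(anova.treatment_p),
            "design": anova.design,
        })
        comp = dunnett(sub, VEHICLE_LABEL, anova=anova, seed=config.seed)
        for _, c in comp.iterrows():
            rows.append({
                "metric": metric, "group": c["group"], "estimate": c["estimate"],
                "F": np.nan, "p": c["p_unadjusted"], "p_adjusted": c["p_adjusted"],
                "stars": c["stars"], "design": anova.design,
            })
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "stats.csv", index=False)
    return table


def run_demo(outdir: str | Path, seed: int = 0, n_cultures: int = 2) -> Path:
    """Reproducible end-to-end demo: small synthetic drebrin experiment with
    a planted soma-drebrin increase at 1e-06 M, quantified and tested."""
    from .experiments import demo_config

    config = demo_config(seed=seed, n_cultures=n_cultures)
    outdir = Path(outdir)
    run_quantify(config, outdir)
    metrics = pd.read_csv(outdir / "culture_metrics.csv")
    run_stats(metrics, config, outdir)
    return outdir
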