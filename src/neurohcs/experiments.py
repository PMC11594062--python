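"""Canned experiments: desk-scale study conditions and recovery checks.

These functions bundle the study conditions the package is validated under:
a scaled-down plate (96x96 px sites, ~10 cells each, 3 sites per group) that
keeps whole-plate simulations fast while exercising every pipeline stage.
The full acquisition layout (9 sites x 3 wells per group, 256x256 default
scenes) remains available through ``PlateLayout`` and ``SceneSpec`` defaults.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PlacementError, VEHICLE_LABEL, default_channel_map
from .pipeline import QuantParams, RunConfig, quantify_plate, run_quantify
from .stats import dunnett, two_way_anova
from .synth import EffectModel, SceneSpec, generate_plate, generate_site_image
from .drebrin import measure_soma_axon
from .segmentation import detect_nuclei, dilate_labels

__all__ = [
    "small_scene",
    "demo_config",
    "soma_drebrin_power",
    "zero_noise_recovery",
    "conservation_sweep",
]

#: label of the concentration carrying the planted effect in the demo/power
#: experiments (1 uM)
EFFECT_GROUP = "1e-06"


def small_scene(noisy: bool = True) -> SceneSpec:
    """Desk-scale drebrin scene: 96x96 px, 10 cells, short neurites."""
    return SceneSpec(
        shape=(96, 96), n_cells=10,
        neuron_fraction=0.4, astrocyte_fraction=0.2,
        nucleus_radius=(4, 5), soma_dilation_px=3,
        neurites_per_neuron=(1, 2), neurite_length=(10, 20),
        min_separation=18, max_place_tries=1000,
        blur_sigma=0.8 if noisy else 0.0,
        poisson_noise=noisy,
        gaussian_noise_sd=60.0 if noisy else 0.0,
    )


def _small_quant(scene: SceneSpec) -> QuantParams:
    return QuantParams(dilation_radius=scene.soma_dilation_px,
                       threshold_sample_size=4)


def demo_config(seed: int = 0, n_cultures: int = 2,
                effect_factor: float = 1.5) -> RunConfig:
    scene = small_scene(noisy=True)
    effect = EffectModel({EFFECT_GROUP: {"primary_soma": effect_factor}})
    return RunConfig(seed=seed, region="hippocampal", n_cultures=n_cultures,
                     wells_per_group=1, sites_per_well=3, marker="drebrin",
                     scene=scene, effect=effect, quant=_small_quant(scene))


@dataclass
class PowerResult:
    detection_rate: float
    adjusted_p: list[float]   # adjusted p of the effect group, per run
    n_runs: int


def soma_drebrin_power(
    n_runs: int = 20,
    n_cultures: int = 8,
    effect_factor: float = 1.5,
    effect_group: str = EFFECT_GROUP,
    seed: int = 0,
) -> PowerResult:
    """Planted-effect recovery: fraction of seeded runs in which the
    two-way-ANOVA + Dunnett pipeline flags the effect concentration
    (adjusted p < 0.05) for soma drebrin."""
    master = np.random.SeedSequence(seed)
    run_seeds = master.generate_state(n_runs) % 2**31
    pvals = []
    for rs in run_seeds:
        config = demo_config(seed=int(rs), n_cultures=n_cultures,
                             effect_factor=effect_factor)
        cm = default_channel_map(config.marker)
        culture_seeds = np.random.SeedSequence(config.seed).spawn(n_cultures)
        rows = []
        for ci, cseed in enumerate(culture_seeds):
            layout = config.layout(f"c{ci + 1}")
            gen_seed, thr_seed = cseed.spawn(2)
            images, _ = generate_plate(layout, config.scene, cm,
                                       effect=config.effect, seed=gen_seed)
            site_df, _thr = quantify_plate(
                images, config.quant,
                seed=int(thr_seed.generate_state(1)[0] % 2**31))
            ok = site_df[site_df["qc_flags"] == ""]
            agg = ok.groupby("group")["soma_drebrin"].mean()
            for grp, val in agg.items():
                rows.append({"culture": f"c{ci + 1}", "group": grp,
                             "value": float(val)})
        values = pd.DataFrame(rows)
        anova = two_way_anova(values)
        comp = dunnett(values, VEHICLE_LABEL, anova=anova, seed=int(rs))
        p = float(comp.set_index("group").loc[effect_group, "p_adjusted"])
        pvals.append(p)
    rate = float(np.mean([p < 0.05 for p in pvals]))
    return PowerResult(detection_rate=rate, adjusted_p=pvals, n_runs=n_runs)


def zero_noise_recovery(seed: int = 0, n_sites: int = 6) -> dict[str, float]:
    """Quantify noiseless synthetic sites and compare against planted truth.

    Returns worst-case absolute errors across sites: nuclei count, MAP2 and
    GFAP thresholded areas, neuron percentage (all expected exact) and the
    relative soma-drebrin error with the dilation radius matched to the
    generator (expected ~0).
    """
    scene = small_scene(noisy=False)
    scene = dataclasses.replace(scene, shape=(160, 160), n_cells=15)
    cm = default_channel_map("drebrin")
    params = _small_quant(scene)
    ss = np.random.SeedSequence(seed)
    worst = {"nuclei_count_error": 0.0, "map2_area_error": 0.0,
             "gfap_area_error": 0.0, "neuron_pct_error": 0.0,
             "soma_drebrin_rel_error": 0.0}
    from .segmentation import estimate_culture_thresholds
    from .celltype import celltype_areas, neuron_percentage
    from .drebrin import gate_map2_positive

    pairs = [generate_site_image(scene, cm, child) for child in ss.spawn(n_sites)]
    thresholds = estimate_culture_thresholds(
        [img for img, _ in pairs], sample_size=min(4, n_sites), seed=seed)
    for img, truth in pairs:
        nuclei = detect_nuclei(img, thresholds["nuclei"], params.min_area,
                               params.max_area, params.min_circularity)
        worst["nuclei_count_error"] = max(
            worst["nuclei_count_error"], abs(nuclei.label_count - truth.n_cells))
        areas = celltype_areas(img, thresholds)
        worst["map2_area_error"] = max(
            worst["map2_area_error"],
            abs(areas.map2_area - truth.channel_foreground_area["map2"]))
        worst["gfap_area_error"] = max(
            worst["gfap_area_error"],
            abs(areas.gfap_area - truth.channel_foreground_area["gfap"]))
        soma = dilate_labels(nuclei, params.dilation_radius)
        gate = gate_map2_positive(nuclei, soma, img, thresholds["map2"],
                                  params.positivity_fraction)
        pct, _ = neuron_percentage(gate.positive_cells, gate.total_cells)
        true_pct = 100.0 * truth.count("neuron") / truth.n_cells
        worst["neuron_pct_error"] = max(worst["neuron_pct_error"],
                                        abs(pct - true_pct))
        metrics = measure_soma_axon(img, gate.soma)
        expected = truth.soma_roi_noiseless["primary_marker"]
        rel = abs(metrics.soma_drebrin - expected) / expected
        worst["soma_drebrin_rel_error"] = max(worst["soma_drebrin_rel_error"], rel)
    return worst


def conservation_sweep(n_sites: int = 1000, seed: int = 0) -> int:
    """Count violations of soma + axonal == total (integer equality) over
    random noisy synthetic sites with randomised scene parameters."""
    rng = np.random.default_rng(seed)
    cm = default_channel_map("drebrin")
    violations = 0
    for child in np.random.SeedSequence(seed).spawn(n_sites):
        scene = SceneSpec(
            shape=(48, 48),
            n_cells=int(rng.integers(0, 6)),
            neuron_fraction=float(rng.uniform(0.2, 0.7)),
            astrocyte_fraction=float(rng.uniform(0.0, 0.3)),
            nucleus_radius=(3, 4), soma_dilation_px=int(rng.integers(0, 4)),
            neurites_per_neuron=(1, 2), neurite_length=(5, 12),
            min_separation=12, gaussian_noise_sd=float(rng.uniform(0, 120)),
            blur_sigma=float(rng.uniform(0, 1.5)),
        )
        try:
            img, _ = generate_site_image(scene, cm, child)
        except PlacementError:
            # crowded draw: rerun the site with a sparser scene
            sparse = dataclasses.replace(scene, n_cells=2)
            img, _ = generate_site_image(sparse, cm, child.spawn(1)[0])
        nuclei = detect_nuclei(img, threshold=1000, min_area=5, max_area=200,
                               min_circularity=0.0)
        soma = dilate_labels(nuclei, int(rng.integers(0, 6)))
        m = measure_soma_axon(img, soma)
        if m.soma_drebrin + m.axonal_drebrin != m.total_drebrin:
            violations += 1
    return violations
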