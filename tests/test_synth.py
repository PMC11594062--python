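import dataclasses

import numpy as np
import pandas as pd
import pytest

from neurohcs.model import PlacementError, PlateLayout, default_channel_map
from neurohcs.synth import (
    EffectModel,
    SceneSpec,
    generate_absorbance_table,
    generate_cq_table,
    generate_plate,
    generate_site_image,
)
from neurohcs.experiments import small_scene


def test_zero_cells_background_only(drebrin_map):
    spec = small_scene(noisy=False)
    spec = dataclasses.replace(spec, n_cells=0)
    img, truth = generate_site_image(spec, drebrin_map, seed=0)
    assert truth.n_cells == 0
    assert (img.pixels == spec.background).all()


def test_determinism_same_seed(noisy_scene, drebrin_map):
    a, _ = generate_site_image(noisy_scene, drebrin_map, seed=42)
    b, _ = generate_site_image(noisy_scene, drebrin_map, seed=42)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    c, _ = generate_site_image(noisy_scene, drebrin_map, seed=43)
    assert (a.pixels != c.pixels).any()


@pytest.mark.parametrize("seed", [0, 7, 19])
def test_zero_noise_bookkeeping_exact(noiseless_scene, drebrin_map, seed):
    """With no blur/noise, each channel's pixel sum equals the truth-table
    structure contributions plus background x area, exactly."""
    img, truth = generate_site_image(noiseless_scene, drebrin_map, seed=seed)
    h, w = noiseless_scene.shape
    for role, ch in drebrin_map.roles.items():
        painted = sum(
            sum(cell.contributions.get(role, {}).values()) for cell in truth.cells
        )
        expected = painted + noiseless_scene.background * h * w
        assert int(img.pixels[ch].sum(dtype=np.int64)) == expected
        assert truth.channel_total[role] == expected


def test_type_counts_deterministic():
    spec = SceneSpec(n_cells=20, neuron_fraction=0.35, astrocyte_fraction=0.25)
    assert spec.type_counts() == (7, 5, 8)


def test_placement_failure():
    spec = small_scene(noisy=False)
    spec = dataclasses.replace(spec, shape=(40, 40), n_cells=30, max_place_tries=20)
    with pytest.raises(PlacementError):
        generate_site_image(spec, default_channel_map("drebrin"), seed=0)


def test_plate_site_count(noisy_scene, drebrin_map):
    """9 sites x 3 wells per group over 6 groups -> 162 images per plate."""
    layout = PlateLayout(culture_id="c1", region="hippocampal")
    assert layout.sites_per_group == 27
    small = dataclasses.replace(noisy_scene, n_cells=2)
    images, truths = generate_plate(layout, small, drebrin_map, seed=0)
    assert len(images) == 6 * 27 == 162
    assert len(truths) == 162
    labels = {im.ids.group for im in images}
    assert labels == {"vehicle", "1e-09", "1e-08", "1e-07", "1e-06", "1e-05"}


def test_effect_model_vehicle_identity(noiseless_scene):
    effect = EffectModel({"1e-06": {"primary_soma": 1.5}})
    assert effect.spec_for(noiseless_scene, "vehicle") == noiseless_scene
    scaled = effect.spec_for(noiseless_scene, "1e-06")
    assert scaled.primary_soma == round(noiseless_scene.primary_soma * 1.5)
    with pytest.raises(ValueError):
        EffectModel({"vehicle": {"primary_soma": 2.0}})
    with pytest.raises(ValueError):
        EffectModel({"1e-06": {"primary_soma": -1.0}})


def test_planted_effect_scales_measured_soma(drebrin_map):
    """A 1.5x factor on soma marker intensity is recovered by the
    measurement pipeline on zero-noise sites."""
    from neurohcs.segmentation import detect_nuclei, dilate_labels
    from neurohcs.drebrin import gate_map2_positive, measure_soma_axon

    spec = small_scene(noisy=False)
    effect = EffectModel({"1e-06": {"primary_soma": 1.5}})

    def measured_soma(s, seed):
        img, truth = generate_site_image(s, drebrin_map, seed=seed)
        nuclei = detect_nuclei(img, 1500, min_area=10, max_area=500,
                               min_circularity=0.0)
        soma = dilate_labels(nuclei, s.soma_dilation_px)
        gate = gate_map2_positive(nuclei, soma, img, map2_threshold=800)
        m = measure_soma_axon(img, gate.soma)
        bg = truth.soma_roi_noiseless["primary_marker"] - sum(
            c.contributions["primary_marker"]["soma"]
            for c in truth.cells if c.cell_type == "neuron")
        return m.soma_drebrin - bg  # background-free planted soma signal

    base = measured_soma(effect.spec_for(spec, "vehicle"), seed=5)
    scaled = measured_soma(effect.spec_for(spec, "1e-06"), seed=5)
    assert scaled / base == pytest.approx(1.5, rel=1e-12)


def test_soma_factor_ordering_recovered_under_noise(drebrin_map):
    """Factors {0.5, 1, 2} on soma marker intensity order correctly in
    >= 95% of seeded measurements at moderate noise."""
    from neurohcs.segmentation import detect_nuclei, dilate_labels
    from neurohcs.drebrin import measure_soma_axon

    spec = small_scene(noisy=True)
    effect = EffectModel({"lo": {"primary_soma": 0.5},
                          "hi": {"primary_soma": 2.0}})

    def soma(label, seed):
        s = effect.spec_for(spec, label)
        img, _ = generate_site_image(s, drebrin_map, seed=seed)
        nuclei = detect_nuclei(img, 1500, min_area=10, max_area=500,
                               min_circularity=0.0)
        rois = dilate_labels(nuclei, s.soma_dilation_px)
        return measure_soma_axon(img, rois).soma_drebrin

    ordered = sum(soma("lo", s) < soma("mid", s) < soma("hi", s)
                  for s in range(20))
    assert ordered >= 19


# ---------------------------------------------------------------------------
# qPCR / plate-reader generators
# ---------------------------------------------------------------------------

def test_cq_table_no_fold_no_noise_constant():
    df = generate_cq_table(["vehicle", "1e-06"], fold_changes={}, noise_sd_cq=0.0)
    spread = df.groupby(["culture", "gene"])["cq"].nunique()
    assert (spread == 1).all()


def test_cq_fold_half_is_one_cycle_later():
    df = generate_cq_table(
        ["vehicle", "1e-06"], fold_changes={"Dbn1": {"1e-06": 0.5}},
        efficiencies={"Dbn1": 2.0}, noise_sd_cq=0.0, n_cultures=1)
    sub = df[df["gene"] == "Dbn1"].groupby("group")["cq"].mean()
    assert sub["1e-06"] - sub["vehicle"] == pytest.approx(1.0, abs=1e-12)


def test_cq_replicate_structure():
    df = generate_cq_table(["vehicle"], fold_changes={}, replicates=2,
                           n_cultures=2)
    counts = df.groupby(["culture", "group", "gene"])["replicate"].count()
    assert (counts == 2).all()
    with pytest.raises(ValueError):
        generate_cq_table(["vehicle"], fold_changes={"Dbn1": {"x": -1}})


def test_absorbance_exact_levels():
    df = generate_absorbance_table(
        ["vehicle", "1e-05"], {"vehicle": 1.0, "1e-05": 0.5},
        assay="ldh", noise_sd=0.0, blank_level=0.0)
    means = df.groupby("group")["absorbance"].mean()
    assert means["1e-05"] == pytest.approx(0.5 * means["vehicle"])
    assert (df["wavelength"] == 492).all()
    assert "triton_x" in set(df["group"])
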