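"""Reactivity index, calibration and the hierarchical rule cascade."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from hep2 import ChannelImage, FieldOfView, FieldSpec, render_field
from hep2.descriptors import MetaphaseSignal
from hep2.interpretation import (
    ReactivityIndex, CalibrationModel, PipelineConfig, FieldAggregate,
    UnevaluableSampleError,
    compute_ri, calibrate, classify_positivity, classify_localization,
    classify_nuclear_pattern, interpret_field, interpret_sample,
)


def agg(nuclear=10000.0, ring=500.0, bg=500.0, dots=0.0, dot_peak=0.0,
        blobs=0.0, blob_rel=1.0, cv=0.05, meta=None):
    meta = meta or MetaphaseSignal(indeterminate=False)
    return FieldAggregate(nuclear_median=nuclear, ring_median=ring,
                          background_median=bg, dot_count=dots,
                          dot_peak_mean=dot_peak, blob_count=blobs,
                          blob_rel_intensity=blob_rel, cv=cv, metaphase=meta)


# ---------------------------------------------------------------- RI

def test_blank_image_scores_zero():
    px = np.full((64, 64), 1000.0)
    fg = np.zeros((64, 64), bool)
    fg[20:40, 20:40] = True
    ri = compute_ri(ChannelImage(px, 16, "fitc"), fg)
    assert ri.value == 0.0
    assert ri.contrast_component == 0.0


def test_two_level_toy_image_hand_computed():
    """bg 0, half the mask at full range: every component known in closed form."""
    px = np.zeros((64, 64))
    fg = np.zeros((64, 64), bool)
    fg[:32, :32] = True
    px[:32, :16] = 65535.0
    ri = compute_ri(ChannelImage(px, 16, "fitc"), fg, titer_gamma=0.66)
    assert ri.intensity_component == pytest.approx(1.0)  # max = full range, gain 1
    # crest (top 1% of fg) sits at full range; background mean is 0
    assert ri.contrast_component == pytest.approx(1.0)
    assert ri.greyscale_richness == pytest.approx(2 / 65536)
    assert ri.value == pytest.approx(100 * 1 * 1 * 2 / 65536)


def test_ri_increases_with_rendered_intensity(rendered):
    lo = interpret_field(rendered("homogeneous", 0.4, seed=3)[0]).ri
    hi = interpret_field(rendered("homogeneous", 0.8, seed=3)[0]).ri
    assert hi.value > lo.value


def test_ri_monotone_in_intensity_for_each_pattern():
    levels = np.linspace(0.1, 1.0, 8)
    for pattern in ("homogeneous", "centromere", "cytoplasmic"):
        values = [interpret_field(render_field(
            FieldSpec(pattern=pattern, intensity_level=float(l), seed=5))[0]).ri.value
            for l in levels]
        rho = spearmanr(levels, values).statistic
        assert rho > 0.9, pattern


def test_ri_component_invariant_validation():
    with pytest.raises(ValueError):
        ReactivityIndex(1.0, 0.5, 0.5, 0.5)  # value != 100*product
    with pytest.raises(ValueError):
        ReactivityIndex(100 * 1.2 * 0.5 * 0.5, 1.2, 0.5, 0.5)


def test_fully_masked_image_rejected():
    px = np.full((16, 16), 100.0)
    with pytest.raises(ValueError):
        compute_ri(ChannelImage(px, 16, "fitc"), np.ones((16, 16), bool),
                   np.ones((16, 16), bool))


# ------------------------------------------------------- calibration

def test_calibration_percentile_and_ratio():
    rng = np.random.default_rng(0)
    values = rng.gamma(2.0, 0.1, size=200)
    cal = calibrate(values)
    assert cal.negative_threshold == pytest.approx(np.percentile(values, 99))
    assert cal.positive_threshold == pytest.approx(2.5 * cal.negative_threshold)
    assert cal.source_n == 200
    # held-out false positives bounded by percentile construction
    held = rng.gamma(2.0, 0.1, size=400)
    assert np.mean(held > cal.negative_threshold) <= 0.05


def test_calibration_shift_equivariance():
    rng = np.random.default_rng(4)
    values = rng.gamma(2.0, 0.1, size=200)
    base = calibrate(values)
    shifted = calibrate(values + 3.0)
    assert shifted.negative_threshold == pytest.approx(base.negative_threshold + 3.0)
    assert shifted.positive_threshold == pytest.approx(2.5 * shifted.negative_threshold)


def test_calibration_input_validation():
    with pytest.raises(ValueError):
        calibrate(np.ones(200))  # constant population
    with pytest.raises(ValueError):
        calibrate(np.arange(10))  # too few
    with pytest.warns(UserWarning):
        calibrate(np.random.default_rng(1).gamma(2, 0.1, 50))


def test_positivity_boundaries_go_to_higher_class():
    cal = CalibrationModel(1.0, 2.5, 200, "test")
    mk = lambda v: classify_positivity(v, cal)
    assert mk(0.0) == "negative"
    assert mk(0.999) == "negative"
    assert mk(1.0) == "weak_positive"
    assert mk(2.4999) == "weak_positive"
    assert mk(2.5) == "positive"


def test_positivity_is_a_step_function_of_ri():
    cal = CalibrationModel(1.0, 2.5, 200, "test")
    order = {"negative": 0, "weak_positive": 1, "positive": 2}
    values = np.linspace(0, 4, 60)
    classes = [order[classify_positivity(v, cal)] for v in values]
    assert classes == sorted(classes)


# ------------------------------------------------------- rules

def test_localization_rules():
    config = PipelineConfig()
    # ring clearly outshines nucleus -> cytoplasmic
    loc, _ = classify_localization(agg(nuclear=3000, ring=9000), config)
    assert loc == "cytoplasmic"
    # nuclear staining dominates
    loc, _ = classify_localization(agg(nuclear=9000, ring=600), config)
    assert loc == "nuclear"
    # only the metaphase plate stains
    meta = MetaphaseSignal(False, chromatin_positive=True, ratio=20.0)
    loc, _ = classify_localization(agg(nuclear=600, ring=550, bg=500, meta=meta), config)
    assert loc == "mitotic_chromatin"


def test_pattern_rule_cascade_order_and_boundaries():
    config = PipelineConfig()
    dotted = MetaphaseSignal(False, chromatin_dotted=True)
    plain = MetaphaseSignal(False)
    positive = MetaphaseSignal(False, chromatin_positive=True, ratio=1.2)

    # >30 dots with dotted metaphase -> centromere
    assert classify_nuclear_pattern(
        agg(dots=45, dot_peak=20000, nuclear=800, meta=dotted), config)[0] == "centromere"
    # exactly 30: centromere only with metaphase confirmation
    assert classify_nuclear_pattern(
        agg(dots=30, dot_peak=20000, nuclear=800, meta=dotted), config)[0] == "centromere"
    assert classify_nuclear_pattern(
        agg(dots=30, dot_peak=20000, nuclear=800, cv=0.9, meta=plain), config)[0] == "nuclear_dots"
    # few discrete dots on dark nucleoplasm -> nuclear dots
    assert classify_nuclear_pattern(
        agg(dots=6, dot_peak=20000, nuclear=800, cv=1.5, meta=plain), config)[0] == "nuclear_dots"
    # many dots without metaphase confirmation read as dense speckling
    assert classify_nuclear_pattern(
        agg(dots=60, dot_peak=20000, nuclear=8000, cv=0.6, meta=plain), config)[0] == "speckled"
    # bright blobs over weak diffuse nucleus -> nucleolar
    assert classify_nuclear_pattern(
        agg(blobs=3, blob_rel=5.0, nuclear=2000, cv=1.0, meta=plain), config)[0] == "nucleolar"
    # stained metaphase chromatin -> homogeneous even with speckle texture
    assert classify_nuclear_pattern(
        agg(cv=0.6, nuclear=9000, meta=positive), config)[0] == "homogeneous"
    # high CV, dark chromatin -> speckled
    assert classify_nuclear_pattern(
        agg(cv=0.6, nuclear=9000, meta=plain), config)[0] == "speckled"
    # low CV, dark chromatin -> homogeneous by default
    assert classify_nuclear_pattern(
        agg(cv=0.05, nuclear=9000, meta=plain), config)[0] == "homogeneous"


def test_texture_fallback_when_metaphase_indeterminate():
    config = PipelineConfig()
    indet = MetaphaseSignal(indeterminate=True)
    pat, trace = classify_nuclear_pattern(agg(cv=0.05, nuclear=9000, meta=indet), config)
    assert pat == "homogeneous"
    assert any("reduced confidence" in t for t in trace)
    pat, _ = classify_nuclear_pattern(agg(cv=0.6, nuclear=9000, meta=indet), config)
    assert pat == "speckled"


def test_rule_trace_logs_every_evaluated_rule():
    pat, trace = classify_nuclear_pattern(agg(cv=0.6, nuclear=9000,
                                              meta=MetaphaseSignal(False)))
    assert pat == "speckled"
    fired = [t for t in trace if t.endswith("True")]
    assert fired, trace
    assert len(trace) >= 4  # centromere, dots, nucleolar, homogeneous, speckled all logged


# ------------------------------------------------------- end-to-end

def test_rendered_localization_ground_truth(field_aggregates):
    assert classify_localization(field_aggregates["cytoplasmic"])[0] == "cytoplasmic"
    assert classify_localization(field_aggregates["homogeneous"])[0] == "nuclear"


def test_mixed_nuclear_plus_strong_cytoplasm_reads_cytoplasmic(rendered):
    """Cytoplasmic staining is emphasized over coincident nuclear staining."""
    speckled, _ = rendered("speckled_fine", 0.4, seed=19)
    cyto, _ = rendered("cytoplasmic", 1.0, seed=19)
    mixed_fitc = np.clip(speckled.fitc.pixels.astype(float)
                         + cyto.fitc.pixels.astype(float) - 500.0, 0, 65535)
    mixed = FieldOfView(dapi=speckled.dapi, fitc=ChannelImage(mixed_fitc, 16, "fitc"))
    fi = interpret_field(mixed)
    assert classify_localization(fi.aggregate)[0] == "cytoplasmic"


def test_documented_confusions_reproduced(field_aggregates):
    """Nuclear-membrane rim reads as speckled; Golgi reads as cytoplasmic."""
    loc, _ = classify_localization(field_aggregates["nuclear_membrane"])
    assert loc == "nuclear"
    assert classify_nuclear_pattern(field_aggregates["nuclear_membrane"])[0] == "speckled"
    assert classify_localization(field_aggregates["golgi"])[0] == "cytoplasmic"


def test_interpret_sample_negative_has_no_pattern(rendered, negative_calibration):
    fov, _ = rendered("negative", 0.02, seed=77)
    res = interpret_sample([fov], negative_calibration)
    assert res.positivity == "negative"
    assert res.localization == "none"
    assert res.pattern == "none"
    assert res.fields_used == 1


def test_interpret_sample_recovers_homogeneous(rendered, negative_calibration):
    fov, _ = rendered("homogeneous", 0.9, seed=31)
    res = interpret_sample([fov], negative_calibration)
    assert res.positivity == "positive"
    assert res.localization == "nuclear"
    assert res.pattern == "homogeneous"
    assert res.rule_trace
    assert res.ri.value > negative_calibration.positive_threshold


def test_interpret_sample_is_deterministic(rendered, negative_calibration):
    fov, _ = rendered("centromere", 0.8, seed=55)
    a = interpret_sample([fov], negative_calibration)
    b = interpret_sample([fov], negative_calibration)
    assert a == b


def test_unevaluable_sample_distinct_from_negative(negative_calibration):
    px = np.full((64, 64), 300.0)
    px[:48, :] = 65535.0  # saturated artifact over most tiles
    bad = FieldOfView(dapi=ChannelImage(px.copy(), 16, "dapi"),
                      fitc=ChannelImage(px.copy(), 16, "fitc"))
    with pytest.raises(UnevaluableSampleError):
        interpret_sample([bad], negative_calibration)
    with pytest.raises(ValueError):
        interpret_sample([], negative_calibration)
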