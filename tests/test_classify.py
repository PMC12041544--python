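import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

import canopymap as cm
from canopymap.classify import ThresholdTreeClassifier, propose_thresholds
from canopymap.types import GRASS, NONVEG, TREE

from oracles import classify_oracle


def make_stack(ndvi, ndwi, brightness, texture):
    shape = np.shape(ndvi)
    return cm.IndexStack(
        ndvi=np.asarray(ndvi, float),
        ndwi=np.asarray(ndwi, float),
        brightness=np.asarray(brightness, float),
        texture=np.asarray(texture, float),
        nodata_mask=np.zeros(shape, bool),
    )


def one_pixel(ndvi, ndwi, brightness=60_000.0, texture=10.0):
    return make_stack([[ndvi]], [[ndwi]], [[brightness]], [[texture]])


class TestStageOne:
    def test_water_like_pixel_is_nonvegetation(self, cfg2013):
        veg = cm.stage1_vegetation_mask(one_pixel(ndvi=-0.1, ndwi=0.1), cfg2013)
        assert not veg.values[0, 0]

    def test_green_pixel_is_vegetation(self, cfg2013):
        veg = cm.stage1_vegetation_mask(one_pixel(ndvi=0.6, ndwi=-0.2), cfg2013)
        assert veg.values[0, 0]

    def test_boundary_equality_falls_through_to_vegetation(self):
        # thresholds are strict: NDWI > 0 and NDVI < 0 are both unmet at 0
        cfg = cm.load_year_config("2021")
        veg = cm.stage1_vegetation_mask(one_pixel(ndvi=0.0, ndwi=0.0), cfg)
        assert veg.values[0, 0]


class TestStageTwo:
    def test_dark_vegetated_pixel_is_tree(self, cfg2013):
        idx = one_pixel(ndvi=0.5, ndwi=-0.3, brightness=40_000, texture=0.0)
        veg = cm.stage1_vegetation_mask(idx, cfg2013)
        assert cm.stage2_classify(idx, veg, cfg2013).labels[0, 0] == TREE

    def test_brightness_overturns_stage1_vegetation_call(self, cfg2013):
        idx = one_pixel(ndvi=0.5, ndwi=-0.3, brightness=200_000, texture=0.0)
        veg = cm.stage1_vegetation_mask(idx, cfg2013)
        assert veg.values[0, 0]  # Stage I says vegetation
        assert cm.stage2_classify(idx, veg, cfg2013).labels[0, 0] == NONVEG

    def test_bright_smooth_vegetated_pixel_is_grassland(self, cfg2013):
        idx = one_pixel(ndvi=0.5, ndwi=-0.3, brightness=100_000, texture=10.0)
        veg = cm.stage1_vegetation_mask(idx, cfg2013)
        assert cm.stage2_classify(idx, veg, cfg2013).labels[0, 0] == GRASS

    def test_stage1_nonvegetation_never_overturned(self, cfg2013):
        # Node 2's tree conditions must not rescue a Stage I non-veg pixel
        idx = one_pixel(ndvi=-0.2, ndwi=0.3, brightness=10_000, texture=100.0)
        veg = cm.stage1_vegetation_mask(idx, cfg2013)
        assert cm.stage2_classify(idx, veg, cfg2013).labels[0, 0] == NONVEG


@pytest.mark.parametrize("year", ["2013", "2015", "2017", "2019", "2021"])
def test_rules_match_perpixel_oracle_every_year(year):
    """Vectorized Stage I+II agrees with naive per-pixel rule evaluation."""
    cfg = cm.load_year_config(year)
    rng = np.random.default_rng(17)
    idx = make_stack(
        rng.uniform(-1, 1, (15, 15)),
        rng.uniform(-1, 1, (15, 15)),
        rng.uniform(0, 260_100, (15, 15)),
        rng.uniform(0, 300, (15, 15)),
    )
    veg = cm.stage1_vegetation_mask(idx, cfg)
    got = cm.stage2_classify(idx, veg, cfg).labels
    want = classify_oracle(idx.ndvi, idx.ndwi, idx.brightness, idx.texture, cfg)
    np.testing.assert_array_equal(got, want)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_partition_exhaustive_and_exclusive(cfg2013, seed):
    rng = np.random.default_rng(seed)
    idx = make_stack(
        rng.uniform(-1, 1, (10, 10)),
        rng.uniform(-1, 1, (10, 10)),
        rng.uniform(0, 260_100, (10, 10)),
        rng.uniform(0, 300, (10, 10)),
    )
    veg = cm.stage1_vegetation_mask(idx, cfg2013)
    labels = cm.stage2_classify(idx, veg, cfg2013).labels
    assert np.isin(labels, (GRASS, NONVEG, TREE)).all()
    # Node-1 containment: Stage I non-vegetation stays non-vegetation
    assert (labels[~veg.values] == NONVEG).all()


def test_threshold_monotonicity(cfg2013):
    rng = np.random.default_rng(5)
    idx = make_stack(
        rng.uniform(-1, 1, (20, 20)),
        rng.uniform(-1, 1, (20, 20)),
        rng.uniform(0, 260_100, (20, 20)),
        rng.uniform(0, 300, (20, 20)),
    )

    def counts(cfg):
        veg = cm.stage1_vegetation_mask(idx, cfg)
        lab = cm.stage2_classify(idx, veg, cfg).labels
        return (lab == NONVEG).sum(), (lab == TREE).sum()

    nv_lo, _ = counts(cfg2013.replace(brightness_nonveg_min=100_000))
    nv_hi, _ = counts(cfg2013.replace(brightness_nonveg_min=200_000))
    assert nv_hi <= nv_lo  # raising the cutoff never adds non-vegetation
    _, tr_hi = counts(cfg2013.replace(brightness_tree_max=80_000))
    _, tr_lo = counts(cfg2013.replace(brightness_tree_max=30_000))
    assert tr_lo <= tr_hi  # lowering the cutoff never adds trees


class TestProposeThresholds:
    def test_two_point_midpoint(self):
        table = pd.DataFrame({"ndvi": [0.0, 1.0]})
        assert propose_thresholds(table, ["ndvi"])["ndvi"] == pytest.approx(0.5)

    def test_cut_falls_in_the_gap_between_clusters(self):
        rng = np.random.default_rng(123)
        vals = np.concatenate([
            rng.normal(0.6, 0.05, 200), rng.normal(-0.2, 0.05, 200)
        ])
        cut = propose_thresholds(pd.DataFrame({"ndvi": vals}), ["ndvi"])["ndvi"]
        assert 0.0 < cut < 0.4

    def test_degenerate_samples_raise_naming_the_feature(self):
        table = pd.DataFrame({"texture": [5.0] * 10})
        with pytest.raises(ValueError, match="texture"):
            propose_thresholds(table, ["texture"])


class TestEstimator:
    def test_predict_matches_raster_path(self, cfg2013):
        rng = np.random.default_rng(2)
        X = np.column_stack([
            rng.uniform(-1, 1, 500),
            rng.uniform(-1, 1, 500),
            rng.uniform(0, 260_100, 500),
            rng.uniform(0, 300, 500),
        ])
        est = ThresholdTreeClassifier.from_config(cfg2013)
        got = est.predict(X)
        idx = make_stack(
            X[:, 0].reshape(20, 25), X[:, 1].reshape(20, 25),
            X[:, 2].reshape(20, 25), X[:, 3].reshape(20, 25),
        )
        veg = cm.stage1_vegetation_mask(idx, cfg2013)
        want = cm.stage2_classify(idx, veg, cfg2013).labels.ravel()
        np.testing.assert_array_equal(got, want)

    def test_sklearn_protocol(self):
        est = ThresholdTreeClassifier(ndvi_max=-0.05)
        params = est.get_params()
        assert params["ndvi_max"] == -0.05
        cloned = clone(est)
        cloned.set_params(texture_tree_min=60.0)
        assert cloned.get_params()["texture_tree_min"] == 60.0
        fitted = est.fit()
        assert list(fitted.classes_) == [GRASS, NONVEG, TREE]

    def test_fit_proposes_unset_thresholds_from_samples(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({
            "ndvi": np.r_[rng.normal(0.6, 0.05, 100), rng.normal(-0.2, 0.05, 100)],
            "ndwi": rng.uniform(-1, 1, 200),
            "brightness": np.r_[rng.normal(30_000, 2_000, 100),
                                rng.normal(120_000, 5_000, 100)],
            "texture": rng.uniform(0, 10, 200),
        })
        est = ThresholdTreeClassifier(ndvi_max=None, brightness_nonveg_min=None)
        est.fit(X)
        assert 0.0 < est.thresholds_["ndvi_max"] < 0.4
        assert 40_000 < est.thresholds_["brightness_nonveg_min"] < 110_000
        # explicitly-set thresholds are untouched
        assert est.thresholds_["texture_tree_min"] == 50.0

    def test_unset_thresholds_without_samples_raise(self):
        with pytest.raises(ValueError, match="unset"):
            ThresholdTreeClassifier(ndwi_min=None).fit()


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="brightness_tree_max"):
        cm.ThresholdConfig(brightness_tree_max=200_000, brightness_nonveg_min=150_000)
    with pytest.raises(ValueError, match="sieve_min_pixels"):
        cm.ThresholdConfig(sieve_min_pixels=0)


def test_packaged_configs_cover_all_survey_years():
    years = cm.available_years()
    assert years == ["2013", "2015", "2017", "2019", "2021"]
    for year in years:
        cfg = cm.load_year_config(year)
        assert cfg.sieve_min_pixels == 9  # fixed ground area at both resolutions
        assert cfg.texture_tree_min == 50
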