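import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reedmap.classify import (
    cohens_kappa,
    fit_reed_model,
    kappa_threshold,
    oob_learning_curve,
    predict_probability,
    sample_training_points,
)
from reedmap.core import FeatureStack
from reedmap.features import build_feature_stack
from reedmap.preprocess import seasonal_median_composite
from reedmap.vector import TruthPolygon, mask_to_polygon

pytestmark = pytest.mark.filterwarnings(
    "ignore:Some inputs do not have OOB scores")


def square_polygon(r0, c0, size, label):
    mask = np.zeros((max(r0 + size, 40), max(c0 + size, 40)), dtype=bool)
    mask[r0:r0 + size, c0:c0 + size] = True
    return TruthPolygon(mask_to_polygon(mask), label)


def toy_stack(shape=(40, 40), seed=0, n_layers=4):
    rng = np.random.default_rng(seed)
    layers = rng.normal(0, 1, (n_layers, *shape))
    return FeatureStack(layers, [f"f{i}" for i in range(n_layers)], "two_season")


@pytest.fixture(scope="module")
def clean_stack_and_polygons(clean_dataset):
    comps = seasonal_median_composite(clean_dataset.passes,
                                      clean_dataset.season_windows)
    stack = build_feature_stack(comps, "two_season")
    polys = [TruthPolygon(p.geometry,
                          "reedbed" if p.label == "reedbed" else "non-reedbed")
             for p in clean_dataset.truth_polygons]
    return stack, polys


@pytest.fixture(scope="module")
def clean_sample(clean_stack_and_polygons):
    stack, polys = clean_stack_and_polygons
    return sample_training_points(polys, stack, n_per_polygon=80, seed=0)


class TestSampleTrainingPoints:
    def test_single_pixel_polygon_keeps_one_point(self):
        stack = toy_stack()
        poly = square_polygon(5, 5, 1, "reedbed")
        big = square_polygon(20, 20, 5, "non-reedbed")
        sample = sample_training_points([poly, big], stack, 100, seed=1)
        assert (sample.points["polygon_id"] == 0).sum() == 1

    def test_retained_count_bounded_by_pixels(self):
        stack = toy_stack()
        polys = [square_polygon(0, 0, 5, "reedbed"),
                 square_polygon(10, 10, 20, "non-reedbed")]
        sample = sample_training_points(polys, stack, 100, seed=2)
        counts = sample.per_polygon_counts
        assert counts[0] <= 25
        assert counts[1] <= 100

    def test_deterministic_given_seed(self):
        stack = toy_stack()
        polys = [square_polygon(0, 0, 8, "reedbed"),
                 square_polygon(20, 20, 8, "non-reedbed")]
        a = sample_training_points(polys, stack, 50, seed=3)
        b = sample_training_points(polys, stack, 50, seed=3)
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_polygon_outside_raster_rejected(self):
        stack = toy_stack(shape=(20, 20))
        poly = square_polygon(30, 30, 5, "reedbed")
        with pytest.raises(ValueError, match="outside"):
            sample_training_points([poly], stack, 10, seed=0)

    def test_invalid_feature_pixels_dropped(self):
        stack = toy_stack()
        stack.layers[0, 0:10, 0:10] = np.nan
        polys = [square_polygon(0, 0, 10, "reedbed"),
                 square_polygon(20, 20, 10, "non-reedbed")]
        sample = sample_training_points(polys, stack, 100, seed=1)
        assert (sample.points["polygon_id"] == 0).sum() == 0


class TestFitReedModel:
    def test_separable_classes_low_oob_error(self, clean_sample):
        model = fit_reed_model(clean_sample, n_trees=100, seeds=(0, 1))
        for f in ("RF1", "RF2"):
            assert model.oob_by_class[f]["reedbed"] < 0.05
            assert model.oob_by_class[f]["non-reedbed"] < 0.05

    def test_importance_vector_matches_feature_count(self, clean_sample):
        model = fit_reed_model(clean_sample, n_trees=50, seeds=(0, 1))
        assert model.variable_importance.shape == (16, 2)

    def test_single_class_rejected(self, clean_sample):
        sub = clean_sample.points[clean_sample.points["label"] == "non-reedbed"]
        from reedmap.classify import TrainingSample
        with pytest.raises(ValueError):
            fit_reed_model(TrainingSample(sub, clean_sample.feature_names))

    def test_balancing_evens_per_class_oob_errors(self):
        """10:1 imbalance: balanced second forest has more similar class errors."""
        rng = np.random.default_rng(0)
        n1, n0 = 60, 600
        X = np.vstack([rng.normal(1.2, 1.0, (n1, 4)), rng.normal(0, 1.0, (n0, 4))])
        y = np.array(["reedbed"] * n1 + ["non-reedbed"] * n0)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
        df["row"] = 0; df["col"] = 0; df["label"] = y; df["polygon_id"] = 0
        from reedmap.classify import TrainingSample
        sample = TrainingSample(df, [f"f{i}" for i in range(4)])
        gaps = {}
        for balanced in (False, True):
            diffs = []
            for s in range(3):
                m = fit_reed_model(sample, balanced=balanced, n_trees=100,
                                   vars_per_split=2, seeds=(s, s + 50))
                oob = m.oob_by_class["RF2"]
                # commission gap between the classes of the second forest
                diffs.append(abs(oob["reedbed"] - oob["non-reedbed"]))
            gaps[balanced] = np.mean(diffs)
        assert gaps[True] < gaps[False]


class TestPredictProbability:
    def test_identical_forests_idempotent_min(self, clean_sample,
                                              clean_stack_and_polygons):
        stack, _ = clean_stack_and_polygons
        model = fit_reed_model(clean_sample, n_trees=50, seeds=(0, 0),
                               balanced=False)
        fused = predict_probability(model, stack)
        single = predict_probability(model, stack, fusion="single")
        np.testing.assert_allclose(fused.p[fused.valid], single.p[single.valid])

    def test_min_dominated_by_each_forest(self, clean_sample,
                                          clean_stack_and_polygons):
        stack, _ = clean_stack_and_polygons
        model = fit_reed_model(clean_sample, n_trees=50, seeds=(0, 1))
        fused = predict_probability(model, stack)
        v = fused.valid
        X = stack.matrix(v)
        p1 = model.reed_proba(X, model.rf1)
        p2 = model.reed_proba(X, model.rf2)
        assert (fused.p[v] <= p1 + 1e-12).all()
        assert (fused.p[v] <= p2 + 1e-12).all()

    def test_fused_false_positive_area_not_larger(self, clean_dataset,
                                                  clean_sample,
                                                  clean_stack_and_polygons):
        """Min fusion shrinks false-positive area vs either single forest."""
        stack, _ = clean_stack_and_polygons
        model = fit_reed_model(clean_sample, n_trees=100, seeds=(0, 1))
        v = stack.valid
        truth = clean_dataset.reed_truth
        thr = 0.5
        X = stack.matrix(v)
        p1 = model.reed_proba(X, model.rf1)
        p2 = model.reed_proba(X, model.rf2)
        fused = np.minimum(p1, p2)
        t = truth[v]
        fp_fused = ((fused > thr) & ~t).sum()
        assert fp_fused <= ((p1 > thr) & ~t).sum()
        assert fp_fused <= ((p2 > thr) & ~t).sum()

    def test_feature_name_mismatch_rejected(self, clean_sample):
        model = fit_reed_model(clean_sample, n_trees=20, seeds=(0, 1))
        bad = toy_stack(n_layers=16)
        with pytest.raises(ValueError, match="feature names"):
            predict_probability(model, bad)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(10, 0, 0, 20) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        assert cohens_kappa(25, 25, 25, 25) == pytest.approx(0.0)

    def test_validation_matrix_value(self):
        # hand evaluation of the formula on (21, 297, 18, 588)
        assert cohens_kappa(21, 297, 18, 588) == pytest.approx(0.0459, abs=5e-5)

    def test_degenerate_single_cell_matrix(self):
        assert cohens_kappa(10, 0, 0, 0) == 0.0

    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_swap_invariance(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        assert cohens_kappa(tp, fp, fn, tn) == pytest.approx(
            cohens_kappa(tn, fn, fp, tp), abs=1e-12)


def brute_force_kappa_threshold(probs, y, step=0.001):
    grid = np.arange(0.0, 1.0 + step, step)
    best_t, best_k = None, -np.inf
    for t in grid:
        pred = probs > t
        tp = int((pred & y).sum()); fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum()); tn = int((~pred & ~y).sum())
        k = cohens_kappa(tp, fp, fn, tn)
        if k > best_k + 1e-12:
            best_k, best_t = k, t
    return best_t, best_k


class TestKappaThreshold:
    def test_separated_probs_midpoint(self):
        probs = np.array([0.2, 0.4, 0.6, 0.9])
        y = np.array([False, False, True, True])
        assert kappa_threshold(probs, y) == pytest.approx(0.5)

    def test_inverted_scores_nonpositive_kappa(self):
        probs = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([False, False, True, True])
        t = kappa_threshold(probs, y)
        pred = probs > t
        tp = int((pred & y).sum()); fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum()); tn = int((~pred & ~y).sum())
        assert cohens_kappa(tp, fp, fn, tn) <= 0.0 + 1e-12

    def test_identical_probs_rejected(self):
        with pytest.raises(ValueError):
            kappa_threshold(np.full(10, 0.5), np.arange(10) % 2 == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        y = rng.random(n) < 0.3
        probs = np.clip(rng.normal(0.3 + 0.3 * y, 0.2), 0, 1)
        t = kappa_threshold(probs, y)
        bf_t, bf_k = brute_force_kappa_threshold(probs, y)
        pred = probs > t
        tp = int((pred & y).sum()); fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum()); tn = int((~pred & ~y).sum())
        assert cohens_kappa(tp, fp, fn, tn) >= bf_k - 1e-9
        assert abs(t - bf_t) <= 0.001 + max(
            np.diff(np.unique(probs)).max() / 2, 0.001)


class TestLearningCurve:
    def test_full_subset_matches_direct_fit(self, clean_sample):
        curve = oob_learning_curve(clean_sample, n_trees=50)
        model = fit_reed_model(clean_sample, n_trees=50)
        last = curve.iloc[-1]
        expect = np.nanmean([model.oob_by_class[f]["reedbed"]
                             for f in ("RF1", "RF2")])
        assert last["reed_commission_oob"] == pytest.approx(expect, nan_ok=True)

    def test_one_row_per_cumulative_subset(self, clean_sample):
        n_reed = clean_sample.points.loc[
            clean_sample.points["label"] == "reedbed", "polygon_id"].nunique()
        curve = oob_learning_curve(clean_sample, n_trees=20)
        assert len(curve) == n_reed

    def test_homogeneous_signal_commission_declines(self, clean_sample):
        """With a homogeneous reed signal the reed commission error should
        not increase (up to noise) as reed polygons accumulate."""
        curves = []
        for s in range(5):
            c = oob_learning_curve(clean_sample, n_trees=50, seeds=(s, s + 10))
            curves.append(c["reed_commission_oob"].to_numpy())
        med = np.nanmedian(np.stack(curves), axis=0)
        med = med[~np.isnan(med)]
        assert med[-1] <= med[0] + 0.05
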