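import itertools

import numpy as np
import pandas as pd
import pytest

from reedmap.core import HectareCoverMap
from reedmap.validate import (
    ConfusionMetrics,
    ValidationDesign,
    auc,
    collect_validation_records,
    confusion_from_records,
    corrected_extent,
    cover_regression,
    fp_landcover_chisq,
    sample_cells,
    stratify_hectares,
    stratum_of,
)

# printed 10 m confusion counts of the published national map (both variants)
HPC_10M = dict(tp=21, fp=297, fn=18, tn=588)
GEE_10M = dict(tp=10, fp=17, fn=29, tn=868)


class TestStratification:
    def test_stratum_boundaries(self):
        assert stratum_of(0.0) == "p=0"
        assert stratum_of(0.5) == "0.33<p<=0.66"
        assert stratum_of(0.33) == "0<p<=0.33"
        assert stratum_of(0.66) == "0.33<p<=0.66"
        assert stratum_of(1.0) == "0.66<p<=1"

    def _cover(self, seed=0, shape=(20, 20)):
        rng = np.random.default_rng(seed)
        grid = rng.uniform(0, 1, shape)
        grid[rng.random(shape) < 0.5] = 0.0
        return HectareCoverMap(grid)

    def test_small_stratum_fully_sampled(self):
        grid = np.zeros((10, 10))
        grid[:2, :4] = 0.9  # 8 hectares in the top stratum
        sample = stratify_hectares(HectareCoverMap(grid), ValidationDesign(seed=1))
        top = sample[sample["stratum"] == "0.66<p<=1"]
        assert len(top) == 8

    def test_samples_capped_at_design_size(self):
        sample = stratify_hectares(self._cover(), ValidationDesign(seed=2))
        assert sample.groupby("stratum").size().max() <= 10

    def test_deterministic_given_seed(self):
        c = self._cover(3)
        a = stratify_hectares(c, ValidationDesign(seed=5))
        b = stratify_hectares(c, ValidationDesign(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_sample_confined_to_richest_quadrant(self):
        grid = np.zeros((20, 20))
        grid[10:, 10:] = 0.5  # all non-zero cover in the SE quadrant
        sample = stratify_hectares(HectareCoverMap(grid), ValidationDesign(seed=0))
        nz = sample[sample["predicted_cover"] > 0]
        assert (nz["hectare_row"] >= 10).all() and (nz["hectare_col"] >= 10).all()

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError):
            stratify_hectares(HectareCoverMap(np.full((5, 5), np.nan)),
                              ValidationDesign())


class TestSampleCells:
    def test_six_distinct_cells_when_possible(self):
        rng = np.random.default_rng(0)
        presence = np.zeros((10, 10), dtype=bool)
        presence[:5] = True
        valid = np.ones((10, 10), dtype=bool)
        cells = sample_cells(presence, valid, (0, 0), ValidationDesign(), rng)
        assert len(cells) == 6
        assert not cells.duplicated(["cell_row", "cell_col"]).any()
        assert cells["cell_pred"].sum() == 3

    def test_degenerate_hectare_records_shortfall(self):
        rng = np.random.default_rng(1)
        presence = np.ones((10, 10), dtype=bool)
        valid = np.ones((10, 10), dtype=bool)
        cells = sample_cells(presence, valid, (0, 0), ValidationDesign(), rng)
        assert len(cells) == 3  # no predicted-absence cells exist
        assert (cells["cell_pred"] == 1).all()

    def test_seeded_determinism(self):
        presence = np.zeros((10, 10), dtype=bool)
        presence[::2] = True
        valid = np.ones((10, 10), dtype=bool)
        a = sample_cells(presence, valid, (0, 0), ValidationDesign(),
                         np.random.default_rng(7))
        b = sample_cells(presence, valid, (0, 0), ValidationDesign(),
                         np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)


class TestConfusionMetrics:
    def test_hpc_10m_rates(self):
        m = ConfusionMetrics(**HPC_10M)
        assert m.commission_reed == pytest.approx(0.934, abs=5e-4)
        assert m.omission_reed == pytest.approx(0.4615, abs=5e-5)
        assert m.predicted_prevalence == pytest.approx(0.3442, abs=5e-5)
        assert m.true_prevalence == pytest.approx(0.0422, abs=5e-5)
        assert m.commission_nonreed == pytest.approx(0.030, abs=5e-4)

    def test_gee_10m_rates(self):
        m = ConfusionMetrics(**GEE_10M)
        assert m.commission_reed == pytest.approx(0.630, abs=5e-4)
        assert m.omission_reed == pytest.approx(0.744, abs=5e-4)

    def test_all_correct_records(self):
        records = pd.DataFrame({
            "hectare_id": ["a"] * 3 + ["b"] * 3,
            "predicted_cover": [0.5] * 3 + [0.0] * 3,
            "observed_cover": [0.5] * 3 + [0.0] * 3,
            "cell_pred": [1, 1, 0, 0, 0, 1],
            "cell_obs": [1, 1, 0, 0, 0, 1],
        })
        m = confusion_from_records(records, "tenm")
        assert m.commission_reed == 0 and m.omission_reed == 0 and m.overall == 1

    def test_hectare_scale_presence_threshold(self):
        records = pd.DataFrame({
            "hectare_id": ["a", "b", "c"],
            "predicted_cover": [0.4, 0.0, 0.2],
            "observed_cover": [0.0, 0.3, 0.1],
            "cell_pred": [1, 0, 1],
            "cell_obs": [0, 1, 1],
        })
        m = confusion_from_records(records, "hectare")
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 1, 0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_records(pd.DataFrame(), "tenm")


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.7, 0.6, 0.2], [1, 1, 0, 0]) == 1.0

    def test_four_pair_brute_force(self):
        assert auc([0.7, 0.3, 0.5, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        y = rng.random(n) < 0.3
        if y.all() or not y.any():
            y[0] = ~y[0]
        s = np.round(rng.normal(0.4 + 0.2 * y, 0.2), 2)  # rounded: forces ties
        pos, neg = s[y], s[~y]
        wins = sum((p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg))
        oracle = wins / (len(pos) * len(neg))
        assert auc(s, y) == pytest.approx(oracle, abs=1e-12)


class TestCoverRegression:
    def test_exact_agreement_r2_one(self):
        x = np.array([0.1, 0.4, 0.7, 0.9])
        assert cover_regression(x, x)[2] == pytest.approx(1.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            cover_regression([0.1, 0.5, 0.9], [0.3, 0.3, 0.3])

    def test_toy_set_r2(self):
        # frozen from an independent OLS computation on this 4-point set
        _, _, r2 = cover_regression([0, 0.2, 0.4, 1.0], [0, 0.1, 0.5, 0.8])
        assert r2 == pytest.approx(0.9216, abs=1e-4)


class TestFpLandcoverChisq:
    def test_proportional_fp_zero_statistic(self):
        x2, df, p = fp_landcover_chisq([30, 70], [0.3, 0.7])
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_group_direct_formula(self):
        x2, df, _ = fp_landcover_chisq([75, 25], [0.5, 0.5])
        assert x2 == pytest.approx(25.0)
        assert df == 1

    def test_df_is_groups_minus_one(self):
        _, df, _ = fp_landcover_chisq([5, 5, 5, 5], [0.25] * 4)
        assert df == 3

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            fp_landcover_chisq([5, 5], [1.0, 0.0])

    def test_agrees_with_scipy(self):
        from scipy.stats import chisquare
        obs = np.array([40.0, 25.0, 35.0])
        comp = np.array([0.5, 0.2, 0.3])
        x2, df, p = fp_landcover_chisq(obs, comp)
        ref = chisquare(obs, comp * obs.sum())
        assert x2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestCorrectedExtent:
    def test_symmetric_point_same_under_both_variants(self):
        assert corrected_extent(100, 0.5, 0.5, "standard") == pytest.approx(100.0)
        assert corrected_extent(100, 0.5, 0.5, "as_printed") == pytest.approx(100.0)

    def test_published_inputs_standard(self):
        out = corrected_extent(54273, 297 / 318, 18 / 39, "standard")
        assert out == pytest.approx(6656.1, abs=0.5)

    def test_published_inputs_as_printed(self):
        # reproduces the printed national estimate (7,765 ha) to rounding
        out = corrected_extent(54273, 297 / 318, 18 / 39, "as_printed")
        assert out == pytest.approx(7765.5, abs=1.0)

    def test_no_error_returns_prediction(self):
        assert corrected_extent(500, 0.0, 0.0, "standard") == pytest.approx(500.0)

    def test_zero_omission_standard_gives_tp_area(self):
        assert corrected_extent(200, 0.25, 0.0, "standard") == pytest.approx(150.0)

    def test_monotone_in_errors(self):
        base = corrected_extent(100, 0.3, 0.4, "standard")
        assert corrected_extent(100, 0.4, 0.4, "standard") < base
        assert corrected_extent(100, 0.3, 0.5, "standard") > base

    def test_degenerate_omission_rejected(self):
        with pytest.raises(ValueError):
            corrected_extent(100, 0.5, 0.0, "as_printed")
        with pytest.raises(ValueError):
            corrected_extent(100, 0.5, 1.0, "standard")


class TestDesignBasedEstimation:
    def test_sampled_records_track_exhaustive_confusion(self):
        """Stratified per-cell sampling converges on the map's true 10 m
        commission/omission rates over seeds."""
        rng = np.random.default_rng(0)
        shape = (200, 200)
        truth = rng.random(shape) < 0.25
        # imperfect map: flip 15% of pixels
        presence = truth ^ (rng.random(shape) < 0.15)
        valid = np.ones(shape, dtype=bool)
        from reedmap.postprocess import aggregate_to_hectare
        cover = aggregate_to_hectare(presence, valid)
        exhaustive = ConfusionMetrics(
            tp=int((presence & truth).sum()), fp=int((presence & ~truth).sum()),
            fn=int((~presence & truth).sum()), tn=int((~presence & ~truth).sum()))
        comms, omms = [], []
        for seed in range(8):
            rec = collect_validation_records(
                cover, presence, valid, truth, ValidationDesign(seed=seed))
            m = confusion_from_records(rec, "tenm")
            comms.append(m.commission_reed)
            omms.append(m.omission_reed)
        assert np.mean(comms) == pytest.approx(exhaustive.commission_reed, abs=0.08)
        assert np.mean(omms) == pytest.approx(exhaustive.omission_reed, abs=0.10)

    def test_observed_cover_quantised_to_tenths(self):
        rng = np.random.default_rng(1)
        shape = (40, 40)
        truth = rng.random(shape) < 0.3
        presence = truth.copy()
        valid = np.ones(shape, dtype=bool)
        from reedmap.postprocess import aggregate_to_hectare
        cover = aggregate_to_hectare(presence, valid)
        rec = collect_validation_records(cover, presence, valid, truth,
                                         ValidationDesign(seed=0))
        obs = rec["observed_cover"].to_numpy()
        np.testing.assert_allclose(np.round(obs * 10), obs * 10)
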