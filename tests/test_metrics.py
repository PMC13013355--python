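import numpy as np
import pytest

import _oracles
from lesioneval import (
    LabelVolume,
    bland_altman,
    detection_stats,
    dice,
    extract_components,
    fnv,
    fpv,
    match_lesions,
    taxonomy_tally,
    tmtv,
)
from lesioneval.benchmarks import detection_fixture, m_fp_lesion_fixture
from lesioneval.lesion_analysis import GROUND_TRUTH, Lesion, MatchResult
from lesioneval.metrics import round_pct


class TestDice:
    def test_identical_masks(self):
        a = np.ones((3, 3, 3))
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice(a, b) == 0.0

    def test_closed_form_half_overlap(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, :2, :] = 1  # 8 voxels
        b[0, 1:3, :] = 1  # 8 voxels, overlap 4
        assert dice(a, b) == 0.5

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert dice(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))) == 1.0

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a, b = _oracles.random_mask_pair(rng, max_side=12)
            assert dice(a, b) == pytest.approx(_oracles.dice_loop(a, b))


def _match_setup(gt_arr, pred_arr, spacing=(2.0, 2.0, 2.0)):
    gt_vol = LabelVolume(gt_arr, spacing)
    pred_vol = LabelVolume(pred_arr, spacing)
    gt = extract_components(gt_vol, source=GROUND_TRUTH)
    pred = extract_components(pred_vol)
    return gt_vol, pred_vol, gt, pred, match_lesions(gt, pred)


class TestVolumes:
    def test_perfect_prediction_zero_fnv_fpv(self):
        arr = np.zeros((5, 5, 5), dtype=int)
        arr[1:3, 1:3, 1] = 1
        _, _, gt, pred, m = _match_setup(arr, arr)
        assert fnv(gt, m) == 0.0 and fpv(pred, m) == 0.0

    def test_empty_prediction_fnv_is_tmtv(self):
        arr = np.zeros((5, 5, 5), dtype=int)
        arr[1:4, 1, 1] = 1
        _, _, gt, pred, m = _match_setup(arr, np.zeros_like(arr))
        assert fnv(gt, m) == pytest.approx(tmtv(gt))
        assert fpv(pred, m) == 0.0

    def test_missed_five_voxel_lesion_at_2mm(self):
        """5 voxels x 8 mm3 = 40 mm3 = 0.04 mL of false-negative volume."""
        gt_arr = np.zeros((8, 8, 8), dtype=int)
        gt_arr[1:6, 1, 1] = 1
        _, _, gt, pred, m = _match_setup(gt_arr, np.zeros_like(gt_arr))
        assert fnv(gt, m) == pytest.approx(0.04)

    def test_tmtv_sums_lesion_volumes(self):
        lesions = [
            Lesion(1, "ground_truth", 10, 1.0),
            Lesion(2, "ground_truth", 25, 2.5),
        ]
        assert tmtv(lesions) == pytest.approx(3.5)
        assert tmtv([]) == 0.0

    def test_fnv_fpv_match_flood_fill_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            a, b = _oracles.random_mask_pair(rng, max_side=12)
            _, _, gt, pred, m = _match_setup(
                a.astype(int), b.astype(int), spacing=(1.0, 1.0, 1.0)
            )
            o_fnv, o_fpv = _oracles.fnv_fpv_loop(a, b, voxel_ml=0.001)
            assert fnv(gt, m) == pytest.approx(o_fnv)
            assert fpv(pred, m) == pytest.approx(o_fpv)

    def test_volume_conservation(self):
        """FNV + detected gt volume = TMTV_gt; FPV + matched pred = TMTV_pred."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            a, b = _oracles.random_mask_pair(rng, max_side=12)
            _, _, gt, pred, m = _match_setup(a.astype(int), b.astype(int))
            detected = sum(
                l.volume_ml for l in gt if l.lesion_id in m.detected_gt_ids
            )
            matched = sum(
                l.volume_ml for l in pred if l.lesion_id in m.matched_pred_ids
            )
            assert fnv(gt, m) + detected == pytest.approx(tmtv(gt))
            assert fpv(pred, m) + matched == pytest.approx(tmtv(pred))


class TestBlandAltman:
    def test_equal_pairs_zero_bias_zero_loa(self):
        res = bland_altman([(1.0, 1.0), (2.5, 2.5), (7.0, 7.0)])
        assert res.bias_ml == 0.0
        assert res.loa_low_ml == 0.0 and res.loa_high_ml == 0.0

    def test_symmetric_differences(self):
        """Differences {+2, -2}: sample SD 2.828, LoA ±5.54."""
        res = bland_altman([(0.0, 2.0), (0.0, -2.0)])
        assert res.bias_ml == pytest.approx(0.0)
        assert res.loa_high_ml == pytest.approx(1.96 * np.sqrt(8.0), abs=1e-9)
        assert res.loa_high_ml == pytest.approx(5.54, abs=0.01)

    def test_translation_shifts_bias_only(self):
        pairs = [(1.0, 2.0), (3.0, 2.5), (5.0, 7.0)]
        base = bland_altman(pairs)
        shifted = bland_altman([(g, p + 10.0) for g, p in pairs])
        assert shifted.bias_ml == pytest.approx(base.bias_ml + 10.0)
        width = base.loa_high_ml - base.loa_low_ml
        assert shifted.loa_high_ml - shifted.loa_low_ml == pytest.approx(width)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 1.0)])


class TestDetectionStats:
    def test_reference_counts_reproduce_printed_ratios(self):
        det = detection_stats(detection_fixture())
        t = det.table
        assert t.loc["T", "sensitivity_pct"] == 96.7  # 411/425
        assert t.loc["T", "precision_pct"] == 94.9  # 411/433
        assert t.loc["M", "sensitivity_pct"] == 94.8  # 548/578
        assert t.loc["M", "precision_pct"] == 73.7  # 548/744
        assert t.loc["pooled", "precision_pct"] == 87.5  # 1787/2042

    def test_all_false_positives(self):
        pred = [Lesion(1, "predicted", 1, 0.1, category="T")]
        m = MatchResult(fp_ids={1})
        det = detection_stats([([], pred, m)])
        assert det.table.loc["pooled", "precision"] == 0.0
        assert np.isnan(det.table.loc["pooled", "sensitivity"])

    def test_zero_gt_category_sensitivity_is_missing(self):
        gt = [Lesion(1, "ground_truth", 1, 0.1, category="T")]
        pred = [Lesion(1, "predicted", 1, 0.1, category="T")]
        m = MatchResult(tp_pairs={(1, 1)})
        det = detection_stats([(gt, pred, m)])
        assert np.isnan(det.table.loc["N", "sensitivity"])
        assert det.table.loc["N", "fn"] == 0


class TestTaxonomy:
    def test_reference_fp_shares(self):
        tal = taxonomy_tally(m_fp_lesion_fixture())
        assert tal.total == 196
        assert tal.by_class.loc["physiologic", "n"] == 58
        assert tal.by_class.loc["physiologic", "share_pct"] == 29.6
        assert tal.by_class.loc["benign", "share_pct"] == 35.7
        assert tal.by_class.loc["pathologic", "share_pct"] == 34.7

    def test_single_physiologic_fp(self):
        l = Lesion(1, "predicted", 1, 0.1, category="M",
                   etiology_class="physiologic", etiology="brown_adipose_tissue")
        tal = taxonomy_tally([l])
        assert tal.by_class.loc["physiologic", "share_pct"] == 100.0

    def test_missing_etiology_counted_as_unannotated(self):
        lesions = [
            Lesion(1, "predicted", 1, 0.1, category="M"),
            Lesion(2, "predicted", 1, 0.1, category="M",
                   etiology_class="benign", etiology="x"),
        ]
        tal = taxonomy_tally(lesions)
        assert tal.by_class.loc["unannotated", "n"] == 1
        assert int(tal.by_class["n"].sum()) == 2

    def test_shares_sum_to_100_within_rounding(self):
        tal = taxonomy_tally(m_fp_lesion_fixture())
        assert abs(tal.by_class["share_pct"].sum() - 100.0) <= 0.1 * len(tal.by_class)


def test_round_half_away_from_zero():
    assert round_pct(2.25) == 2.3  # dyadic half case
    assert round_pct(-2.25) == -2.3
    assert round_pct(100 * 207 / 306) == 67.6
    assert round_pct(100 * 411 / 425) == 96.7
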