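"""Detection classification, per-patient metrics and operator agreement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cathtrack import (
    Metrics,
    Region,
    TipEstimate,
    aggregate_patients,
    build_report,
    classify_detection,
    classify_dynamic,
    compute_metrics,
    make_multislice_gt,
    operator_agreement,
)

# the per-patient pipeline results reported for the seven-patient cohort:
# (accuracy %, specificity %, sensitivity %)
PATIENT_RESULTS = {
    "p1": (100.0, 100.0, 100.0),
    "p2": (100.0, 100.0, 100.0),
    "p3": (100.0, 100.0, 100.0),
    "p4": (95.2, 100.0, 86.4),
    "p5": (100.0, 100.0, 100.0),
    "p6": (97.3, 99.3, 92.6),
    "p7": (96.3, 100.0, 89.0),
}


def region_at(centroid, size=3, score=1.0, slice_index=0):
    r0, c0 = int(centroid[0]), int(centroid[1])
    return Region(slice_index=slice_index,
                  pixels=tuple((r0, c0 + k) for k in range(size)),
                  centroid=centroid, intensity_score=score)


def gt_disk(shape=(16, 16), center=(8, 8), radius=2.5):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (np.hypot(yy - center[0], xx - center[1]) <= radius).astype(np.uint8)


class TestClassifyDetection:
    def test_single_region_centroid_inside_gt_is_tp(self):
        gt = gt_disk()
        assert classify_detection([region_at((8.2, 7.8))], gt) == "TP"

    def test_no_region_empty_gt_is_tn(self):
        assert classify_detection([], np.zeros((8, 8))) == "TN"

    def test_no_region_nonempty_gt_is_fn(self):
        assert classify_detection([], gt_disk()) == "FN"

    def test_region_on_empty_gt_is_fp(self):
        assert classify_detection([region_at((4.0, 4.0))], np.zeros((16, 16))) == "FP"

    def test_wrong_location_is_fp_by_default(self):
        assert classify_detection([region_at((1.0, 1.0))], gt_disk()) == "FP"

    def test_wrong_location_fn_convention(self):
        assert classify_detection([region_at((1.0, 1.0))], gt_disk(),
                                  missed_gt_label="FN") == "FN"

    def test_multiple_regions_never_tp(self):
        gt = gt_disk()
        regions = [region_at((8.0, 8.0)), region_at((1.0, 1.0))]
        assert classify_detection(regions, gt) == "FP"

    def test_centroid_rounding_to_nearest_pixel(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[8, 8] = 1
        assert classify_detection([region_at((7.6, 8.4))], gt) == "TP"
        assert classify_detection([region_at((7.4, 8.4))], gt) == "FP"

    def test_exhaustive_truth_table_oracle(self):
        """All combinations of region count x gt state x centroid location
        against an independently hand-built decision table."""
        gt_cases = {"empty": np.zeros((16, 16), dtype=np.uint8), "disk": gt_disk()}
        inside, outside = (8.0, 8.0), (1.0, 1.0)
        for n_regions in (0, 1, 2):
            for gt_name, gt in gt_cases.items():
                for where in (inside, outside):
                    regions = [region_at(where)] * n_regions
                    # oracle decision table
                    if n_regions == 0:
                        expected = "TN" if gt_name == "empty" else "FN"
                    elif gt_name == "empty":
                        expected = "FP"
                    elif n_regions == 1 and where == inside:
                        expected = "TP"
                    else:
                        expected = "FP"
                    assert classify_detection(regions, gt) == expected, \
                        (n_regions, gt_name, where)


class TestMultiSliceGT:
    def test_single_nonempty_slice_kept(self):
        gts = np.zeros((3, 16, 16), dtype=np.uint8)
        gts[1] = gt_disk()
        ref = make_multislice_gt(gts, np.ones((3, 16, 16)))
        assert ref.slice_index == 1 and ref.mask.sum() == gt_disk().sum()

    def test_highest_mean_intensity_slice_wins(self):
        gts = np.zeros((3, 16, 16), dtype=np.uint8)
        gts[0] = gt_disk()
        gts[1] = gt_disk()
        images = np.ones((3, 16, 16))
        images[0] *= 0.9
        images[1] *= 1.4
        assert make_multislice_gt(gts, images).slice_index == 1

    def test_all_empty(self):
        ref = make_multislice_gt(np.zeros((3, 8, 8)), np.ones((3, 8, 8)))
        assert ref.empty and ref.mask is None

    def test_classify_dynamic_against_reference(self):
        gts = np.zeros((3, 16, 16), dtype=np.uint8)
        gts[2] = gt_disk()
        ref = make_multislice_gt(gts, np.ones((3, 16, 16)))
        hit = TipEstimate(present=True, slice_index=2, tip=(8.0, 8.0))
        wrong_slice = TipEstimate(present=True, slice_index=0, tip=(8.0, 8.0))
        miss = TipEstimate(present=False)
        assert classify_dynamic(hit, ref) == "TP"
        assert classify_dynamic(wrong_slice, ref) == "FP"
        assert classify_dynamic(miss, ref) == "FN"
        empty_ref = make_multislice_gt(np.zeros((3, 16, 16)), np.ones((3, 16, 16)))
        assert classify_dynamic(miss, empty_ref) == "TN"
        assert classify_dynamic(hit, empty_ref) == "FP"


class TestComputeMetrics:
    def test_hand_computed_counts(self):
        outcomes = ["TP"] * 19 + ["FN"] * 3 + ["TN"] * 60
        m = compute_metrics(outcomes)
        assert round(m.sensitivity, 1) == 86.4  # 19/22
        assert m.specificity == pytest.approx(100.0)
        assert round(m.accuracy, 1) == 96.3  # 79/82

    def test_all_tp_degenerate_specificity(self):
        with pytest.warns(UserWarning, match="specificity undefined"):
            m = compute_metrics(["TP", "TP"])
        assert m.accuracy == 100.0 and m.sensitivity == 100.0
        assert np.isnan(m.specificity)

    def test_symmetric_unit_counts(self):
        m = compute_metrics(["TP", "FP", "TN", "FN"])
        assert m.as_tuple() == (50.0, 50.0, 50.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([])

    @given(st.lists(st.sampled_from(["TP", "FP", "TN", "FN"]), min_size=1, max_size=60))
    def test_outcomes_partition_and_accuracy_bounds(self, outcomes):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(outcomes)
        n_correct = sum(o in ("TP", "TN") for o in outcomes)
        assert m.accuracy == pytest.approx(100.0 * n_correct / len(outcomes))


class TestAggregatePatients:
    def test_seven_patient_cohort_means(self):
        mean, sd = aggregate_patients(PATIENT_RESULTS)
        assert round(mean.accuracy, 1) == 98.4
        assert round(mean.specificity, 1) == 99.9
        assert round(mean.sensitivity, 1) == 95.4
        # population-sd spreads of the specificity and sensitivity columns
        assert round(sd.specificity, 1) == 0.2
        assert round(sd.sensitivity, 1) == 5.5

    def test_single_patient(self):
        mean, sd = aggregate_patients({"p": (90.0, 95.0, 85.0)})
        assert mean.as_tuple() == (90.0, 95.0, 85.0)
        assert sd.as_tuple() == (0.0, 0.0, 0.0)

    def test_nan_entries_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            mean, _ = aggregate_patients({
                "a": (100.0, float("nan"), 100.0),
                "b": (80.0, 90.0, 60.0),
            })
        assert mean.accuracy == pytest.approx(90.0)
        assert mean.specificity == pytest.approx(90.0)

    def test_build_report_counts_sum_to_n(self):
        report = build_report({
            "a": ["TP", "TN", "FP"],
            "b": ["TP", "TP", "FN", "TN"],
        })
        assert sum(report.counts["a"].values()) == 3
        assert sum(report.counts["b"].values()) == 4
        d = report.to_dict()
        assert set(d["per_patient"]) == {"a", "b"}
        assert d["mean"]["accuracy"] is not None


class TestOperatorAgreement:
    def test_identical_masks_agree(self):
        m = gt_disk()
        assert operator_agreement(m, m)

    def test_disjoint_masks_disagree(self):
        a = np.zeros((16, 16)); a[2:4, 2:4] = 1
        b = np.zeros((16, 16)); b[10:12, 10:12] = 1
        assert not operator_agreement(a, b)

    def test_both_empty_agree_one_empty_disagrees(self):
        z = np.zeros((8, 8))
        assert operator_agreement(z, z)
        assert not operator_agreement(z, gt_disk((8, 8), (4, 4), 1.5))

    def test_blob_on_ring_disagrees(self):
        # B is a ring whose centre of mass falls in the hole, outside A
        yy, xx = np.mgrid[0:32, 0:32]
        d = np.hypot(yy - 16, xx - 16)
        ring = ((d >= 8) & (d <= 11)).astype(np.uint8)
        blob = np.zeros((32, 32), dtype=np.uint8)
        blob[14:19, 25:27] = ring[14:19, 25:27]  # a patch of the ring
        assert blob.sum() > 0 and (ring[blob > 0] == 1).all()
        assert not operator_agreement(blob, ring)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((10, 10)) > 0.8).astype(np.uint8)
        b = (rng.random((10, 10)) > 0.8).astype(np.uint8)
        assert operator_agreement(a, b) == operator_agreement(b, a)
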