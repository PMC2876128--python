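import numpy as np
import pytest

from crpcna import (
    ContingencyCounts,
    compute_metrics,
    contingency,
    contingency_from_labels,
    evaluate_labels,
)
from crpcna.metrics import regions_from_labels


# Published per-sample benchmark rows (sr, sp, rr, rp, hr, hp, f) for an
# HMM caller on the 500K simulation, used to pin down the hybrid-metric
# conventions: hr = sr*rr, hp = sp*rp, f = harmonic mean of hp and hr.
HMM_ROWS = [
    (0.9718, 0.9857, 0.9091, 0.7143, 0.8834, 0.7041, 0.7836),
    (0.98, 0.9709, 0.9545, 0.7241, 0.9355, 0.703, 0.8028),
    (0.9376, 0.9803, 0.8182, 0.6923, 0.7672, 0.6787, 0.7202),
    (0.9659, 0.967, 0.9091, 0.7143, 0.8781, 0.6907, 0.7732),
    (0.9459, 0.9841, 0.8636, 0.7143, 0.8169, 0.7029, 0.7556),
    (0.98, 0.9731, 0.9545, 0.7241, 0.9355, 0.7047, 0.8038),
    (0.8918, 0.9768, 0.7727, 0.68, 0.6891, 0.6642, 0.6764),
    (0.92, 0.9583, 0.7727, 0.68, 0.7109, 0.6517, 0.68),
    (0.7765, 0.9836, 0.6364, 0.6364, 0.4941, 0.6259, 0.5523),
    (0.9435, 0.9686, 0.9091, 0.7143, 0.8578, 0.6919, 0.7659),
    (0.8235, 0.979, 0.6818, 0.6667, 0.5615, 0.6527, 0.6037),
    (0.9071, 0.9674, 0.7727, 0.68, 0.7009, 0.6578, 0.6787),
    (0.5247, 0.8352, 0.3636, 0.4444, 0.1908, 0.3712, 0.252),
    (0.9129, 0.8509, 0.7727, 0.6538, 0.7055, 0.5563, 0.6221),
    (0.6165, 0.9758, 0.5455, 0.6, 0.3363, 0.5855, 0.4272),
    (0.8518, 0.836, 0.7273, 0.64, 0.6195, 0.5351, 0.5742),
    (0.7718, 0.9061, 0.6364, 0.6087, 0.4911, 0.5515, 0.5196),
    (0.8235, 0.8516, 0.7273, 0.6667, 0.5989, 0.5677, 0.5829),
]

# First published CRP row of the same benchmark.  Its hybrid cells
# follow the *crossed* products (hr = sp*rr, hp = sr*rp) instead: the
# two published tables are mutually inconsistent, and this package
# implements the straight-product convention that the HMM table obeys.
CRP_ROW_CROSSED = (0.986, 0.972, 0.955, 1.000, 0.928, 0.986)


def _harmonic(a, b):
    return 2 * a * b / (a + b) if a + b else 0.0


@pytest.mark.parametrize("row", HMM_ROWS)
def test_hybrid_and_f_cells_follow_straight_products(row):
    sr, sp, rr, rp, hr, hp, f = row
    assert sr * rr == pytest.approx(hr, abs=1e-3)
    assert sp * rp == pytest.approx(hp, abs=1e-3)
    assert _harmonic(sp * rp, sr * rr) == pytest.approx(f, abs=1e-3)


def test_crossed_product_table_is_inconsistent_with_straight_products():
    sr, sp, rr, rp, hr, hp = CRP_ROW_CROSSED
    # crossed products reproduce the cells ...
    assert sp * rr == pytest.approx(hr, abs=1e-3)
    assert sr * rp == pytest.approx(hp, abs=1e-3)
    # ... straight products do not
    assert abs(sr * rr - hr) > 1e-3


def test_published_row_reproduced_from_its_base_metrics():
    sr, sp, rr, rp, hr, hp, f = HMM_ROWS[0]
    assert sr * rr == pytest.approx(0.8834, abs=1e-3)
    assert _harmonic(hp, hr) == pytest.approx(0.7836, abs=1e-3)


# ---------------------------------------------------------------------------
# contingency counting


def test_contingency_of_overlapping_truth_and_prediction():
    counts = contingency([(10, 20)], [(12, 26)], n_markers=40)
    assert counts.snp_tp == 8
    assert counts.snp_fn == 2
    assert counts.snp_fp == 6
    assert counts.snp_tn == 24
    assert counts.region_detected == 1
    assert counts.region_missed == 0
    assert counts.pred_region_true == 1
    assert counts.pred_region_false == 0


def test_perfect_prediction():
    truth = [(3, 9), (20, 30)]
    counts = contingency(truth, truth, n_markers=40)
    assert counts.snp_fp == counts.snp_fn == 0
    assert counts.region_detected == 2
    assert counts.pred_region_false == 0
    report = compute_metrics(counts)
    assert report.as_dict() == pytest.approx(
        {"sr": 1, "sp": 1, "rr": 1, "rp": 1, "hr": 1, "hp": 1, "f": 1}
    )


def test_empty_prediction():
    counts = contingency([(3, 9)], [], n_markers=20)
    assert counts.snp_tp == 0
    assert counts.region_missed == 1
    assert counts.pred_region_true == counts.pred_region_false == 0
    report = compute_metrics(counts)
    assert report.sr == 0.0
    assert report.rr == 0.0
    assert report.f == 0.0


def test_overlapping_regions_within_one_set_rejected():
    with pytest.raises(ValueError, match="overlap"):
        contingency([(0, 5), (4, 9)], [], n_markers=10)


def test_single_snp_overlap_detects_a_region():
    # region detection requires only one shared marker
    counts = contingency([(10, 50)], [(49, 55)], n_markers=60)
    assert counts.region_detected == 1
    assert counts.pred_region_true == 1


def test_labels_route_matches_region_route():
    truth = np.full(30, 2)
    truth[5:12] = 1
    pred = np.full(30, 2)
    pred[7:15] = 1
    pred[20:24] = 3
    a = contingency_from_labels(truth, pred, normal_state=2)
    b = contingency(
        regions_from_labels(truth != 2), regions_from_labels(pred != 2), 30
    )
    assert a == b


# ---------------------------------------------------------------------------
# metric properties


def test_all_metrics_bounded_and_f_below_max():
    counts = ContingencyCounts(5, 3, 2, 20, 1, 1, 1, 1)
    r = compute_metrics(counts)
    for v in r.as_dict().values():
        assert 0.0 <= v <= 1.0
    assert r.f <= max(r.hp, r.hr) + 1e-12
    assert r.hr == pytest.approx(r.sr * r.rr)
    assert r.hp == pytest.approx(r.sp * r.rp)


def test_adding_a_correct_marker_never_decreases_recall():
    truth = np.full(50, 2)
    truth[10:30] = 3
    pred = np.full(50, 2)
    pred[10:20] = 3
    before = compute_metrics(contingency_from_labels(truth, pred))
    pred[20] = 3  # extend the correct call by one marker
    after = compute_metrics(contingency_from_labels(truth, pred))
    assert after.sr >= before.sr
    assert after.rr >= before.rr


def test_spurious_isolated_region_never_increases_region_precision():
    truth = np.full(50, 2)
    truth[10:20] = 3
    pred = np.full(50, 2)
    pred[10:20] = 3
    before = compute_metrics(contingency_from_labels(truth, pred))
    pred[40:43] = 1  # a fabricated region far from any truth
    after = compute_metrics(contingency_from_labels(truth, pred))
    assert after.rp <= before.rp


def test_degenerate_empty_truth_conventions():
    # nothing to find, nothing called: vacuously perfect
    perfect = compute_metrics(contingency([], [], n_markers=10))
    assert perfect.as_dict() == pytest.approx({k: 1.0 for k in "sr sp rr rp hr hp f".split()})
    # nothing to find but something called: recalls stay 1-less semantics, precisions 0
    noisy = compute_metrics(contingency([], [(2, 5)], n_markers=10))
    assert noisy.sp == 0.0
    assert noisy.rp == 0.0
    assert noisy.f == 0.0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyCounts(-1, 0, 0, 0, 0, 0, 0, 0)


def test_evaluate_labels_end_to_end():
    truth = np.full(100, 2)
    truth[10:20] = 1
    truth[60:80] = 3
    report = evaluate_labels(truth, truth)
    assert report.f == 1.0
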