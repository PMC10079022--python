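"""Threshold selection, binarization/merging, false-positive exclusion and
segment geometry, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import arousalhrv as ah
from arousalhrv.config import AnalysisConfig


def brute_force_roc(scores, labels, threshold):
    """Confusion-matrix counts for the predicate score > threshold."""
    pred = scores > threshold
    tp = np.sum(pred & (labels == 1))
    fn = np.sum(~pred & (labels == 1))
    fp = np.sum(pred & (labels == 0))
    tn = np.sum(~pred & (labels == 0))
    return tp / (tp + fn), fp / (fp + tn)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_separable_case():
    probs = ah.ProbSeries(np.array([0.1, 0.2, 0.8, 0.9]))
    roc = ah.compute_roc(probs, [0, 0, 1, 1])
    tpr, fpr = brute_force_roc(probs.values, np.array([0, 0, 1, 1]), 0.5)
    assert (tpr, fpr) == (1.0, 0.0)
    by_thr = {t: (tp, fp) for t, tp, fp in roc}
    assert by_thr[0.2] == (1.0, 0.0)


def test_roc_perfect_scores_hit_corner():
    labels = np.array([0, 1, 0, 1, 1, 0])
    probs = ah.ProbSeries(labels.astype(float))
    roc = ah.compute_roc(probs, labels)
    assert any(tpr == 1.0 and fpr == 0.0 for _, tpr, fpr in roc)


def test_roc_matches_brute_force_counts():
    rng = np.random.default_rng(0)
    scores = np.round(rng.random(1000), 3)
    labels = (rng.random(1000) < 0.3).astype(int)
    roc = ah.compute_roc(ah.ProbSeries(scores), labels)
    assert len(roc) == len(np.unique(np.concatenate(([0.0], scores))))
    for t, tpr, fpr in roc:
        bt, bf = brute_force_roc(scores, labels, t)
        assert tpr == pytest.approx(bt, abs=1e-12)
        assert fpr == pytest.approx(bf, abs=1e-12)


def test_roc_agrees_with_sklearn_on_shared_thresholds():
    """Independent cross-check: at threshold t, our (tpr, fpr) for score > t
    equals sklearn's point for score >= next-larger distinct value."""
    from sklearn.metrics import roc_curve

    rng = np.random.default_rng(1)
    scores = np.round(rng.random(500), 2)
    labels = (rng.random(500) < scores).astype(int)
    ours = {t: (tpr, fpr) for t, tpr, fpr in
            ah.compute_roc(ah.ProbSeries(scores), labels)}
    fpr_sk, tpr_sk, thr_sk = roc_curve(labels, scores, drop_intermediate=False)
    distinct = np.unique(scores)
    for v_lo, v_hi in zip(distinct[:-1], distinct[1:]):
        i = np.where(thr_sk == v_hi)[0]
        if i.size:
            assert ours[v_lo][0] == pytest.approx(tpr_sk[i[0]], abs=1e-12)
            assert ours[v_lo][1] == pytest.approx(fpr_sk[i[0]], abs=1e-12)


def test_roc_degenerate_labels():
    probs = ah.ProbSeries(np.array([0.1, 0.9]))
    with pytest.raises(ah.DegenerateLabelsError):
        ah.compute_roc(probs, [1, 1])


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

def test_select_threshold_hand_enumeration():
    roc = [(0.1, 0.9, 0.4), (0.5, 0.7, 0.1), (0.9, 0.3, 0.0)]
    choice = ah.select_threshold(roc)
    assert choice.threshold == 0.5
    assert choice.score == pytest.approx(0.63)


def test_select_threshold_tie_breaks_to_smallest():
    roc = [(0.2, 1.0, 0.0), (0.4, 1.0, 0.0), (0.6, 0.5, 0.0)]
    assert ah.select_threshold(roc).threshold == 0.2


def test_select_threshold_uninformative_bound():
    """Independent scores: max tpr*(1-fpr) cannot much exceed 1/4."""
    rng = np.random.default_rng(2)
    scores = rng.random(5000)
    labels = (rng.random(5000) < 0.5).astype(int)
    choice = ah.select_threshold(ah.compute_roc(ah.ProbSeries(scores), labels))
    assert choice.score <= 0.25 + 0.03


def test_select_threshold_equals_exhaustive_search():
    rng = np.random.default_rng(3)
    for trial in range(20):
        n = int(rng.integers(50, 2000))
        scores = np.round(rng.random(n), 3)
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.min() == labels.max():
            continue
        choice = ah.select_threshold(ah.compute_roc(ah.ProbSeries(scores), labels))
        best_score, best_t = -1.0, None
        for t in np.unique(np.concatenate(([0.0], scores))):
            tpr, fpr = brute_force_roc(scores, labels, t)
            s = tpr * (1 - fpr)
            if s > best_score + 1e-15:
                best_score, best_t = s, t
        assert choice.threshold == best_t
        assert choice.score == pytest.approx(best_score, abs=1e-12)


# ---------------------------------------------------------------------------
# Binarize and merge
# ---------------------------------------------------------------------------

def _series(high_runs, n=200, high=0.9, low=0.1):
    v = np.full(n, low)
    for a, b in high_runs:
        v[a:b] = high
    return ah.ProbSeries(v)


def test_single_run():
    events = ah.binarize_and_merge(_series([(10, 15)]), 0.5)
    assert len(events) == 1
    assert events[0].onset_s == 10 and events[0].duration_s == 5


def test_three_second_run_discarded():
    assert ah.binarize_and_merge(_series([(10, 13)]), 0.5) == []
    assert len(ah.binarize_and_merge(_series([(10, 14)]), 0.5)) == 1


def test_gap_of_five_merges():
    events = ah.binarize_and_merge(_series([(100, 105), (110, 116)]), 0.5)
    assert len(events) == 1
    assert events[0].onset_s == 100 and events[0].end_s == 116


def test_gap_of_twelve_stays_separate():
    events = ah.binarize_and_merge(_series([(100, 105), (117, 123)]), 0.5)
    assert len(events) == 2


def test_gap_rule_drop_discards_later_run():
    config = AnalysisConfig(gap_rule="drop")
    events = ah.binarize_and_merge(_series([(100, 105), (110, 116)]), 0.5, config)
    assert len(events) == 1
    assert events[0].onset_s == 100 and events[0].duration_s == 5


def test_peak_is_earliest_max_excluding_gap_seconds():
    v = np.full(200, 0.1)
    v[100:105] = [0.6, 0.95, 0.95, 0.7, 0.6]
    v[107] = 0.99  # gap second? no: above threshold -> separate run, merged
    v[110:116] = 0.8
    probs = ah.ProbSeries(v)
    events = ah.binarize_and_merge(probs, 0.5)
    assert len(events) == 1
    assert events[0].peak_time_s == 107 and events[0].peak_prob == 0.99
    # with the 0.99 second below threshold it is a true gap second: ignored
    v2 = v.copy()
    v2[107] = 0.2
    events2 = ah.binarize_and_merge(ah.ProbSeries(v2), 0.5)
    assert events2[0].peak_time_s == 101  # earliest of the tied 0.95 maxima


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=30, max_size=120),
       st.floats(min_value=0.05, max_value=0.95))
def test_merge_idempotent(values, threshold):
    """Re-binarizing an indicator built from the detected events is a fixpoint."""
    probs = ah.ProbSeries(np.array(values))
    events = ah.binarize_and_merge(probs, threshold)
    indicator = np.zeros(len(values))
    for ev in events:
        indicator[int(ev.onset_s):int(ev.end_s)] = 1.0
    again = ah.binarize_and_merge(ah.ProbSeries(indicator), 0.5)
    assert [(e.onset_s, e.duration_s) for e in again] == \
           [(e.onset_s, e.duration_s) for e in events]


# ---------------------------------------------------------------------------
# False-positive exclusion
# ---------------------------------------------------------------------------

def _detected(onset, dur):
    return ah.DetectedArousal(onset_s=onset, duration_s=dur,
                              peak_time_s=onset + 1, peak_prob=0.9)


@pytest.mark.parametrize("scored_iv,kept", [
    ((105.0, 7.0), True),    # 5 s overlap
    ((1500.0, 10.0), False),  # no overlap anywhere near
    ((109.5, 5.5), False),   # 0.5 s < 1 s minimum overlap
    ((109.0, 5.0), True),    # exactly 1 s
])
def test_exclude_false_positives(scored_iv, kept):
    det = _detected(100.0, 10.0)
    scored = [ah.ScoredEvent("arousal", *scored_iv)]
    out = ah.exclude_false_positives([det], scored)
    assert (len(out) == 1) is kept
    if kept:
        assert out[0].matched and out[0].matched_scored


def test_exclusion_ignores_non_arousal_events():
    det = _detected(100.0, 10.0)
    scored = [ah.ScoredEvent("OSA", 100.0, 10.0)]
    assert ah.exclude_false_positives([det], scored) == []


# ---------------------------------------------------------------------------
# Segment triplets
# ---------------------------------------------------------------------------

def test_segment_arithmetic():
    det = _detected(95.0, 10.0)
    det.peak_time_s = 100.0
    seg = ah.define_segments(det, 1000.0)
    assert (seg.pre.start, seg.pre.end) == (63.0, 88.0)
    assert (seg.intra.start, seg.intra.end) == (88.0, 113.0)
    assert (seg.post.start, seg.post.end) == (113.0, 138.0)


def test_segment_edge_exclusion():
    det = _detected(18.0, 6.0)
    det.peak_time_s = 20.0
    assert ah.define_segments(det, 1000.0) is None  # pre would start at -17
    det2 = _detected(986.0, 6.0)
    det2.peak_time_s = 988.0
    assert ah.define_segments(det2, 1000.0) is None  # post beyond recording


def test_segments_tile_75_contiguous_seconds():
    for peak in (40.0, 200.5, 900.0):
        det = _detected(peak - 2, 5.0)
        det.peak_time_s = peak
        seg = ah.define_segments(det, 1000.0)
        assert seg.post.end - seg.pre.start == 75.0
        assert seg.pre.end == seg.intra.start and seg.intra.end == seg.post.start
        assert seg.intra.start <= peak < seg.intra.end


def test_disjoint_triplets_for_distant_events():
    a, b = _detected(195.0, 8.0), _detected(395.0, 8.0)
    a.peak_time_s, b.peak_time_s = 200.0, 400.0
    sa, sb = ah.define_segments(a, 1000.0), ah.define_segments(b, 1000.0)
    assert sa.post.end <= sb.pre.start
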