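"""From probability series to included arousal events.

Steps, in pipeline order: per-second ROC against scored-arousal labels,
threshold selection by max TPR x (1 - FPR), binarization with the strict
``score > threshold`` predicate, merging of runs separated by gaps of at
most 11 s, removal of events lasting 3 s or less, false-positive exclusion
against scored arousals (>= 1 s overlap), and the 25-s pre/intra/post
segment triplet centred on the peak-probability second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import DegenerateLabelsError, ValidationError
from .io_formats import ProbSeries, ScoredEvent

logger = logging.getLogger(__name__)


@dataclass
class ThresholdChoice:
    threshold: float
    tpr: float
    fpr: float

    @property
    def score(self) -> float:
        return self.tpr * (1.0 - self.fpr)


@dataclass
class DetectedArousal:
    """A merged above-threshold event on the 1 Hz probability grid."""

    onset_s: float
    duration_s: float
    peak_time_s: float
    peak_prob: float
    matched: bool = False
    matched_scored: List[ScoredEvent] = field(default_factory=list)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Window:
    start: float
    end: float

    def __iter__(self):
        yield self.start
        yield self.end

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class SegmentTriplet:
    pre: Window
    intra: Window
    post: Window

    def __post_init__(self) -> None:
        if not (self.pre.end == self.intra.start and self.intra.end == self.post.start):
            raise ValidationError("segments must be contiguous")
        lens = {self.pre.length, self.intra.length, self.post.length}
        if len(lens) != 1:
            raise ValidationError("segments must have equal length")


# ---------------------------------------------------------------------------
# ROC and threshold selection
# ---------------------------------------------------------------------------

def labels_from_events(scored: Sequence[ScoredEvent], n_seconds: int,
                       start_offset_s: float = 0.0) -> np.ndarray:
    """Per-second binary indicator: 1 where the second overlaps a scored arousal."""
    labels = np.zeros(n_seconds, dtype=int)
    for ev in scored:
        if ev.kind != "arousal":
            continue
        lo = int(np.floor(ev.start_s - start_offset_s))
        hi = int(np.ceil(ev.end_s - start_offset_s))
        labels[max(lo, 0): min(hi, n_seconds)] = 1
    return labels


def compute_roc(probs: ProbSeries, labels) -> List[Tuple[float, float, float]]:
    """ROC points ``(threshold, tpr, fpr)`` for the predicate score > threshold.

    One point per distinct score value plus a threshold-0 endpoint; sorted by
    increasing threshold, so TPR and FPR are non-increasing along the list.
    """
    scores = np.asarray(probs.values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(scores) != len(y):
        raise ValidationError("probability series and labels differ in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("labels are all identical; ROC undefined")

    thresholds = np.unique(np.concatenate(([0.0], scores)))
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = y[order]
    # suffix sums: positives/negatives with score strictly greater than t
    cum_pos = np.concatenate(([0], np.cumsum(y_sorted)))
    cum_neg = np.concatenate(([0], np.cumsum(1 - y_sorted)))
    idx = np.searchsorted(s_sorted, thresholds, side="right")
    tp = n_pos - cum_pos[idx]
    fp = n_neg - cum_neg[idx]
    return [(float(t), float(tpi) / n_pos, float(fpi) / n_neg)
            for t, tpi, fpi in zip(thresholds, tp, fp)]


def select_threshold(roc: Sequence[Tuple[float, float, float]]) -> ThresholdChoice:
    """Pick the ROC point maximizing TPR x (1 - FPR); ties -> smaller threshold."""
    if not roc:
        raise ValidationError("empty ROC")
    best = None
    for t, tpr, fpr in sorted(roc, key=lambda p: p[0]):
        score = tpr * (1.0 - fpr)
        if best is None or score > best[0] + 1e-15:
            best = (score, t, tpr, fpr)
    _, t, tpr, fpr = best
    return ThresholdChoice(threshold=t, tpr=tpr, fpr=fpr)


# ---------------------------------------------------------------------------
# Binarization, merging, duration filtering
# ---------------------------------------------------------------------------

def binarize_and_merge(probs: ProbSeries, threshold: float,
                       config: AnalysisConfig = DEFAULT_CONFIG) -> List[DetectedArousal]:
    """Turn the per-second score series into candidate arousal events.

    Seconds with ``score > threshold`` form runs; runs whose gap is at most
    ``merge_gap_s`` are merged (``gap_rule="merge"``) or the later run is
    dropped (``gap_rule="drop"``).  Events lasting ``min_event_duration_s``
    or less are then discarded (strict >).  The peak is the earliest
    above-threshold second achieving the maximum score; gap seconds never
    contribute to the peak search.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    values = probs.values
    above = values > threshold
    if not above.any():
        return []

    # runs of consecutive above-threshold seconds, as index intervals [i0, i1)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))

    groups: List[List[Tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        gap = run[0] - groups[-1][-1][1]
        if gap <= config.merge_gap_s:
            if config.gap_rule == "merge":
                groups[-1].append(run)
            # "drop": the later run is discarded
        else:
            groups.append([run])

    events = []
    offset = probs.start_offset_s
    for group in groups:
        i0, i1 = group[0][0], group[-1][1]
        duration = float(i1 - i0)
        if duration <= config.min_event_duration_s:
            continue
        member_idx = np.concatenate([np.arange(a, b) for a, b in group])
        member_vals = values[member_idx]
        peak_i = int(member_idx[int(np.argmax(member_vals))])  # argmax -> earliest max
        events.append(DetectedArousal(
            onset_s=offset + float(i0),
            duration_s=duration,
            peak_time_s=offset + float(peak_i),
            peak_prob=float(values[peak_i]),
        ))
    events.sort(key=lambda e: e.onset_s)
    return events


def exclude_false_positives(detected: Sequence[DetectedArousal],
                            scored: Sequence[ScoredEvent],
                            config: AnalysisConfig = DEFAULT_CONFIG) -> List[DetectedArousal]:
    """Keep detected events overlapping a scored arousal by >= 1 s."""
    arousals = [ev for ev in scored if ev.kind == "arousal"]
    kept = []
    for det in detected:
        matches = [ev for ev in arousals
                   if ev.overlaps(det.onset_s, det.end_s) >= config.min_match_overlap_s]
        if matches:
            det.matched = True
            det.matched_scored = matches
            kept.append(det)
    return kept


# ---------------------------------------------------------------------------
# Segment triplet
# ---------------------------------------------------------------------------

def define_segments(event: DetectedArousal, recording_duration_s: float,
                    config: AnalysisConfig = DEFAULT_CONFIG) -> Optional[SegmentTriplet]:
    """25-s pre/intra/post windows centred on the peak-probability second.

    Returns ``None`` when any window would extend beyond the recording
    (edge exclusion — a logged outcome, not an error).
    """
    seg = config.segment_len_s
    intra_start = event.peak_time_s - config.intra_pre_s
    intra = Window(intra_start, intra_start + seg)
    pre = Window(intra.start - seg, intra.start)
    post = Window(intra.end, intra.end + seg)
    if pre.start < 0 or post.end > recording_duration_s:
        logger.info("edge exclusion for event at %.0f s", event.onset_s)
        return None
    return SegmentTriplet(pre=pre, intra=intra, post=post)
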