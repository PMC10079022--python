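"""End-to-end orchestration: recordings in, comparison tables out.

Per recording: detect R peaks (or accept precomputed peak times), select or
apply the probability threshold, binarize/merge/filter arousal events,
exclude false positives against scored arousals, build segment triplets,
classify etiology and stage, extract per-segment RR with the abnormal-RR
exclusion, and compute HRV.  Cohort level: pool per-event rows (the
analysis treats events, not subjects, as the unit) and run the stratified
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import arousal_events as ae
from . import etiology as eti
from . import qrs_hrv as qh
from . import stats_report as sr
from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import InsufficientBeatsError
from .io_formats import EcgRecord, Hypnogram, ProbSeries, ScoredEvent

logger = logging.getLogger(__name__)

_METRIC_COLS = ("sdnn_ms", "rmssd_ms", "pnn50_pct", "hr_bpm")


@dataclass
class RecordingAnalysis:
    """Per-recording outcome: annotated events, HRV rows, funnel counts."""

    events: pd.DataFrame
    funnel: Dict[str, int]
    threshold: Optional[ae.ThresholdChoice]
    annotations: List[eti.AnnotatedArousal] = field(default_factory=list)


def analyze_recording(prob: ProbSeries, scored: Sequence[ScoredEvent],
                      hypnogram: Optional[Hypnogram],
                      ecg: Optional[EcgRecord] = None,
                      peak_times_s: Optional[np.ndarray] = None,
                      duration_s: Optional[float] = None,
                      gender: Optional[str] = None,
                      config: AnalysisConfig = DEFAULT_CONFIG) -> RecordingAnalysis:
    """Run the full per-recording pipeline.

    Either ``ecg`` (R peaks detected with Pan-Tompkins) or precomputed
    ``peak_times_s`` must be provided.  ``duration_s`` defaults to the ECG
    duration, else the hypnogram span, else the probability-series length.
    """
    if peak_times_s is None:
        if ecg is None:
            raise ValueError("need either an ECG record or precomputed peak times")
        peak_times_s = qh.pan_tompkins(ecg, config)
    peak_times_s = np.asarray(peak_times_s, dtype=float)
    if duration_s is None:
        if ecg is not None:
            duration_s = ecg.duration_s
        elif hypnogram is not None:
            duration_s = hypnogram.duration_s
        else:
            duration_s = float(len(prob))

    # --- threshold ----------------------------------------------------
    choice = None
    threshold = config.threshold
    if threshold is None:
        labels = ae.labels_from_events(scored, len(prob), prob.start_offset_s)
        choice = ae.select_threshold(ae.compute_roc(prob, labels))
        threshold = choice.threshold

    # --- arousal events -----------------------------------------------
    detected = ae.binarize_and_merge(prob, threshold, config)
    matched = ae.exclude_false_positives(detected, scored, config)

    n_scored = sum(1 for ev in scored if ev.kind == "arousal")
    funnel = {
        "scored_arousals": n_scored,
        "detected": len(detected),
        "matched": len(matched),
    }

    rows = []
    annotations = []
    n_edge = n_wake = n_insufficient = n_abnormal = n_analyzed = 0
    for k, det in enumerate(matched):
        segments = ae.define_segments(det, duration_s, config)
        ann = eti.annotate_arousal(det, segments, scored, hypnogram, config)
        annotations.append(ann)
        row = {
            "event_id": k, "onset_s": det.onset_s, "duration_s": det.duration_s,
            "peak_time_s": det.peak_time_s, "peak_prob": det.peak_prob,
            "etiology": ann.etiology, "stage": ann.stage,
            "reclassified_from_uod": ann.reclassified_from_uod,
            "gender": gender, "excluded_reason": ann.excluded_reason,
        }
        if segments is None:
            n_edge += 1
            rows.append(row)
            continue
        if ann.excluded_reason == "wake":
            n_wake += 1
            rows.append(row)
            continue
        try:
            triplet_rr = [qh.extract_segment_rr(peak_times_s, w, config)
                          for w in (segments.pre, segments.intra, segments.post)]
        except InsufficientBeatsError:
            row["excluded_reason"] = "insufficient"
            n_insufficient += 1
            rows.append(row)
            continue
        if qh.has_abnormal_rr(triplet_rr, config):
            row["excluded_reason"] = "abnormal_rr"
            n_abnormal += 1
            rows.append(row)
            continue
        for seg_name, rr in zip(("pre", "intra", "post"), triplet_rr):
            try:
                m = qh.compute_hrv(rr, config)
            except InsufficientBeatsError:
                row["excluded_reason"] = "insufficient"
                break
            row[f"sdnn_ms_{seg_name}"] = m.sdnn_ms
            row[f"rmssd_ms_{seg_name}"] = m.rmssd_ms
            row[f"pnn50_pct_{seg_name}"] = m.pnn50_pct
            row[f"hr_bpm_{seg_name}"] = m.hr_bpm
            row[f"n_beats_{seg_name}"] = m.n_beats
        if row["excluded_reason"] == "insufficient":
            n_insufficient += 1
        else:
            n_analyzed += 1
        rows.append(row)

    funnel.update(edge_excluded=n_edge, wake_excluded=n_wake,
                  insufficient_beats=n_insufficient,
                  abnormal_rr_excluded=n_abnormal, analyzed=n_analyzed)
    columns = ["event_id", "onset_s", "duration_s", "peak_time_s", "peak_prob",
               "etiology", "stage", "reclassified_from_uod", "gender",
               "excluded_reason"] + [f"{c}_{s}" for c in _METRIC_COLS + ("n_beats",)
                                     for s in ("pre", "intra", "post")]
    events = pd.DataFrame(rows, columns=columns)
    return RecordingAnalysis(events=events, funnel=funnel, threshold=choice,
                             annotations=annotations)


@dataclass
class CohortAnalysis:
    events: pd.DataFrame
    results: List[sr.ComparisonResult]
    funnel: Dict[str, int]
    report: dict


def analyze_cohort(analyses: Sequence[RecordingAnalysis],
                   config: AnalysisConfig = DEFAULT_CONFIG,
                   strata: Sequence[str] = ("overall", "gender", "stage"),
                   ) -> CohortAnalysis:
    """Pool per-recording event tables and run the stratified comparisons."""
    events = pd.concat([a.events for a in analyses], ignore_index=True)
    analyzed = events[events["excluded_reason"].isna()].copy()
    funnel: Dict[str, int] = {}
    for a in analyses:
        for k, v in a.funnel.items():
            funnel[k] = funnel.get(k, 0) + v
    results = sr.build_comparison_tables(analyzed, config, strata=strata)
    normality = sr.normality_summary(analyzed) if len(analyzed) >= 3 else {}
    choice = next((a.threshold for a in analyses if a.threshold is not None), None)
    report = sr.build_run_report(choice, funnel, normality, config,
                                 n_comparisons=sum(
                                     1 for r in results if np.isfinite(r.p_raw)))
    return CohortAnalysis(events=events, results=results, funnel=funnel,
                          report=report)
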