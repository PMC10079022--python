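"""Arousal etiology by temporal lookback, and REM/NREM stage assignment.

Each retained arousal is attributed to the highest-priority scored event
overlapping the 10 s preceding its onset, in the order OSA > CSA >
hypopnea > PLM.  If only an oxygen desaturation overlaps the window the
arousal is an undefined oxygen desaturation (UOD) arousal; a secondary
10-s search before the desaturation onset may reclassify it to the
respiratory event that caused the desaturation.  Arousals with an empty
window are spontaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .arousal_events import DetectedArousal, SegmentTriplet
from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import ArousalHrvError
from .io_formats import Hypnogram, ScoredEvent

ETIOLOGIES = ("OSA", "CSA", "Hypopnea", "PLM", "UOD", "Spontaneous")
#: respiratory/limb priority order for the primary lookback
PRIORITY = ("OSA", "CSA", "hypopnea", "PLM")
#: only respiratory events are searched in the secondary (UOD) window
RESPIRATORY = ("OSA", "CSA", "hypopnea")

_KIND_TO_ETIOLOGY = {"OSA": "OSA", "CSA": "CSA", "hypopnea": "Hypopnea", "PLM": "PLM"}


@dataclass
class AnnotatedArousal:
    event: DetectedArousal
    segments: Optional[SegmentTriplet]
    etiology: str
    stage: Optional[str] = None          # "REM" | "NREM"; None until assigned
    reclassified_from_uod: bool = False
    cause_event: Optional[ScoredEvent] = None
    excluded_reason: Optional[str] = None  # "edge" | "wake" | "insufficient" | "abnormal_rr"

    def __post_init__(self) -> None:
        if self.etiology not in ETIOLOGIES:
            raise ArousalHrvError(f"unknown etiology {self.etiology!r}")
        if self.etiology == "Spontaneous" and self.cause_event is not None:
            raise ArousalHrvError("spontaneous arousal cannot carry a cause event")
        if self.reclassified_from_uod and self.etiology not in ("OSA", "CSA", "Hypopnea"):
            raise ArousalHrvError("UOD reclassification must yield a respiratory etiology")


def _best_candidate(candidates: Sequence[ScoredEvent],
                    kinds: Sequence[str]) -> Optional[ScoredEvent]:
    """Highest-priority candidate; within a priority, the latest-ending one."""
    for kind in kinds:
        of_kind = [ev for ev in candidates if ev.kind == kind]
        if of_kind:
            return max(of_kind, key=lambda ev: ev.end_s)
    return None


def classify_arousal(event: DetectedArousal, scored: Sequence[ScoredEvent],
                     config: AnalysisConfig = DEFAULT_CONFIG
                     ) -> Tuple[str, Optional[ScoredEvent]]:
    """Primary etiology lookback over ``[onset - 10, onset)`` (clipped at 0)."""
    if config.lookback_anchor == "scored" and event.matched_scored:
        onset = min(ev.start_s for ev in event.matched_scored)
    else:
        onset = event.onset_s
    w_lo = max(0.0, onset - config.lookback_s)
    w_hi = onset
    candidates = [ev for ev in scored
                  if ev.kind != "arousal" and ev.overlaps(w_lo, w_hi) > 0]
    cause = _best_candidate(candidates, PRIORITY)
    if cause is not None:
        return _KIND_TO_ETIOLOGY[cause.kind], cause
    desat = _best_candidate(candidates, ("desaturation",))
    if desat is not None:
        return "UOD", desat
    return "Spontaneous", None


def reclassify_uod(arousal: AnnotatedArousal, scored: Sequence[ScoredEvent],
                   config: AnalysisConfig = DEFAULT_CONFIG) -> AnnotatedArousal:
    """Secondary search 10 s before the desaturation onset of a UOD arousal."""
    if arousal.etiology != "UOD":
        return arousal
    desat = arousal.cause_event
    if desat is None or desat.kind != "desaturation":
        raise ArousalHrvError("UOD arousal without an associated desaturation")
    w_lo = max(0.0, desat.start_s - config.lookback_s)
    w_hi = desat.start_s
    candidates = [ev for ev in scored
                  if ev.kind in RESPIRATORY and ev.overlaps(w_lo, w_hi) > 0]
    cause = _best_candidate(candidates, RESPIRATORY)
    if cause is None:
        return arousal
    arousal.etiology = _KIND_TO_ETIOLOGY[cause.kind]
    arousal.reclassified_from_uod = True
    arousal.cause_event = cause
    return arousal


def assign_stage(event: DetectedArousal, hypnogram: Hypnogram) -> str:
    """Stage of the 30-s epoch containing the arousal onset.

    Returns "REM" or "NREM"; a Wake-epoch onset returns "Wake" so the caller
    can exclude the event from stage-stratified analyses.
    """
    stage = hypnogram.stage_at(event.onset_s)
    if stage == "REM":
        return "REM"
    if stage == "Wake":
        return "Wake"
    return "NREM"


def annotate_arousal(event: DetectedArousal, segments: Optional[SegmentTriplet],
                     scored: Sequence[ScoredEvent], hypnogram: Optional[Hypnogram],
                     config: AnalysisConfig = DEFAULT_CONFIG) -> AnnotatedArousal:
    """Full per-event annotation: etiology (with UOD reclassification) + stage."""
    etiology, cause = classify_arousal(event, scored, config)
    ann = AnnotatedArousal(event=event, segments=segments, etiology=etiology,
                           cause_event=cause)
    if etiology == "UOD":
        ann = reclassify_uod(ann, scored, config)
    if hypnogram is not None:
        stage = assign_stage(event, hypnogram)
        if stage == "Wake":
            ann.excluded_reason = "wake"
        else:
            ann.stage = stage
    if segments is None:
        ann.excluded_reason = "edge"
    return ann


def tabulate_etiologies(arousals: Sequence[AnnotatedArousal],
                        genders: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Counts per etiology, with stage and (optionally) gender breakdowns.

    Also reports the fraction of UOD-classified arousals that the secondary
    search reclassified, in the DataFrame ``attrs``.
    """
    rows = []
    for i, ann in enumerate(arousals):
        rows.append({
            "etiology": ann.etiology,
            "stage": ann.stage or "unassigned",
            "gender": genders[i] if genders is not None else "all",
            "reclassified": ann.reclassified_from_uod,
        })
    counts = pd.DataFrame(
        0, index=list(ETIOLOGIES),
        columns=["total", "REM", "NREM", "reclassified_from_uod"],
    )
    if rows:
        df = pd.DataFrame(rows)
        for et, grp in df.groupby("etiology"):
            counts.loc[et, "total"] = len(grp)
            counts.loc[et, "REM"] = int((grp["stage"] == "REM").sum())
            counts.loc[et, "NREM"] = int((grp["stage"] == "NREM").sum())
            counts.loc[et, "reclassified_from_uod"] = int(grp["reclassified"].sum())
        if genders is not None:
            for g in sorted(df["gender"].unique()):
                counts[f"gender_{g}"] = [
                    int(((df["etiology"] == et) & (df["gender"] == g)).sum())
                    for et in counts.index
                ]
        n_uod_origin = int(df["reclassified"].sum() + (df["etiology"] == "UOD").sum())
        counts.attrs["uod_reclassified_fraction"] = (
            float(df["reclassified"].sum()) / n_uod_origin if n_uod_origin else 0.0
        )
    else:
        counts.attrs["uod_reclassified_fraction"] = 0.0
    counts.index.name = "etiology"
    assert int(counts["total"].sum()) == len(arousals)
    return counts
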