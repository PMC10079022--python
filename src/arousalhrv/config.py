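"""Analysis configuration.

Every tunable the pipeline exposes lives here with its default.  Defaults
follow the published analysis design: strict > 3 s arousal duration, > 11 s
inter-event gap (merged), 25-s segments centred on the peak-probability
second, a 10-s etiology lookback, the 400-2000 ms normal-RR band, and a
Bonferroni multiplier of 200.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class PanTompkinsConfig:
    """Free parameters of the QRS detector (the 1985 design)."""

    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    filter_order: int = 3
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    #: how far the fiducial mark may be moved to the local ECG maximum
    refine_window_s: float = 0.050
    #: signal/noise running-estimate update coefficient
    peak_update: float = 0.125
    #: search-back trigger, as a multiple of the running average RR
    searchback_factor: float = 1.66


@dataclass
class AnalysisConfig:
    # --- arousal event definition -------------------------------------
    threshold: Optional[float] = None      # None => select from ROC
    min_event_duration_s: float = 3.0      # strict >
    merge_gap_s: float = 11.0              # strict >  (gap <= 11 s merges)
    gap_rule: str = "merge"                # "merge" | "drop"
    min_match_overlap_s: float = 1.0       # detected vs scored arousal
    segment_len_s: float = 25.0
    #: intra window is [peak - intra_pre_s, peak + (segment_len - intra_pre_s))
    intra_pre_s: float = 12.0

    # --- etiology ------------------------------------------------------
    lookback_s: float = 10.0
    #: anchor the lookback at the detected event onset ("detected") or at
    #: the matched scored arousal onset ("scored")
    lookback_anchor: str = "detected"

    # --- RR / HRV ------------------------------------------------------
    rr_min_ms: float = 400.0               # strict <
    rr_max_ms: float = 2000.0              # strict >
    min_peaks_per_segment: int = 3
    #: RMSSD denominator: "diffs" (number of successive differences,
    #: matches the worked examples) or "intervals" (number of RR intervals)
    rmssd_denominator: str = "diffs"

    # --- statistics ----------------------------------------------------
    independent_test: str = "welch"        # "welch" | "student"
    bonferroni_multiplier: int = 200
    alpha: float = 0.05

    pan_tompkins: PanTompkinsConfig = field(default_factory=PanTompkinsConfig)

    def __post_init__(self) -> None:
        if self.gap_rule not in ("merge", "drop"):
            raise ValueError(f"gap_rule must be 'merge' or 'drop', got {self.gap_rule!r}")
        if self.rmssd_denominator not in ("diffs", "intervals"):
            raise ValueError("rmssd_denominator must be 'diffs' or 'intervals'")
        if self.independent_test not in ("welch", "student"):
            raise ValueError("independent_test must be 'welch' or 'student'")
        if self.threshold is not None and not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pt = PanTompkinsConfig(**raw.pop("pan_tompkins", {}))
        return cls(pan_tompkins=pt, **raw)


DEFAULT_CONFIG = AnalysisConfig()
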