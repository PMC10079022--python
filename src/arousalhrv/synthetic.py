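"""Synthetic sleep recordings with known ground truth.

The generator works RR-first: heart-rate truth is defined on the RR series
(a Gaussian baseline with a programmable intra-arousal rate surge and
variability elevation), and the ECG waveform is synthesised afterwards from
stereotyped beat templates purely to exercise the QRS detector.  Arousals
are spaced > 61 s apart so the 25-s segment triplets of consecutive events
never interact.  Precursor events (apneas, hypopneas, limb movements,
desaturations) are placed overlapping the 10-s lookback window of their
arousal so etiology classification has an exact ground truth; a
configurable fraction of desaturation-only (UOD) arousals additionally get
a respiratory event in the secondary window, making them reclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ScenarioError, ValidationError
from .io_formats import EcgRecord, Hypnogram, ProbSeries, ScoredEvent
from .qrs_hrv import RrSeries

#: etiology label -> scored-event kind of its precursor
_PRECURSOR_KIND = {"OSA": "OSA", "CSA": "CSA", "Hypopnea": "hypopnea", "PLM": "PLM"}

DEFAULT_ETIOLOGY_MIX = {
    # roughly proportional to the published etiology distribution
    "OSA": 3, "CSA": 1, "Hypopnea": 5, "PLM": 1, "UOD": 7, "Spontaneous": 6,
}


@dataclass
class Scenario:
    """Parameters of one synthetic recording."""

    duration_s: float = 2400.0
    base_hr_bpm: float = 60.0
    hr_surge_bpm: float = 8.0
    sdnn_base_ms: float = 50.0
    sdnn_surge_ms: float = 70.0
    surge_onset_lag_s: float = 0.0
    surge_decay_s: float = 15.0
    n_arousals_by_etiology: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ETIOLOGY_MIX))
    rem_fraction: float = 0.2
    prob_noise_sd: float = 0.05
    abnormal_rr_rate: float = 0.0
    seed: int = 0
    #: fraction of UOD arousals whose desaturation has a scored respiratory
    #: cause in the secondary window (most published UODs stayed UOD)
    uod_reclassifiable_fraction: float = 0.15
    #: probability of adding a lower-priority decoy event to an OSA/CSA window
    decoy_rate: float = 0.0
    #: mean / SD of the arousal duration distribution (s), clipped to [4, 20]
    arousal_duration_mean_s: float = 9.08
    arousal_duration_sd_s: float = 5.95

    def __post_init__(self) -> None:
        for name in ("duration_s", "base_hr_bpm", "sdnn_base_ms",
                     "sdnn_surge_ms", "surge_decay_s"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be positive")
        if not (0.0 <= self.rem_fraction <= 1.0):
            raise ScenarioError("rem_fraction must lie in [0, 1]")
        if self.hr_surge_bpm < 0 or self.surge_onset_lag_s < 0:
            raise ScenarioError("surge parameters must be non-negative")
        for hr in (self.base_hr_bpm, self.base_hr_bpm + self.hr_surge_bpm):
            rr = 60000.0 / hr
            if not (200.0 < rr < 3000.0):
                raise ScenarioError(
                    f"heart rate {hr} bpm implies RR {rr:.0f} ms outside (200, 3000)")
        unknown = set(self.n_arousals_by_etiology) - set(DEFAULT_ETIOLOGY_MIX)
        if unknown:
            raise ScenarioError(f"unknown etiologies {sorted(unknown)}")

    @property
    def n_arousals(self) -> int:
        return sum(self.n_arousals_by_etiology.values())

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class TrueArousal:
    onset_s: int
    duration_s: int
    etiology: str
    stage: Optional[str] = None
    reclassifiable: bool = False
    has_decoy: bool = False


@dataclass
class GroundTruth:
    r_peak_times_s: np.ndarray
    arousal_records: List[TrueArousal]
    precursor_events: List[ScoredEvent]


@dataclass
class SyntheticRecording:
    scenario: Scenario
    rr: RrSeries
    prob: ProbSeries
    events: List[ScoredEvent]          # scored arousals + precursors
    hypnogram: Hypnogram
    truth: GroundTruth
    ecg: Optional[EcgRecord] = None
    gender: Optional[str] = None


# ---------------------------------------------------------------------------
# Arousal placement and precursors
# ---------------------------------------------------------------------------

def place_arousals(scenario: Scenario, rng: np.random.Generator) -> List[TrueArousal]:
    """Integer-second onsets with > 61 s spacing; etiologies shuffled."""
    n = scenario.n_arousals
    if n == 0:
        return []
    step = int((scenario.duration_s - 220.0) // n)
    if step < 64:
        raise ScenarioError(
            f"{n} arousals do not fit in {scenario.duration_s:.0f} s "
            "with > 61 s spacing")
    etis = [et for et, k in sorted(scenario.n_arousals_by_etiology.items())
            for _ in range(k)]
    etis = [etis[i] for i in rng.permutation(n)]
    records = []
    for i, et in enumerate(etis):
        onset = int(100 + i * step + rng.integers(0, step - 62))
        dur = int(np.clip(round(rng.normal(scenario.arousal_duration_mean_s,
                                           scenario.arousal_duration_sd_s)), 4, 20))
        records.append(TrueArousal(onset_s=onset, duration_s=dur, etiology=et))
    return records


def _place_precursors(scenario: Scenario, records: Sequence[TrueArousal],
                      rng: np.random.Generator) -> List[ScoredEvent]:
    """Precursor events overlapping each arousal's [onset-10, onset) window."""
    events: List[ScoredEvent] = []
    for rec in records:
        onset = rec.onset_s
        if rec.etiology in _PRECURSOR_KIND:
            kind = _PRECURSOR_KIND[rec.etiology]
            dur = int(rng.integers(2, 6)) if kind == "PLM" else int(rng.integers(10, 26))
            end = onset - int(rng.integers(1, 9))       # end in [onset-8, onset-1]
            events.append(ScoredEvent(kind, max(0.0, end - dur), min(dur, end)))
            if rec.etiology in ("OSA", "CSA") and rng.random() < scenario.decoy_rate:
                # lower-priority decoy sharing the window
                d_end = onset - int(rng.integers(1, 9))
                events.append(ScoredEvent("hypopnea", max(0.0, d_end - 12),
                                          min(12, d_end)))
                rec.has_decoy = True
        elif rec.etiology == "UOD":
            d = int(rng.integers(1, 6))
            desat_onset = onset - d                      # starts inside the window
            desat_dur = int(rng.integers(15, 31))
            desat_pct = float(np.round(rng.uniform(3.0, 6.0), 1))
            events.append(ScoredEvent("desaturation", desat_onset, desat_dur,
                                      desat_pct))
            if rng.random() < scenario.uod_reclassifiable_fraction:
                # respiratory cause inside [desat_onset-10, desat_onset) but
                # clear of the primary window [onset-10, onset)
                resp_end = onset - 10 - int(rng.integers(0, d))
                resp_dur = int(rng.integers(10, 21))
                kind = str(rng.choice(["OSA", "CSA", "hypopnea"]))
                events.append(ScoredEvent(kind, max(0.0, resp_end - resp_dur),
                                          min(resp_dur, resp_end)))
                rec.reclassifiable = True
        # Spontaneous: nothing within the lookback window
    return events


def generate_hypnogram(scenario: Scenario, rng: np.random.Generator) -> Hypnogram:
    n = int(np.ceil(scenario.duration_s / 30.0))
    n_rem = int(round(scenario.rem_fraction * n))
    stages = np.array(
        rng.choice(["N1", "N2", "N3"], size=n, p=[0.15, 0.60, 0.25]), dtype=object)
    rem_idx = rng.choice(n, size=n_rem, replace=False)
    stages[rem_idx] = "REM"
    return Hypnogram(list(stages))


def generate_precursors_and_hypnogram(
        scenario: Scenario, rng: Optional[np.random.Generator] = None
) -> Tuple[List[ScoredEvent], Hypnogram, List[TrueArousal]]:
    """Place arousals, their precursor events, and the hypnogram.

    Returns ``(precursor_events, hypnogram, arousal_records)`` with each
    record's stage filled in from the hypnogram epoch of its onset.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    records = place_arousals(scenario, rng)
    events = _place_precursors(scenario, records, rng)
    hyp = generate_hypnogram(scenario, rng)
    for rec in records:
        st = hyp.stage_at(rec.onset_s)
        rec.stage = "REM" if st == "REM" else ("Wake" if st == "Wake" else "NREM")
    return events, hyp, records


# ---------------------------------------------------------------------------
# RR series and ECG
# ---------------------------------------------------------------------------

def generate_rr_series(scenario: Scenario, arousal_records: Sequence[TrueArousal],
                       rng: Optional[np.random.Generator] = None) -> RrSeries:
    """Gaussian RR baseline with an intra-arousal surge.

    Within ``[onset + lag, onset + lag + decay)`` of each arousal the mean RR
    shortens to ``60000 / (base_hr + hr_surge)`` and the SD becomes
    ``sdnn_surge_ms``; elsewhere mean ``60000 / base_hr``, SD ``sdnn_base_ms``.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    base_rr = 60000.0 / scenario.base_hr_bpm
    surge_rr = 60000.0 / (scenario.base_hr_bpm + scenario.hr_surge_bpm)
    starts = np.array(sorted(r.onset_s + scenario.surge_onset_lag_s
                             for r in arousal_records))
    ends = starts + scenario.surge_decay_s
    times = [0.3]
    rrs = []
    t = 0.3
    while True:
        i = np.searchsorted(starts, t, side="right") - 1
        in_surge = i >= 0 and t < ends[i]
        mean = surge_rr if in_surge else base_rr
        sd = scenario.sdnn_surge_ms if in_surge else scenario.sdnn_base_ms
        rr = rng.normal(mean, sd)
        if scenario.abnormal_rr_rate > 0 and rng.random() < scenario.abnormal_rr_rate:
            rr = float(rng.choice([300.0, 2200.0]))
        rr = max(rr, 250.0)
        t += rr / 1000.0
        if t >= scenario.duration_s:
            break
        times.append(t)
        rrs.append(rr)
    return RrSeries(np.asarray(times), np.asarray(rrs))


def synthesize_ecg(rr: RrSeries, fs: float, noise_sd: float = 0.0,
                   rng: Optional[np.random.Generator] = None,
                   duration_s: Optional[float] = None) -> EcgRecord:
    """Stereotyped-beat ECG with R waves at the RR series' peak times.

    Each beat is an analytic template: a narrow unit-amplitude Gaussian R
    wave with smaller P and T deflections; ``noise_sd`` (mV, i.e. a
    fraction of the R amplitude) adds white noise.  Not a physiological
    PQRST model — its sole purpose is exercising the QRS detector.
    """
    if fs < 100:
        raise ValidationError("fs must be >= 100 Hz")
    if duration_s is None:
        duration_s = float(np.ceil(rr.peak_times_s[-1] + 1.0))
    n = int(round(fs * duration_s))
    sig = np.zeros(n)
    components = (
        (1.00, 0.000, 0.012),   # R
        (0.15, -0.200, 0.030),  # P
        (0.25, 0.300, 0.060),   # T
    )
    for amp, offset, sigma in components:
        half = int(np.ceil(4 * sigma * fs))
        rel = np.arange(-half, half + 1)
        for tc in rr.peak_times_s + offset:
            c = int(round(tc * fs))
            idx = c + rel
            ok = (idx >= 0) & (idx < n)
            sig[idx[ok]] += amp * np.exp(-((idx[ok] / fs - tc) ** 2)
                                         / (2 * sigma ** 2))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sig = sig + rng.normal(0.0, noise_sd, n)
    return EcgRecord(fs=fs, samples=sig, duration_s=n / fs)


# ---------------------------------------------------------------------------
# Probability trace
# ---------------------------------------------------------------------------

def generate_prob_series(arousal_records: Sequence[TrueArousal], duration_s: float,
                         prob_noise_sd: float = 0.0,
                         rng: Optional[np.random.Generator] = None,
                         seed: Optional[int] = None) -> ProbSeries:
    """Per-second scores: low plateau 0.05, high plateau 0.8 inside arousals,
    a unique 0.95 maximum second per arousal, truncated Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    n = int(np.ceil(duration_s))
    values = np.full(n, 0.05)
    for rec in arousal_records:
        o, d = rec.onset_s, rec.duration_s
        if o + d > n:
            raise ValidationError("arousal extends beyond the recording")
        values[o:o + d] = 0.8
        values[o + d // 2] = 0.95
    if prob_noise_sd > 0:
        values = values + rng.normal(0.0, prob_noise_sd, n)
    return ProbSeries(np.clip(values, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Full recording / cohort
# ---------------------------------------------------------------------------

def generate_recording(scenario: Scenario, with_ecg: bool = False,
                       fs: float = 256.0, ecg_noise_sd: float = 0.1,
                       gender: Optional[str] = None) -> SyntheticRecording:
    """Deterministic full recording: same scenario + seed, same bits out."""
    rng = np.random.default_rng(scenario.seed)
    precursors, hyp, records = generate_precursors_and_hypnogram(scenario, rng)
    rr = generate_rr_series(scenario, records, rng)
    prob = generate_prob_series(records, scenario.duration_s,
                                scenario.prob_noise_sd, rng)
    scored = [ScoredEvent("arousal", float(r.onset_s), float(r.duration_s))
              for r in records] + precursors
    scored.sort(key=lambda ev: (ev.start_s, ev.kind))
    ecg = None
    if with_ecg:
        ecg = synthesize_ecg(rr, fs, noise_sd=ecg_noise_sd, rng=rng,
                             duration_s=scenario.duration_s)
    truth = GroundTruth(r_peak_times_s=rr.peak_times_s.copy(),
                        arousal_records=records, precursor_events=precursors)
    return SyntheticRecording(scenario=scenario, rr=rr, prob=prob, events=scored,
                              hypnogram=hyp, truth=truth, ecg=ecg, gender=gender)


def generate_cohort(base_scenario: Scenario, n_recordings: int, seed: int,
                    with_ecg: bool = False) -> List[SyntheticRecording]:
    """Cohort of recordings with alternating genders and derived seeds."""
    children = np.random.SeedSequence(seed).spawn(n_recordings)
    out = []
    for i, ss in enumerate(children):
        sc = Scenario(**{**base_scenario.to_dict(),
                         "seed": int(ss.generate_state(1)[0] % (2 ** 31))})
        out.append(generate_recording(sc, with_ecg=with_ecg,
                                      gender="male" if i % 2 == 0 else "female"))
    return out


def estimate_hr_surge(events, scenario: Scenario, segment_len_s: float = 25.0,
                      intra_pre_s: float = 12.0) -> float:
    """Recover the programmed intra-arousal HR surge from pipeline output.

    The intra window only partly overlaps the surge interval
    ``[onset + lag, onset + lag + decay)``, so the raw intra-minus-pre HR
    difference understates the surge.  This estimator inverts the mixture:
    with ``T_s`` seconds of surge inside the 25-s window, the window holds
    ``T_s / RR_s + (25 - T_s) / RR_b`` beats, which given the measured intra
    and pre mean RR solves for the surge RR per event.  Returns the mean
    surge estimate (bpm) over events with >= 1 s of surge overlap.
    """
    lag, decay = scenario.surge_onset_lag_s, scenario.surge_decay_s
    estimates = []
    for _, row in events.iterrows():
        if not (np.isfinite(row.get("hr_bpm_intra", np.nan))
                and np.isfinite(row.get("hr_bpm_pre", np.nan))):
            continue
        i0 = row["peak_time_s"] - intra_pre_s
        i1 = i0 + segment_len_s
        s0 = row["onset_s"] + lag
        s1 = s0 + decay
        t_surge = max(0.0, min(i1, s1) - max(i0, s0))
        if t_surge < 1.0:
            continue
        rr_intra = 60000.0 / row["hr_bpm_intra"]
        rr_base = 60000.0 / row["hr_bpm_pre"]
        n_intervals = segment_len_s * 1000.0 / rr_intra
        n_base = (segment_len_s - t_surge) * 1000.0 / rr_base
        n_surge = n_intervals - n_base
        if n_surge <= 0:
            continue
        rr_surge = t_surge * 1000.0 / n_surge
        estimates.append(60000.0 / rr_surge - 60000.0 / rr_base)
    if not estimates:
        raise ValidationError("no events with surge overlap; cannot estimate")
    return float(np.mean(estimates))


def null_scenario(**overrides) -> Scenario:
    """Scenario with no intra-arousal autonomic response (type-I testing)."""
    params = dict(hr_surge_bpm=0.0)
    params["sdnn_surge_ms"] = overrides.pop("sdnn_base_ms", 50.0)
    params["sdnn_base_ms"] = params["sdnn_surge_ms"]
    params.update(overrides)
    return Scenario(**params)
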