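"""Domain types and file I/O.

All downstream modules consume only the types defined here.  Conventions,
applied uniformly: times are seconds from recording start, 0-based;
intervals are half-open ``[start, start + duration)``.

Supported formats
-----------------
ECG          EDF (read via :mod:`mne`; written by a minimal built-in
             single-channel writer) or a CSV fallback with ``# fs=<Hz>``
             and ``# channel=<label>`` header comments and columns
             ``time_s,mv``.
Probability  CSV, one score per second, one value per line (optional
             non-numeric header line).
Annotations  NSRR-profile XML (``ScoredEvent`` elements with
             ``EventConcept``/``Name``, ``Start``, ``Duration``) or a CSV
             dialect ``kind,start_s,duration_s,desat_pct`` where stage
             rows use ``stage,<epoch start>,30,<label>``.
Hypnogram    CSV ``epoch_index,stage``.
Results      TSV, one row per stratified comparison.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .errors import ChannelNotFoundError, FormatError, ValidationError

logger = logging.getLogger(__name__)

EVENT_KINDS = ("arousal", "OSA", "CSA", "hypopnea", "PLM", "desaturation")
STAGES = ("Wake", "N1", "N2", "N3", "REM")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EcgRecord:
    """Sampled single-channel ECG voltage (mV)."""

    fs: float
    samples: np.ndarray
    duration_s: float
    channel_label: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        expect = round(self.fs * self.duration_s)
        if len(self.samples) != expect:
            raise ValidationError(
                f"sample count {len(self.samples)} != fs*duration = {expect}"
            )


@dataclass
class ProbSeries:
    """Per-second arousal-probability scores, aligned to the recording."""

    values: np.ndarray
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        bad = np.where((self.values < 0) | (self.values > 1))[0]
        if bad.size:
            raise ValidationError(
                f"probability out of [0, 1] at row {bad[0]}: {self.values[bad[0]]}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def second_start(self, i: int) -> float:
        """Start time of the i-th scored second."""
        return self.start_offset_s + float(i)


@dataclass
class ScoredEvent:
    """A scored polysomnography event."""

    kind: str
    start_s: float
    duration_s: float
    desat_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValidationError("event duration must be positive")
        if self.start_s < 0:
            raise ValidationError("event start must be >= 0")
        if self.desat_pct is not None and self.kind != "desaturation":
            raise ValidationError("desat_pct only valid for desaturation events")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def overlaps(self, start: float, end: float) -> float:
        """Overlap length (s) with the half-open window [start, end)."""
        return max(0.0, min(self.end_s, end) - max(self.start_s, start))


@dataclass
class Hypnogram:
    """Per-epoch sleep stages at a fixed 30-s epoch length."""

    stages: list
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_len_s != 30.0:
            raise ValidationError("epoch length must be 30 s")
        if not self.stages:
            raise ValidationError("hypnogram must contain at least one epoch")
        for s in self.stages:
            if s not in STAGES:
                raise ValidationError(f"unknown sleep stage {s!r}")

    def stage_at(self, t_s: float) -> str:
        idx = int(t_s // self.epoch_len_s)
        if t_s < 0 or idx >= len(self.stages):
            from .errors import CoverageError
            raise CoverageError(f"time {t_s} s outside hypnogram span")
        return self.stages[idx]

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_len_s


# ---------------------------------------------------------------------------
# Annotation name mapping (case-insensitive, config-extensible)
# ---------------------------------------------------------------------------

#: Default mapping from annotation concept strings to the six event kinds.
#: Keys are compared lower-cased against the full concept string and against
#: the part before the first "|".  Extend via the ``extra_names`` argument of
#: :func:`read_annotations`.
DEFAULT_EVENT_NAMES = {
    "arousal": "arousal",
    "arousal ()": "arousal",
    "arousal|arousal ()": "arousal",
    "spontaneous arousal": "arousal",
    "osa": "OSA",
    "obstructive apnea": "OSA",
    "obstructive apnea|obstructive apnea": "OSA",
    "csa": "CSA",
    "central apnea": "CSA",
    "central apnea|central apnea": "CSA",
    "hypopnea": "hypopnea",
    "hypopnea|hypopnea": "hypopnea",
    "plm": "PLM",
    "periodic leg movement": "PLM",
    "limb movement": "PLM",
    "limb movement (left)": "PLM",
    "limb movement (right)": "PLM",
    "desaturation": "desaturation",
    "spo2 desaturation": "desaturation",
    "spo2 desaturation|spo2 desaturation": "desaturation",
}

DEFAULT_STAGE_NAMES = {
    "wake": "Wake", "wake|0": "Wake", "w": "Wake",
    "stage 1 sleep": "N1", "stage 1 sleep|1": "N1", "n1": "N1",
    "stage 2 sleep": "N2", "stage 2 sleep|2": "N2", "n2": "N2",
    "stage 3 sleep": "N3", "stage 3 sleep|3": "N3", "n3": "N3",
    "stage 4 sleep": "N3", "stage 4 sleep|4": "N3",
    "rem sleep": "REM", "rem sleep|5": "REM", "rem": "REM",
}


def _map_name(name: str, table: dict) -> Optional[str]:
    low = name.strip().lower()
    if low in table:
        return table[low]
    head = low.split("|", 1)[0].strip()
    return table.get(head)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def read_ecg(path, channel: Optional[str] = None) -> EcgRecord:
    """Read a single ECG channel from EDF or from the CSV fallback.

    For EDF the named channel must be present (``channel=None`` takes the
    first channel).  The CSV dialect carries ``# fs=`` and optionally
    ``# channel=`` comment lines followed by ``time_s,mv`` rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_ecg_edf(path, channel)
    return _read_ecg_csv(path, channel)


def _read_ecg_edf(path: Path, channel: Optional[str]) -> EcgRecord:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of types on bad headers
        raise FormatError(f"cannot read EDF header of {path}: {exc}") from exc
    names = raw.ch_names
    if channel is None:
        channel = names[0]
    if channel not in names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name} (has {names})"
        )
    data = raw.get_data(picks=[channel])[0]
    fs = float(raw.info["sfreq"])
    # mne rescales EDF physical units to SI (V); our writer stores mV
    return EcgRecord(fs=fs, samples=data * 1e3, duration_s=len(data) / fs,
                     channel_label=channel)


def _read_ecg_csv(path: Path, channel: Optional[str]) -> EcgRecord:
    fs = None
    label = "ECG"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("fs="):
                    fs = float(body.split("=", 1)[1])
                elif body.lower().startswith("channel="):
                    label = body.split("=", 1)[1].strip()
                continue
            if line.lower().startswith("time"):
                continue
            parts = line.split(",")
            rows.append(float(parts[1]))
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=<Hz>' header comment")
    if channel is not None and channel != label:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name} (file has {label!r})"
        )
    samples = np.asarray(rows)
    return EcgRecord(fs=fs, samples=samples, duration_s=len(samples) / fs,
                     channel_label=label)


def write_ecg(record: EcgRecord, path) -> None:
    """Write an ECG record; format chosen by suffix (.edf or .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_ecg_edf(record, path)
    else:
        _write_ecg_csv(record, path)


def _write_ecg_csv(record: EcgRecord, path: Path) -> None:
    t = np.arange(len(record.samples)) / record.fs
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n# channel={record.channel_label}\n")
        fh.write("time_s,mv\n")
        for ti, vi in zip(t, record.samples):
            fh.write(f"{ti:.6f},{vi:.9g}\n")


def _write_ecg_edf(record: EcgRecord, path: Path) -> None:
    """Minimal single-channel EDF writer (1-s data records, 16-bit).

    The sampling rate must be an integer and the recording an integer
    number of seconds; samples are quantized to the 16-bit digital range,
    so one write/read cycle is idempotent but not float-exact.
    """
    fs = int(round(record.fs))
    if fs != record.fs:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(len(record.samples) / fs))
    x = np.zeros(n_rec * fs)
    x[: len(record.samples)] = record.samples
    amp = float(np.max(np.abs(x))) or 1.0
    phys_min, phys_max = -amp, amp
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((x - phys_min) / scale + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),                         # version
        pad("X X X X", 80),                  # patient id (anonymous)
        pad("Startdate X X X X", 80),        # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 + 256), 8),              # header bytes (1 signal)
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),                         # record duration (s)
        pad("1", 4),                         # number of signals
    ])
    sig = b"".join([
        pad(record.channel_label, 16),
        pad("", 80),                         # transducer
        pad("mV", 8),
        pad(f"{phys_min:.6g}", 8), pad(f"{phys_max:.6g}", 8),
        pad(str(dig_min), 8), pad(str(dig_max), 8),
        pad("", 80),                         # prefiltering
        pad(str(fs), 8),
        pad("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# Probability series
# ---------------------------------------------------------------------------

def read_prob_series(path) -> ProbSeries:
    """Read a 1 Hz probability series (one value per line, header optional).

    Out-of-range values are rejected with the offending row index, never
    clipped.
    """
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line.split(",")[0])
            except ValueError:
                if not values and lineno == 0:
                    continue  # header row
                raise FormatError(f"{path}: non-numeric value at line {lineno}")
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"{path}: probability out of [0, 1] at row {len(values)}: {v}"
                )
            values.append(v)
    return ProbSeries(np.asarray(values))


def write_prob_series(series: ProbSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("prob\n")
        for v in series.values:
            fh.write(f"{v:.6f}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path, extra_names: Optional[dict] = None):
    """Read scored events and (if present) sleep stages.

    Returns ``(events, hypnogram)``; ``hypnogram`` is ``None`` when the file
    carries no stage information.  Event names are resolved through a
    case-insensitive table; unmapped names are logged and skipped.
    """
    path = Path(path)
    table = dict(DEFAULT_EVENT_NAMES)
    if extra_names:
        table.update({k.lower(): v for k, v in extra_names.items()})
    if path.suffix.lower() == ".xml":
        return _read_annotations_xml(path, table)
    return _read_annotations_csv(path, table)


def _read_annotations_xml(path: Path, table: dict):
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed annotation XML {path}: {exc}") from exc
    events = []
    stage_spans = []  # (start, duration, stage)
    for el in tree.iter("ScoredEvent"):
        concept = el.findtext("EventConcept") or el.findtext("Name") or ""
        start = float(el.findtext("Start") or 0.0)
        duration = float(el.findtext("Duration") or 0.0)
        stage = _map_name(concept, DEFAULT_STAGE_NAMES)
        if stage is not None:
            stage_spans.append((start, duration, stage))
            continue
        kind = _map_name(concept, table)
        if kind is None:
            logger.warning("skipping unmapped event name %r in %s", concept, path.name)
            continue
        if duration <= 0:
            raise ValidationError(f"{path}: non-positive duration for {concept!r}")
        desat = None
        if kind == "desaturation":
            txt = el.findtext("Desaturation")
            desat = float(txt) if txt else None
        events.append(ScoredEvent(kind, start, duration, desat))
    hyp = _spans_to_hypnogram(stage_spans) if stage_spans else None
    return events, hyp


def _read_annotations_csv(path: Path, table: dict):
    events = []
    stage_spans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("kind,"):
                continue
            parts = [p.strip() for p in line.split(",")]
            name = parts[0]
            if name.lower() == "stage":
                stage = _map_name(parts[3], DEFAULT_STAGE_NAMES)
                if stage is None:
                    raise ValidationError(f"{path}:{lineno}: unknown stage {parts[3]!r}")
                stage_spans.append((float(parts[1]), float(parts[2]), stage))
                continue
            kind = _map_name(name, table)
            if kind is None:
                logger.warning("skipping unmapped event name %r in %s", name, path.name)
                continue
            start, duration = float(parts[1]), float(parts[2])
            if duration <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive duration")
            desat = None
            if len(parts) > 3 and parts[3]:
                desat = float(parts[3])
            events.append(ScoredEvent(kind, start, duration, desat))
    hyp = _spans_to_hypnogram(stage_spans) if stage_spans else None
    return events, hyp


def _spans_to_hypnogram(spans) -> Hypnogram:
    end = max(s + d for s, d, _ in spans)
    n = int(round(end / 30.0))
    stages = ["Wake"] * n
    for start, duration, stage in spans:
        i0 = int(round(start / 30.0))
        i1 = int(round((start + duration) / 30.0))
        for i in range(i0, min(i1, n)):
            stages[i] = stage
    return Hypnogram(stages)


def write_events_csv(events: Sequence[ScoredEvent], path,
                     hypnogram: Optional[Hypnogram] = None) -> None:
    with open(path, "w") as fh:
        fh.write("kind,start_s,duration_s,desat_pct\n")
        for ev in events:
            desat = "" if ev.desat_pct is None else f"{ev.desat_pct:g}"
            fh.write(f"{ev.kind},{ev.start_s:g},{ev.duration_s:g},{desat}\n")
        if hypnogram is not None:
            for i, st in enumerate(hypnogram.stages):
                fh.write(f"stage,{i * 30:g},30,{st}\n")


def read_hypnogram_csv(path) -> Hypnogram:
    """Read ``epoch_index,stage`` rows into a hypnogram."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("epoch"):
                continue
            idx_s, stage_s = [p.strip() for p in line.split(",")]
            stage = _map_name(stage_s, DEFAULT_STAGE_NAMES)
            if stage is None:
                raise ValidationError(f"{path}: unknown stage {stage_s!r}")
            rows[int(idx_s)] = stage
    if not rows:
        raise ValidationError(f"{path}: empty hypnogram")
    n = max(rows) + 1
    return Hypnogram([rows.get(i, "Wake") for i in range(n)])


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index,stage\n")
        for i, st in enumerate(hyp.stages):
            fh.write(f"{i},{st}\n")


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "stratum", "etiology", "metric", "segment_a", "segment_b", "n",
    "mean_a", "sd_a", "mean_b", "sd_b", "t", "p_raw", "p_adj",
    "cohens_d", "significant",
]


def results_to_dataframe(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "stratum": r.stratum, "etiology": r.etiology, "metric": r.metric,
            "segment_a": r.pair[0], "segment_b": r.pair[1], "n": r.n_a,
            "mean_a": r.mean_a, "sd_a": r.sd_a,
            "mean_b": r.mean_b, "sd_b": r.sd_b,
            "t": r.t_stat, "p_raw": r.p_raw, "p_adj": r.p_adj,
            "cohens_d": r.cohens_d, "significant": r.significant,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_table(results, path) -> None:
    """Write one TSV row per stratified comparison (6 significant digits)."""
    if not list(results):
        raise ValidationError("results list is empty")
    df = results_to_dataframe(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
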