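"""Stratified statistical comparisons of segment HRV.

Design: Shapiro-Wilk normality is reported (advisory — the analysis
proceeds with t-tests either way); paired t-tests compare segment pairs
within an etiology; Welch t-tests compare gender and stage strata; every
raw p-value is Bonferroni-adjusted with a fixed multiplier of 200 and
significance requires adjusted p < 0.05 strictly; Cohen's d accompanies
every test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import DegenerateSampleError, ValidationError

logger = logging.getLogger(__name__)

METRICS = ("SDNN", "RMSSD", "pNN50", "HR")
_METRIC_COLS = {"SDNN": "sdnn_ms", "RMSSD": "rmssd_ms",
                "pNN50": "pnn50_pct", "HR": "hr_bpm"}
SEGMENTS = ("pre", "intra", "post")
PAIRED_PAIRS = (("pre", "intra"), ("intra", "post"), ("pre", "post"))


@dataclass
class ComparisonResult:
    stratum: str
    etiology: str
    metric: str
    pair: Tuple[str, str]
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    p_raw: float
    p_adj: float
    cohens_d: float
    significant: bool
    paired: bool = True


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def check_normality(values) -> Tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (advisory; logged, never gating)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DegenerateSampleError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample; normality undefined")
    stat, p = sstats.shapiro(x)
    return float(stat), float(p)


def paired_t(a, b) -> Tuple[float, float]:
    """Two-sided paired t-test on matched samples.

    All-zero differences (identical samples) return (0.0, 1.0); zero-variance
    differences with a nonzero mean are degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("paired samples must have equal length")
    if len(a) < 2:
        raise DegenerateSampleError("paired t-test needs n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateSampleError("zero-variance nonzero differences")
    res = sstats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def independent_t(a, b, config: AnalysisConfig = DEFAULT_CONFIG) -> Tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateSampleError("independent t-test needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DegenerateSampleError("both groups constant; t undefined")
    res = sstats.ttest_ind(a, b, equal_var=(config.independent_test == "student"))
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_raw: float, multiplier: int = 200) -> float:
    """p_adj = min(1, p_raw * multiplier); significance is p_adj < 0.05 strictly."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValidationError("p-value must lie in [0, 1]")
    if multiplier < 1:
        raise ValidationError("multiplier must be >= 1")
    return min(1.0, p_raw * multiplier)


def cohens_d(a, b, paired: bool) -> float:
    """Paired: mean(diff)/sd(diff).  Independent: mean difference / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        d = a - b
        sd = np.std(d, ddof=1)
        if sd == 0:
            if np.mean(d) == 0:
                return 0.0
            raise DegenerateSampleError("zero-variance differences; d undefined")
        return float(np.mean(d) / sd)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0
        raise DegenerateSampleError("zero pooled SD; d undefined")
    return float((np.mean(a) - np.mean(b)) / pooled)


def percent_change(mean_pre: float, mean_intra: float) -> float:
    """(intra - pre) / pre * 100; rounding is left to display code."""
    if mean_pre <= 0:
        raise ValidationError("baseline mean must be positive")
    return (mean_intra - mean_pre) / mean_pre * 100.0


def funnel_percentage(count: int, total: int) -> float:
    """Share of the original arousal population, in percent."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return count / total * 100.0


# ---------------------------------------------------------------------------
# Table builder
# ---------------------------------------------------------------------------

def _compare(a, b, paired: bool, stratum: str, etiology: str, metric: str,
             pair: Tuple[str, str], config: AnalysisConfig) -> ComparisonResult:
    if paired:
        t, p = paired_t(a, b)
    else:
        t, p = independent_t(a, b, config)
    d = cohens_d(a, b, paired=paired)
    p_adj = bonferroni_adjust(p, config.bonferroni_multiplier)
    return ComparisonResult(
        stratum=stratum, etiology=etiology, metric=metric, pair=pair,
        n_a=len(a), n_b=len(b),
        mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)),
        t_stat=t, p_raw=p, p_adj=p_adj, cohens_d=d,
        significant=p_adj < config.alpha, paired=paired,
    )


def _skipped(stratum, etiology, metric, pair, n_a, n_b, paired) -> ComparisonResult:
    return ComparisonResult(stratum=stratum, etiology=etiology, metric=metric,
                            pair=pair, n_a=n_a, n_b=n_b,
                            mean_a=np.nan, sd_a=np.nan, mean_b=np.nan, sd_b=np.nan,
                            t_stat=np.nan, p_raw=np.nan, p_adj=np.nan,
                            cohens_d=np.nan, significant=False, paired=paired)


def build_comparison_tables(events: pd.DataFrame,
                            config: AnalysisConfig = DEFAULT_CONFIG,
                            strata: Sequence[str] = ("overall", "gender", "stage"),
                            ) -> List[ComparisonResult]:
    """All stratified comparisons from the per-event HRV table.

    ``events`` has one row per analyzed arousal with columns ``etiology``,
    ``stage``, ``gender`` (optional) and ``<metric>_<segment>`` values.
    Paired tests compare segment pairs within an etiology (overall and
    within each gender/stage stratum); Welch tests compare the strata
    against each other per segment.  Strata with fewer than two events
    yield flagged rows with the tests skipped.
    """
    results: List[ComparisonResult] = []
    etiologies = sorted(events["etiology"].unique()) if len(events) else []

    def paired_rows(sub: pd.DataFrame, stratum: str) -> None:
        for et in etiologies:
            grp = sub[sub["etiology"] == et]
            for metric in METRICS:
                col = _METRIC_COLS[metric]
                for seg_a, seg_b in PAIRED_PAIRS:
                    a = grp[f"{col}_{seg_a}"].to_numpy()
                    b = grp[f"{col}_{seg_b}"].to_numpy()
                    if len(a) < 2:
                        results.append(_skipped(stratum, et, metric,
                                                (seg_a, seg_b), len(a), len(b), True))
                        continue
                    try:
                        results.append(_compare(a, b, True, stratum, et, metric,
                                                (seg_a, seg_b), config))
                    except DegenerateSampleError:
                        results.append(_skipped(stratum, et, metric,
                                                (seg_a, seg_b), len(a), len(b), True))

    paired_rows(events, "overall")

    group_levels = {"gender": ("male", "female"), "stage": ("REM", "NREM")}
    for column in strata:
        if column == "overall" or column not in events.columns:
            continue
        lv_a, lv_b = group_levels[column]
        for level in (lv_a, lv_b):
            paired_rows(events[events[column] == level], level)
        # between-stratum independent tests per segment
        for et in etiologies:
            grp = events[events["etiology"] == et]
            for metric in METRICS:
                col = _METRIC_COLS[metric]
                for seg in SEGMENTS:
                    a = grp.loc[grp[column] == lv_a, f"{col}_{seg}"].to_numpy()
                    b = grp.loc[grp[column] == lv_b, f"{col}_{seg}"].to_numpy()
                    pair = (f"{lv_a}_{seg}", f"{lv_b}_{seg}")
                    if len(a) < 2 or len(b) < 2:
                        results.append(_skipped(f"{lv_a}_vs_{lv_b}", et, metric,
                                                pair, len(a), len(b), False))
                        continue
                    try:
                        results.append(_compare(a, b, False, f"{lv_a}_vs_{lv_b}",
                                                et, metric, pair, config))
                    except DegenerateSampleError:
                        results.append(_skipped(f"{lv_a}_vs_{lv_b}", et, metric,
                                                pair, len(a), len(b), False))

    logger.info("built %d comparisons (Bonferroni multiplier %d)",
                len(results), config.bonferroni_multiplier)
    return results


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

def normality_summary(events: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    """Shapiro-Wilk per metric x segment over all analyzed events."""
    out: Dict[str, Dict[str, float]] = {}
    for metric in METRICS:
        col = _METRIC_COLS[metric]
        for seg in SEGMENTS:
            vals = events[f"{col}_{seg}"].dropna().to_numpy()
            key = f"{metric}_{seg}"
            try:
                stat, p = check_normality(vals)
                out[key] = {"W": stat, "p": p, "n": int(len(vals))}
            except DegenerateSampleError:
                out[key] = {"W": float("nan"), "p": float("nan"), "n": int(len(vals))}
    return out


def build_run_report(threshold_choice, funnel: Dict[str, int],
                     normality: Dict, config: AnalysisConfig,
                     n_comparisons: Optional[int] = None) -> dict:
    """JSON-serialisable run report: threshold, event funnel, normality, config."""
    total = funnel.get("scored_arousals", 0) or funnel.get("detected", 0)
    funnel_pct = {}
    if total:
        for key, count in funnel.items():
            funnel_pct[f"{key}_pct"] = funnel_percentage(count, total)
    report = {
        "threshold": None if threshold_choice is None else {
            "threshold": threshold_choice.threshold,
            "tpr": threshold_choice.tpr,
            "fpr": threshold_choice.fpr,
            "score": threshold_choice.score,
        },
        "funnel": dict(funnel),
        "funnel_pct": funnel_pct,
        "normality": normality,
        "n_comparisons": n_comparisons,
        "config": config.to_dict(),
    }
    return report


def write_run_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
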