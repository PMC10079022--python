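"""Statistical routines against closed-form oracles, plus the table builder
on surge and null synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

import arousalhrv as ah
from arousalhrv.config import AnalysisConfig


# ---------------------------------------------------------------------------
# Normality
# ---------------------------------------------------------------------------

def test_normal_draws_mostly_pass():
    rng = np.random.default_rng(0)
    passes = sum(ah.check_normality(rng.normal(0, 1, 500))[1] > 0.05
                 for _ in range(100))
    assert passes >= 90


def test_skewed_draws_fail():
    rng = np.random.default_rng(1)
    fails = sum(ah.check_normality(rng.exponential(1.0, 500))[1] < 0.05
                for _ in range(100))
    assert fails >= 99


def test_constant_sample_degenerate():
    with pytest.raises(ah.DegenerateSampleError):
        ah.check_normality([1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ah.DegenerateSampleError):
        ah.check_normality([1.0, 2.0])


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def test_paired_identical_samples():
    x = [1.0, 2.0, 3.0]
    assert ah.paired_t(x, x) == (0.0, 1.0)


def test_paired_matches_closed_form():
    from scipy import stats as sstats
    rng = np.random.default_rng(2)
    d = rng.normal(1.0, 1.0, 100)
    a = rng.normal(10.0, 2.0, 100)
    b = a - d
    t, p = ah.paired_t(a, b)
    t_exp = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(100))
    p_exp = 2 * sstats.t.sf(abs(t_exp), df=99)
    assert t == pytest.approx(t_exp, rel=1e-9)
    assert p == pytest.approx(p_exp, rel=1e-9)


def test_paired_insufficient_n():
    with pytest.raises(ah.DegenerateSampleError):
        ah.paired_t([1.0], [2.0])


def test_paired_zero_variance_nonzero_mean_degenerate():
    with pytest.raises(ah.DegenerateSampleError):
        ah.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def test_welch_matches_closed_form():
    from scipy import stats as sstats
    rng = np.random.default_rng(3)
    a = rng.normal(0.0, 1.0, 200)
    b = rng.normal(1.0, 1.0, 200)
    t, p = ah.independent_t(a, b)
    va, vb = np.var(a, ddof=1) / 200, np.var(b, ddof=1) / 200
    t_exp = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / 199 + vb ** 2 / 199)
    p_exp = 2 * sstats.t.sf(abs(t_exp), df=df)
    assert t == pytest.approx(t_exp, rel=1e-9)
    assert p == pytest.approx(p_exp, rel=1e-9)


def test_welch_one_group_constant_still_defined():
    rng = np.random.default_rng(4)
    a = np.full(20, 5.0)
    b = rng.normal(6.0, 1.0, 25)
    t, p = ah.independent_t(a, b)
    assert np.isfinite(t) and 0.0 <= p <= 1.0


def test_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = ah.independent_t(x, x.copy())
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Bonferroni, Cohen's d, percent change
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p_raw,expected,significant", [
    (1e-4, 0.02, True),
    (0.01, 1.0, False),         # capped
    (0.00025, 0.05, False),     # exactly 0.05 is NOT significant (strict <)
])
def test_bonferroni(p_raw, expected, significant):
    p_adj = ah.bonferroni_adjust(p_raw, 200)
    assert p_adj == pytest.approx(expected)
    assert (p_adj < 0.05) is significant


def test_bonferroni_monotone_and_capped():
    rng = np.random.default_rng(5)
    for p in rng.random(100):
        p_adj = ah.bonferroni_adjust(float(p), 200)
        assert p_adj >= p and p_adj <= 1.0


def test_cohens_d_paired():
    a = np.array([10.0, 15.0, 20.0, 5.0, 10.0]) + 5.0
    b = np.array([10.0, 15.0, 20.0, 5.0, 10.0])
    d = (a - b)  # constant 5 -> degenerate
    with pytest.raises(ah.DegenerateSampleError):
        ah.cohens_d(a, b, paired=True)
    rng = np.random.default_rng(6)
    diffs = rng.normal(5.0, 5.0, 500)
    base = rng.normal(50.0, 10.0, 500)
    d = ah.cohens_d(base + diffs, base, paired=True)
    assert d == pytest.approx(np.mean(diffs) / np.std(diffs, ddof=1), rel=1e-12)


def test_cohens_d_independent_formula():
    rng = np.random.default_rng(7)
    a, b = rng.normal(0, 1, 40), rng.normal(1, 2, 60)
    d = ah.cohens_d(a, b, paired=False)
    pooled = np.sqrt((39 * np.var(a, ddof=1) + 59 * np.var(b, ddof=1)) / 98)
    assert d == pytest.approx((np.mean(a) - np.mean(b)) / pooled, rel=1e-12)
    assert ah.cohens_d(a, a.copy(), paired=False) == pytest.approx(0.0)


@pytest.mark.parametrize("pre,intra,expected", [
    (17.02, 20.21, 18.74),   # male pNN50, published worked example
    (49.46, 75.09, 51.82),   # REM SDNN
    (58.17, 74.82, 28.62),   # NREM SDNN
    (42.0, 42.0, 0.0),
])
def test_percent_change(pre, intra, expected):
    assert round(ah.percent_change(pre, intra), 2) == expected


def test_percent_change_domain():
    with pytest.raises(ah.ValidationError):
        ah.percent_change(0.0, 10.0)


def test_funnel_percentage_worked_examples():
    assert round(ah.funnel_percentage(106971, 125524), 1) == 85.2
    assert round(ah.funnel_percentage(21037, 125524), 2) == 16.76


# ---------------------------------------------------------------------------
# Table builder
# ---------------------------------------------------------------------------

def _toy_events(n=40, surge=10.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        base = {"etiology": "OSA" if i % 2 else "Spontaneous",
                "stage": "REM" if i % 4 == 0 else "NREM",
                "gender": "male" if (i // 2) % 2 else "female",
                "excluded_reason": None}
        for seg in ("pre", "intra", "post"):
            bump = surge if seg == "intra" else 0.0
            base[f"sdnn_ms_{seg}"] = rng.normal(50 + bump, 5)
            base[f"rmssd_ms_{seg}"] = rng.normal(40 + bump, 5)
            base[f"pnn50_pct_{seg}"] = rng.uniform(5, 25)
            base[f"hr_bpm_{seg}"] = rng.normal(60 + bump / 2, 2)
        rows.append(base)
    return pd.DataFrame(rows)


def test_table_builder_surge_pattern():
    events = _toy_events(n=60, surge=15.0)
    results = ah.build_comparison_tables(events)
    overall = [r for r in results if r.stratum == "overall" and r.metric == "SDNN"]
    for r in overall:
        if r.pair in (("pre", "intra"), ("intra", "post")):
            assert r.significant, r
        if r.pair == ("pre", "post"):
            assert not r.significant, r


def test_table_builder_deterministic():
    events = _toy_events()
    r1 = ah.build_comparison_tables(events)
    r2 = ah.build_comparison_tables(events)
    assert [(a.stratum, a.etiology, a.metric, a.pair, a.t_stat, a.p_adj)
            for a in r1] == \
           [(b.stratum, b.etiology, b.metric, b.pair, b.t_stat, b.p_adj)
            for b in r2]


def test_table_swap_symmetry():
    events = _toy_events()
    results = ah.build_comparison_tables(events)
    ind = next(r for r in results if not r.paired and np.isfinite(r.t_stat)
               and r.stratum == "male_vs_female")
    grp = events[events["etiology"] == ind.etiology]
    col = {"SDNN": "sdnn_ms", "RMSSD": "rmssd_ms",
           "pNN50": "pnn50_pct", "HR": "hr_bpm"}[ind.metric]
    seg = ind.pair[0].rsplit("_", 1)[1]
    a = grp.loc[grp["gender"] == "male", f"{col}_{seg}"]
    b = grp.loc[grp["gender"] == "female", f"{col}_{seg}"]
    t_ab, p_ab = ah.independent_t(a, b)
    t_ba, p_ba = ah.independent_t(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert p_ab == pytest.approx(p_ba)
    assert ah.cohens_d(a, b, paired=False) == pytest.approx(
        -ah.cohens_d(b, a, paired=False))


def test_single_event_etiology_skipped_not_crashed():
    events = _toy_events(n=4)
    events.loc[0, "etiology"] = "CSA"  # singleton stratum
    results = ah.build_comparison_tables(events)
    csa = [r for r in results if r.etiology == "CSA" and r.stratum == "overall"]
    assert csa and all(not r.significant and np.isnan(r.t_stat) for r in csa
                       if r.n_a < 2)


def test_run_report_shape():
    choice = ah.ThresholdChoice(threshold=0.3, tpr=0.95, fpr=0.02)
    funnel = {"scored_arousals": 100, "detected": 98, "matched": 90,
              "analyzed": 85}
    report = ah.build_run_report(choice, funnel, {}, AnalysisConfig())
    assert report["threshold"]["score"] == pytest.approx(0.95 * 0.98)
    assert report["funnel_pct"]["analyzed_pct"] == pytest.approx(85.0)
    assert report["config"]["bonferroni_multiplier"] == 200
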