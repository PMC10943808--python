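"""Normality-gated tests, Fisher exact, EULAR response and association report."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from bcelldyn.clinical_stats import (
    associate_endpoints_with_outcomes,
    compare_timepoints,
    compare_two_groups,
    delta_das28,
    eular_response,
    fisher_exact_2x2,
    normality_gate,
)
from bcelldyn.endpoint_caller import (
    EndpointCall,
    PatientTimeline,
    TimelineVisit,
    classify_patient,
)
from bcelldyn.errors import InsufficientDataError, ParameterError, ValidationError

MONTHS = (0, 1, 3, 6, 12)


def _timeline(das28, pid="P01", ada=None, retreated=False):
    visits = [
        TimelineVisit(
            visit_month=m,
            pct_unmutated=40.0,
            das28=d,
            sample_status="ok",
            retreated=retreated and m == 6,
        )
        for m, d in zip(MONTHS, das28)
    ]
    return PatientTimeline(patient_id=pid, visits=visits, ada_positive_within_12m=ada)


# ---------------------------------------------------------------------------
# delta DAS28


def test_delta_das28_examples():
    tl = _timeline([5.0, 4.0, 4.0, 5.0, 3.8])
    assert delta_das28(tl, 6, 12) == pytest.approx(-1.2)
    assert delta_das28(tl, 0, 1) == pytest.approx(-1.0)
    assert delta_das28(tl, 0, 0) == 0.0


def test_delta_das28_missing_and_unscheduled():
    tl = _timeline([5.0, None, 4.0, 5.0, 3.8])
    assert delta_das28(tl, 0, 1) is None
    with pytest.raises(ParameterError):
        delta_das28(tl, 0, 2)


# ---------------------------------------------------------------------------
# Normality gate


def test_normality_gate_decisions():
    rng = np.random.default_rng(0)
    normal = [rng.normal(size=50) for _ in range(2)]
    assert normality_gate(normal) == "parametric"
    skewed = [rng.exponential(size=50), rng.normal(size=50)]
    assert normality_gate(skewed) == "nonparametric"
    assert normality_gate([rng.normal(size=5), rng.normal(size=50)]) == "nonparametric"
    assert normality_gate([[1.0] * 20, list(rng.normal(size=20))]) == "nonparametric"


def test_normality_gate_parametric_rate_over_seeds():
    # normal samples should pass the gate in the vast majority of seeds
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        hits += normality_gate([rng.normal(size=50), rng.normal(size=50)]) == "parametric"
    assert hits >= 32


# ---------------------------------------------------------------------------
# Two-group comparison


def test_identical_groups_give_null_result():
    # identical normal-looking groups take the t-test path: statistic 0, p 1
    rng = np.random.default_rng(8)
    sample = rng.normal(5, 1, 30).tolist()
    out = compare_two_groups(sample, sample)
    assert out.test_name == "t_unpaired"
    assert out.statistic == pytest.approx(0.0, abs=1e-12)
    assert out.p_value == pytest.approx(1.0)
    # constant groups fall back to the nonparametric branch, still null
    out = compare_two_groups([2.0] * 10, [2.0] * 10)
    assert out.p_value == 1.0


def test_mann_whitney_exact_example():
    out = compare_two_groups([1, 2, 3], [4, 5, 6])
    assert out.test_name == "mann_whitney"
    assert out.p_value == pytest.approx(0.1)
    with pytest.raises(InsufficientDataError):
        compare_two_groups([1.0], [2.0, 3.0])


def _mw_permutation_oracle(a, b):
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        ranks = sps.rankdata(pooled)
        r1 = sum(ranks[i] for i in idx)
        us.append(r1 - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def test_mann_whitney_exact_matches_permutation_enumeration():
    rng = np.random.default_rng(3)
    for n1, n2 in [(3, 3), (4, 5), (6, 6), (8, 7)]:
        a = rng.normal(size=n1).tolist()
        b = (rng.normal(size=n2) + 0.5).tolist()
        ours = compare_two_groups(a, b)
        assert ours.test_name == "mann_whitney"
        assert ours.p_value == pytest.approx(_mw_permutation_oracle(a, b), abs=1e-9)


def test_group_summaries_follow_the_branch():
    rng = np.random.default_rng(1)
    a, b = rng.normal(5, 1, 30), rng.normal(6, 1, 30)
    out = compare_two_groups(a, b)
    if out.test_name == "t_unpaired":
        assert "±" in out.group_summaries[0]
    else:
        assert "(" in out.group_summaries[0]


# ---------------------------------------------------------------------------
# Multi-timepoint comparison


def test_identical_timepoints_give_null_omnibus():
    out = compare_timepoints({0: [2.0, 2.0, 2.0], 1: [2.0] * 3, 3: [2.0] * 3})
    assert out.statistic == 0.0 and out.p_value == 1.0
    with pytest.raises(ParameterError):
        compare_timepoints({0: [1, 2], 1: [1, 2]})


def test_posthoc_adjustment_invariants_and_separated_group_detection():
    rng = np.random.default_rng(7)
    samples = {
        0: rng.normal(0, 1, 30),
        1: rng.normal(0, 1, 30),
        3: rng.normal(3, 1, 30),
    }
    out = compare_timepoints(samples)
    assert out.p_value < 1e-3
    assert out.posthoc is not None and len(out.posthoc) == 3
    for entry in out.posthoc:
        assert entry["adjusted_p"] >= entry["raw_p"] - 1e-15
        assert entry["adjusted_p"] <= 1.0
    sig = {e["pair"] for e in out.posthoc if e["adjusted_p"] <= 0.05}
    assert sig == {(0, 2), (1, 2)}


def test_bonferroni_scaling_of_raw_pvalues():
    rng = np.random.default_rng(11)
    samples = {m: rng.normal(0, 1, 12) for m in (0, 1, 3, 6, 12)}
    out = compare_timepoints(samples)
    m = len(out.posthoc)
    assert m == 10
    for entry in out.posthoc:
        assert entry["adjusted_p"] == pytest.approx(
            min(1.0, entry["raw_p"] * m), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Fisher exact


def fisher_oracle(table, sided):
    """Exhaustive hypergeometric enumeration in exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    if sided == "one":
        if a >= r1 * c1 / n:
            return float(sum(v for k, v in pmf.items() if k >= a))
        return float(sum(v for k, v in pmf.items() if k <= a))
    obs = pmf[a]
    return float(sum(v for v in pmf.values() if v <= obs))


def test_fisher_printed_table_both_sidings():
    table = [[10, 4], [4, 9]]
    assert fisher_exact_2x2(table, "one").p_value == pytest.approx(0.0412, abs=5e-5)
    assert fisher_exact_2x2(table, "two").p_value == pytest.approx(0.0570, abs=5e-5)
    assert fisher_exact_2x2([[1, 0], [0, 1]], "one").p_value == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        fisher_exact_2x2([[0, 0], [1, 1]], "one")


def test_fisher_agrees_with_scipy_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 12, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        ours = fisher_exact_2x2([[a, b], [c, d]], "two").p_value
        ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# EULAR


@pytest.mark.parametrize(
    "baseline,endpoint,expected",
    [
        (5.0, 3.0, "good"),
        (5.0, 4.5, "none"),
        (6.0, 4.4, "moderate"),
        (7.0, 5.5, "moderate"),
        (6.0, 5.2, "none"),
        (3.0, 2.5, "none"),
        (4.5, 3.1, "good"),
    ],
)
def test_eular_grid_cases(baseline, endpoint, expected):
    assert eular_response(baseline, endpoint).category == expected


def test_eular_classification_is_exhaustive_and_consistent():
    for baseline in np.arange(0, 10.01, 0.5):
        for endpoint in np.arange(0, 10.01, 0.5):
            out = eular_response(float(baseline), float(endpoint))
            improvement = baseline - endpoint
            if improvement > 1.2 and endpoint <= 3.2:
                assert out.category == "good"
            elif improvement <= 0.6 or (improvement <= 1.2 and endpoint > 5.1):
                assert out.category == "none"
            else:
                assert out.category == "moderate"
    with pytest.raises(ValidationError):
        eular_response(11.0, 3.0)


# ---------------------------------------------------------------------------
# Association report


def _fabricated_cohort(rng, n_early=9, n_late=14, early_mean=-1.17, late_mean=0.18):
    timelines, calls = [], []
    for i in range(n_early + n_late):
        early = i < n_early
        das28 = [4.3, 4.0, 3.8, 3.5, 0.0]
        step = rng.normal(early_mean if early else late_mean, 0.9)
        das28[4] = float(np.clip(das28[3] + step, 0, 10))
        pid = f"P{i:02d}"
        timelines.append(_timeline(das28, pid=pid, ada=bool(rng.random() < 0.5)))
        call = EndpointCall(
            patient_id=pid,
            depletion_month=1,
            repopulation_month=6 if early else None,
        )
        calls.append(classify_patient(call))
    return timelines, calls


def test_association_report_contains_all_contrasts_and_variants():
    rng = np.random.default_rng(0)
    timelines, calls = _fabricated_cohort(rng)
    report = associate_endpoints_with_outcomes(timelines, calls)
    names = {(c.name, c.variant) for c in report.contrasts}
    for variant in ("all", "no_imputed", "no_retreated"):
        assert ("delta_das28_6_12_by_repopulator", variant) in names
        assert ("ada_x_repopulation_fisher_one_sided", variant) in names
    contrast = report.get("delta_das28_6_12_by_repopulator")
    assert contrast.comparison is not None
    assert contrast.group_means["early"] < contrast.group_means["late"]


def test_null_cohort_rejection_rate_near_alpha():
    # identical DAS28 dynamics in both classes: no systematic rejection
    rng = np.random.default_rng(1)
    rejections = 0
    n_rep = 300
    for _ in range(n_rep):
        timelines, calls = _fabricated_cohort(
            rng, early_mean=0.0, late_mean=0.0
        )
        report = associate_endpoints_with_outcomes(timelines, calls)
        c = report.get("delta_das28_6_12_by_repopulator")
        rejections += c.comparison.p_value <= 0.05
    assert 0.005 <= rejections / n_rep <= 0.11


def test_small_class_contrast_is_skipped_with_reason():
    rng = np.random.default_rng(2)
    timelines, calls = _fabricated_cohort(rng, n_early=1, n_late=10)
    report = associate_endpoints_with_outcomes(timelines, calls)
    c = report.get("delta_das28_6_12_by_repopulator")
    assert c.comparison is None and c.skipped_reason
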