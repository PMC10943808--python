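"""Normality-gated group comparisons, Fisher exact tests and EULAR response.

The statistical layer mirrors a classic clinical-immunology workflow:
D'Agostino-Pearson omnibus normality gating selects between the unpaired
t-test / one-way ANOVA with Bonferroni post-tests (parametric branch) and
Mann-Whitney / Kruskal-Wallis with Dunn's post-tests (nonparametric branch);
contingency tables use Fisher's exact test; clinical response follows the
EULAR DAS28 response grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .endpoint_caller import EndpointCall, PatientTimeline
from .errors import InsufficientDataError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Minimum per-group n for the omnibus normality test to be trusted.
NORMALITY_MIN_N = 8

#: Significance level of the normality gate.
NORMALITY_ALPHA = 0.05

#: Largest group size for which the Mann-Whitney p-value is enumerated exactly.
MANNWHITNEY_EXACT_MAX_N = 20


@dataclass(slots=True)
class GroupComparison:
    """Result of one group contrast, with normality-appropriate summaries."""

    test_name: str
    statistic: float
    p_value: float
    group_summaries: list[str]
    n_per_group: list[int]
    posthoc: Optional[list[dict]] = None


@dataclass(slots=True)
class EularResponse:
    """EULAR DAS28 response category for one baseline/endpoint pair."""

    category: str  # "good" | "moderate" | "none"
    das28_baseline: float
    das28_endpoint: float

    @property
    def improvement(self) -> float:
        return self.das28_baseline - self.das28_endpoint


# ---------------------------------------------------------------------------
# Summaries and gate


def _summary(sample: np.ndarray, parametric: bool) -> str:
    if parametric:
        sd = sample.std(ddof=1) if sample.size > 1 else 0.0
        return f"{sample.mean():.2f} ± {sd:.2f}"
    q1, med, q3 = np.percentile(sample, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f} – {q3:.2f})"


def normality_gate(groups: Sequence[Sequence[float]]) -> str:
    """Choose the test family: 'parametric' iff every group looks normal.

    Each group is screened with the D'Agostino-Pearson K^2 omnibus test
    (transformed skewness + kurtosis, chi-square with 2 df). Groups smaller
    than NORMALITY_MIN_N, or with zero variance, force the nonparametric
    branch: the omnibus statistic is unreliable or undefined there.
    """
    for g in groups:
        sample = np.asarray(g, dtype=float)
        if sample.size < NORMALITY_MIN_N:
            return "nonparametric"
        if np.ptp(sample) == 0.0:
            logger.info("zero-variance group: falling back to nonparametric tests")
            return "nonparametric"
        _, p = stats.normaltest(sample)
        if p < NORMALITY_ALPHA:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# Two-group and multi-group comparisons


def mann_whitney_two_sided(a: Sequence[float], b: Sequence[float]) -> tuple:
    """Two-sided Mann-Whitney U: exact enumeration when both groups have
    <= 20 observations and no ties, otherwise the normal approximation with
    tie correction. Returns (U, p)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = max(x.size, y.size) <= MANNWHITNEY_EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    statistic, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(statistic), float(p)


def compare_two_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Unpaired t-test or Mann-Whitney, selected by the normality gate.

    The t-test is the classic equal-variance form. Mann-Whitney is two-sided:
    exact enumeration when both groups have <= 20 observations and no ties,
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    branch = normality_gate([x, y])
    if branch == "parametric":
        if np.ptp(np.concatenate([x, y])) == 0.0:
            statistic, p = 0.0, 1.0  # identical constant groups
        else:
            statistic, p = stats.ttest_ind(x, y, equal_var=True)
            if math.isnan(statistic):  # zero pooled variance, equal means
                statistic, p = 0.0, 1.0
        name = "t_unpaired"
    else:
        statistic, p = mann_whitney_two_sided(x, y)
        name = "mann_whitney"
    parametric = name == "t_unpaired"
    return GroupComparison(
        test_name=name,
        statistic=float(statistic),
        p_value=float(min(p, 1.0)),
        group_summaries=[_summary(x, parametric), _summary(y, parametric)],
        n_per_group=[int(x.size), int(y.size)],
    )


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def _pairwise_t_pooled(groups: list[np.ndarray]) -> list[dict]:
    """Bonferroni pairwise post-tests with the pooled within-group MSE."""
    k = len(groups)
    n_total = sum(g.size for g in groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n_total - k)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out = []
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        se = math.sqrt(mse * (1.0 / gi.size + 1.0 / gj.size))
        t = (gi.mean() - gj.mean()) / se if se > 0 else 0.0
        raw = 2.0 * stats.t.sf(abs(t), n_total - k) if se > 0 else 1.0
        out.append(
            {
                "pair": (i, j),
                "method": "bonferroni",
                "raw_p": raw,
                "adjusted_p": _bonferroni(raw, len(pairs)),
            }
        )
    return out


def _dunn_posthoc(groups: list[np.ndarray]) -> list[dict]:
    """Dunn's pairwise z-tests on mean ranks, Bonferroni-adjusted.

    The z statistic uses the Kruskal-Wallis rank variance with tie
    correction: var = (N(N+1)/12 - T/(12(N-1))) * (1/ni + 1/nj), where
    T = sum(t^3 - t) over tie groups.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks, offset = [], 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + g.size].mean())
        offset += g.size
    k = len(groups)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out = []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw = 2.0 * stats.norm.sf(abs(z))
        out.append(
            {
                "pair": (i, j),
                "method": "dunn",
                "raw_p": raw,
                "adjusted_p": _bonferroni(raw, len(pairs)),
            }
        )
    return out


def compare_timepoints(samples_by_month: dict[int, Sequence[float]]) -> GroupComparison:
    """Normality-gated one-way ANOVA or Kruskal-Wallis across visit months,
    with Bonferroni (parametric) or Dunn (nonparametric) pairwise post-tests."""
    if len(samples_by_month) < 3:
        raise ParameterError("at least 3 timepoints are required")
    months = sorted(samples_by_month)
    groups = [np.asarray(samples_by_month[m], dtype=float) for m in months]
    if any(g.size < 2 for g in groups):
        raise InsufficientDataError("each timepoint needs at least 2 observations")
    branch = normality_gate(groups)
    if branch == "parametric":
        statistic, p = stats.f_oneway(*groups)
        if math.isnan(statistic):  # zero within- and between-group variance
            statistic, p = 0.0, 1.0
        name, posthoc = "anova_oneway", _pairwise_t_pooled(groups)
    else:
        if np.ptp(np.concatenate(groups)) == 0.0:  # all values identical
            statistic, p = 0.0, 1.0
        else:
            statistic, p = stats.kruskal(*groups)
            if math.isnan(statistic):
                statistic, p = 0.0, 1.0
        name, posthoc = "kruskal_wallis", _dunn_posthoc(groups)
    parametric = name == "anova_oneway"
    return GroupComparison(
        test_name=name,
        statistic=float(statistic),
        p_value=float(min(p, 1.0)),
        group_summaries=[_summary(g, parametric) for g in groups],
        n_per_group=[int(g.size) for g in groups],
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# Fisher exact


def fisher_exact_2x2(table: Sequence[Sequence[int]], sided: str = "two") -> GroupComparison:
    """Fisher's exact test from the hypergeometric distribution.

    One-sided: tail probability P(X >= a | margins) in the enrichment
    direction of the observed table (P(X <= a) when the observed top-left
    cell is below its expectation). Two-sided: sum of the probabilities of
    all tables with point probability <= the observed one (1e-12 slack).
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or (n - c1) == 0:
        raise ValidationError("degenerate table: a margin is zero")
    if sided not in ("one", "two"):
        raise ParameterError("sided must be 'one' or 'two'")

    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    # hypergeometric pmf over the support via log-gamma (fast and stable)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(support + 1)
        - gammaln(r1 - support + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - support + 1)
        - gammaln(r2 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    observed = float(pmf[support == a][0])
    expected_a = r1 * c1 / n
    if sided == "one":
        if a >= expected_a:
            p = float(pmf[support >= a].sum())
        else:
            p = float(pmf[support <= a].sum())
    else:
        p = float(pmf[pmf <= observed * (1.0 + 1e-12)].sum())
    p = min(1.0, p)
    # odds ratio as the conventional effect-size companion
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return GroupComparison(
        test_name=f"fisher_exact_{'1' if sided == 'one' else '2'}sided",
        statistic=odds,
        p_value=p,
        group_summaries=[f"{a}/{r1}", f"{c}/{r2}"],
        n_per_group=[r1, r2],
    )


# ---------------------------------------------------------------------------
# DAS28 / EULAR


def delta_das28(
    timeline: PatientTimeline, from_month: int, to_month: int
) -> Optional[float]:
    """DAS28 change to_month minus from_month; None when either score is missing."""
    vf, vt = timeline.visit(from_month), timeline.visit(to_month)
    if vf is None or vt is None:
        raise ParameterError(
            f"months {from_month} and {to_month} must both be scheduled visits"
        )
    if vf.das28 is None or vt.das28 is None:
        return None
    return vt.das28 - vf.das28


def eular_response(baseline: float, endpoint: float) -> EularResponse:
    """EULAR DAS28 response category from baseline and endpoint scores.

    Good: improvement > 1.2 and endpoint <= 3.2. None: improvement <= 0.6,
    or improvement <= 1.2 with endpoint > 5.1. Moderate otherwise.
    """
    if not (0.0 <= baseline <= 10.0 and 0.0 <= endpoint <= 10.0):
        raise ValidationError("DAS28 scores must lie in [0, 10]")
    improvement = baseline - endpoint
    if improvement > 1.2 and endpoint <= 3.2:
        category = "good"
    elif improvement <= 0.6 or (improvement <= 1.2 and endpoint > 5.1):
        category = "none"
    else:
        category = "moderate"
    return EularResponse(
        category=category, das28_baseline=baseline, das28_endpoint=endpoint
    )


# ---------------------------------------------------------------------------
# Headline association report


@dataclass(slots=True)
class Contrast:
    """One named contrast within a sensitivity variant of the report."""

    name: str
    variant: str
    comparison: Optional[GroupComparison]
    group_means: Optional[dict] = None
    skipped_reason: Optional[str] = None


@dataclass(slots=True)
class AssociationReport:
    contrasts: list[Contrast] = field(default_factory=list)

    def get(self, name: str, variant: str = "all") -> Contrast:
        for c in self.contrasts:
            if c.name == name and c.variant == variant:
                return c
        raise KeyError((name, variant))


def _delta_by_class(
    timelines: dict[str, PatientTimeline],
    calls: Sequence[EndpointCall],
    classifier: str,
    from_month: int,
    to_month: int,
) -> tuple[list[float], list[float]]:
    early, late = [], []
    for call in calls:
        if call.anomaly:
            continue
        tl = timelines[call.patient_id]
        d = delta_das28(tl, from_month, to_month)
        if d is None:
            continue
        cls = getattr(call, classifier)
        (early if cls == "early" else late).append(d)
    return early, late


def associate_endpoints_with_outcomes(
    timelines: Sequence[PatientTimeline],
    calls: Sequence[EndpointCall],
) -> AssociationReport:
    """The four headline contrasts linking endpoints to clinical outcome.

    For each contrast, sensitivity variants re-run it excluding patients
    whose endpoint calling used imputed samples and excluding patients
    retreated during follow-up. ADA association reports both Fisher sidings
    on the ADA-status x repopulation-within-12-months table.
    """
    by_id = {t.patient_id: t for t in timelines}
    report = AssociationReport()

    def variants():
        yield "all", list(calls)
        yield "no_imputed", [c for c in calls if not c.used_imputation]
        yield (
            "no_retreated",
            [
                c
                for c in calls
                if not any(v.retreated for v in by_id[c.patient_id].visits)
            ],
        )

    contrast_specs = [
        ("delta_das28_0_1_by_depleter", "depleter_class", 0, 1),
        ("delta_das28_0_3_by_depleter", "depleter_class", 0, 3),
        ("delta_das28_6_12_by_repopulator", "repopulator_class", 6, 12),
    ]
    for variant, subset in variants():
        for name, classifier, m_from, m_to in contrast_specs:
            early, late = _delta_by_class(by_id, subset, classifier, m_from, m_to)
            if len(early) < 2 or len(late) < 2:
                logger.info("contrast %s (%s): a class is too small", name, variant)
                report.contrasts.append(
                    Contrast(
                        name=name,
                        variant=variant,
                        comparison=None,
                        skipped_reason="a class has fewer than 2 usable patients",
                    )
                )
                continue
            report.contrasts.append(
                Contrast(
                    name=name,
                    variant=variant,
                    comparison=compare_two_groups(early, late),
                    group_means={
                        "early": float(np.mean(early)),
                        "late": float(np.mean(late)),
                    },
                )
            )
        # ADA x repopulation-within-12-months contingency
        table = [[0, 0], [0, 0]]
        usable = 0
        for c in subset:
            tl = by_id[c.patient_id]
            if tl.ada_positive_within_12m is None or c.anomaly:
                continue
            repop = c.repopulation_month is not None
            row = 0 if tl.ada_positive_within_12m else 1
            table[row][0 if repop else 1] += 1
            usable += 1
        for sided in ("one", "two"):
            name = f"ada_x_repopulation_fisher_{sided}_sided"
            try:
                comparison = fisher_exact_2x2(table, sided=sided)
            except ValidationError as exc:
                report.contrasts.append(
                    Contrast(
                        name=name,
                        variant=variant,
                        comparison=None,
                        skipped_reason=str(exc),
                    )
                )
                continue
            report.contrasts.append(
                Contrast(
                    name=name,
                    variant=variant,
                    comparison=comparison,
                    group_means={"table": [row[:] for row in table], "n": usable},
                )
            )
    return report
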