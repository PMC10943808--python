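"""Synthetic longitudinal BCR cohort with planted depletion/repopulation truth.

The generator emulates processed, UMI-consensus rearrangement tables plus a
clinical visit table for a rituximab-style longitudinal study: per-patient
percent-unmutated trajectories that cross the cohort depletion threshold at
planted months, visit-dependent clonal expansion / diversity / mutation-load
targets, DAS28 trajectories whose month-6 to month-12 change differs by
repopulation group, ADA status correlated with repopulation, and missing or
failed samples planted only where the failure-means-depletion assumption is
true.

Because the depletion threshold is recomputed downstream from the realized
baseline values (mean minus two SD), all planted below/above-threshold values
are drawn relative to the cohort's own realized threshold; endpoint recovery
is therefore exact by construction on fully observed cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .cohort_io import (
    ClinicalVisit,
    PatientRecord,
    RearrangementRecord,
    write_clinical_table,
    write_rearrangements,
)
from .errors import InfeasibleTargetError, ValidationError
from .repertoire_metrics import gini_expansion

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Tunable module constants (not part of SimulationConfig; see docs/methods.md)

#: Acceptable realized cohort thresholds (percent); baseline sets are redrawn
#: until mean - 2*SD lands in this band so depletion is representable.
THRESHOLD_BAND = (1.0, 9.0)

#: Baseline percent-unmutated support; the floor keeps every baseline above
#: any threshold the band allows.
BASELINE_RANGE = (10.0, 100.0)

#: Margin (percent) separating planted values from the realized threshold.
THRESHOLD_MARGIN = 0.1

#: SD of not-yet-depleted ("pending") post-baseline values.
PENDING_SD = 2.0

#: Mean/SD of percent unmutated after repopulation.
REPOP_MEAN, REPOP_SD = 25.0, 15.0

#: Per-sample metric-target jitter (SD, truncation half-width).
GINI_JITTER = (0.08, 0.20)
SHANNON_JITTER = (0.10, 0.25)
MUTLOAD_JITTER = (0.004, 0.010)

#: DAS28 random-walk steps to months 1/3/6 (mean, SD) and missing rate.
DAS28_STEP = (-0.3, 0.45)
DAS28_MISSING_RATE = 0.05

#: Probability of a second treatment cycle at month 6.
RETREAT_RATE = 0.2

#: Not-collected samples are planted only at depleted visits strictly between
#: the planted endpoints (where they cannot disturb endpoint calling).
NOT_COLLECTED_RATE = 0.04

#: Fraction of extra low-UMI-support records (1-2 UMIs) per sample; these are
#: removed by the pipeline's UMI filter and carry no planted signal.
LOW_SUPPORT_FRACTION = 0.10

#: Visit-state metric targets for follow-up months after month 1:
#: month -> (gini, shannon, mutation load, lineages). Months 0 and 1 come
#: from SimulationConfig.
FOLLOWUP_METRIC_TARGETS = {
    3: (0.52, 4.60, 0.075, 400),
    6: (0.48, 5.30, 0.065, 700),
    12: (0.45, 5.93, 0.060, 1000),
}

#: Lineage count / Shannon target for month-1 samples.
MONTH1_SHANNON_TARGET = 4.75
MONTH1_N_LINEAGES = 400

#: UMI-count family: discrete power law on counts >= MIN_UMI_COUNT.
MIN_UMI_COUNT = 3
_COUNT_SUPPORT_MAX = MIN_UMI_COUNT + 2**15
_SHAPE_MAX = 30.0
#: Geometric-cutoff ladder: the smallest tail able to reach a Gini target is
#: used, keeping sample-Gini noise low for moderate targets.
_TAU_LADDER = (2000.0, 10000.0, 60000.0)

#: IMGT-like aligned IGHV length and its fixed gap columns.
V_ALIGNED_LENGTH = 312
V_GAP_COLUMNS = (160, 161, 162, 163, 164, 165)

_JUNCTION_LENGTHS = tuple(range(36, 61, 3))
_BASES = b"ACGT"


# ---------------------------------------------------------------------------
# Configuration and truth


def _default_depletion_probs() -> dict:
    return {1: 14 / 23, 3: 5 / 23, 6: 4 / 23}


def _default_repopulation_probs() -> dict:
    return {3: 2 / 23, 6: 7 / 23, 12: 5 / 23, "never": 9 / 23}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the printed cohort summaries of the emulated study: baseline
    and month-1 percent-unmutated moments, Gini/Shannon/mutation-load targets,
    endpoint-month frequencies, DAS28 contrasts by repopulation group, and the
    ADA-repopulation coupling.
    """

    n_patients: int = 23
    visit_months: tuple = (0, 1, 3, 6, 12)
    seed: int = 0
    baseline_unmutated_mean: float = 40.0
    baseline_unmutated_sd: float = 17.8
    month1_unmutated_mean: float = 4.33
    month1_unmutated_sd: float = 3.98
    baseline_gini_target: float = 0.27
    month1_gini_target: float = 0.52
    baseline_shannon_target: float = 7.53
    baseline_mutload_mean: float = 0.04
    month1_mutload_mean: float = 0.07
    depletion_month_probs: dict = field(default_factory=_default_depletion_probs)
    repopulation_month_probs: dict = field(default_factory=_default_repopulation_probs)
    das28_baseline_mean: float = 4.3
    das28_baseline_sd: float = 1.0
    delta_das28_6to12_early_mean: float = -1.17
    delta_das28_6to12_early_sd: float = 0.96
    delta_das28_6to12_late_mean: float = 0.18
    delta_das28_6to12_late_sd: float = 0.67
    p_ada: float = 0.5
    p_repop_given_ada: float = 10 / 14
    p_repop_given_no_ada: float = 4 / 13
    missing_sample_rate: float = 0.05
    n_lineages_baseline: int = 2500
    clonotypes_per_sample: int = 5000

    def __post_init__(self) -> None:
        self.visit_months = tuple(int(m) for m in self.visit_months)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        months = self.visit_months
        if months[0] != 0 or any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError("visit_months must start at 0 and increase")
        for name in ("p_ada", "p_repop_given_ada", "p_repop_given_no_ada",
                     "missing_sample_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        for name, probs in (
            ("depletion_month_probs", self.depletion_month_probs),
            ("repopulation_month_probs", self.repopulation_month_probs),
        ):
            values = list(probs.values())
            if any(not 0.0 <= p <= 1.0 for p in values):
                raise ValidationError(f"{name}: probabilities must be in [0, 1]")
            if abs(sum(values) - 1.0) > 1e-9:
                raise ValidationError(f"{name}: probabilities must sum to 1")
        for name in ("baseline_gini_target", "month1_gini_target"):
            g = getattr(self, name)
            if not 0.0 <= g < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {g}")
        if not (1 <= self.n_lineages_baseline <= self.clonotypes_per_sample):
            raise ValidationError(
                "need 1 <= n_lineages_baseline <= clonotypes_per_sample"
            )
        if self.baseline_shannon_target > math.log(self.n_lineages_baseline) + 1e-9:
            raise ValidationError(
                "baseline_shannon_target exceeds ln(n_lineages_baseline)"
            )
        for name in (
            "baseline_unmutated_mean", "baseline_unmutated_sd",
            "month1_unmutated_mean", "month1_unmutated_sd",
            "baseline_mutload_mean", "month1_mutload_mean",
            "das28_baseline_mean", "das28_baseline_sd",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass(slots=True)
class PatientTruth:
    """Planted ground truth for one patient."""

    patient_id: str
    true_depletion_month: Optional[int]
    true_repopulation_month: Optional[int]
    repopulator_class_true: str  # "early" | "late"
    ada_positive: bool


SyntheticTruth = list  # list[PatientTruth]


@dataclass(slots=True)
class SimulatedCohort:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    patients: list[PatientRecord]
    truth: list[PatientTruth]
    planted_threshold: float
    planted_pct: dict  # (patient_id, month) -> planted percent unmutated


# ---------------------------------------------------------------------------
# UMI-count abundance family: discrete power law with counts >= 3


@lru_cache(maxsize=256)
def _count_cdf(shape: float, tau: float) -> tuple:
    """Support and CDF of the count family: power law with geometric tail,
    pmf(k) ~ (k-2)^(-shape) * exp(-(k-3)/tau) on k >= 3."""
    k = np.arange(MIN_UMI_COUNT, _COUNT_SUPPORT_MAX + 1, dtype=float)
    w = (k - (MIN_UMI_COUNT - 1.0)) ** (-shape) * np.exp(
        -(k - MIN_UMI_COUNT) / tau
    )
    pmf = w / w.sum()
    return k, np.cumsum(pmf)


def _population_gini(shape: float, tau: float) -> float:
    k, cdf = _count_cdf(shape, tau)
    pmf = np.diff(cdf, prepend=0.0)
    mu = float((k * pmf).sum())
    # support spacing is 1, so G = sum F(1-F) / mu over interior points
    return float((cdf[:-1] * (1.0 - cdf[:-1])).sum() / mu)


@lru_cache(maxsize=16)
def _branch_start(tau: float) -> tuple:
    """Start of the decreasing shape branch and the peak Gini for this tau."""
    grid = np.arange(0.8, 2.01, 0.05)
    ginis = [_population_gini(float(s), tau) for s in grid]
    i = int(np.argmax(ginis))
    return float(grid[i]), float(ginis[i])


def _solve_shape_for_population_gini(target: float, tau: float) -> float:
    lo, _ = _branch_start(tau)
    hi = _SHAPE_MAX
    g_lo = _population_gini(lo, tau)
    g_hi = _population_gini(hi, tau)
    if not (g_hi <= target <= g_lo):
        raise InfeasibleTargetError(
            f"Gini target {target:.3f} outside the achievable range "
            f"[{g_hi:.4f}, {g_lo:.4f}] of the count family at tau={tau}"
        )
    return float(
        optimize.brentq(
            lambda s: _population_gini(s, tau) - target, lo, hi, xtol=1e-6
        )
    )


@lru_cache(maxsize=512)
def _solve_count_params(target_r: float, n_clonotypes: int) -> tuple:
    """(shape, tau) whose EXPECTED SAMPLE Gini at n_clonotypes equals target.

    The geometric cutoff tau is taken from a ladder (smallest tail that can
    reach the target); the closed-form population solve is then refined by a
    fixed-seed Monte-Carlo correction, removing the finite-n ratio bias of
    the sample Gini on heavy-tailed counts.
    """
    tau = None
    for candidate in _TAU_LADDER:
        if _branch_start(candidate)[1] >= target_r + 0.02:
            tau = candidate
            break
    if tau is None:
        raise InfeasibleTargetError(
            f"Gini target {target_r:.3f} unreachable by the count family"
        )
    rng = np.random.default_rng(987654321)

    def expected_sample_gini(shape: float) -> float:
        k, cdf = _count_cdf(shape, tau)
        return float(
            np.mean(
                [
                    gini_expansion(k[np.searchsorted(cdf, rng.random(n_clonotypes))])
                    for _ in range(100)
                ]
            )
        )

    g_floor = _population_gini(_SHAPE_MAX, tau) + 1e-6
    g_ceil = _branch_start(tau)[1] - 1e-6
    solved_for = target_r
    shape = _solve_shape_for_population_gini(solved_for, tau)
    for _ in range(3):
        est = expected_sample_gini(shape)
        if abs(est - target_r) < 0.003:
            break
        solved_for = min(max(solved_for + (target_r - est), g_floor), g_ceil)
        shape = _solve_shape_for_population_gini(solved_for, tau)
    return shape, tau


def _draw_umi_counts(
    n_clonotypes: int, gini_target: float, rng: np.random.Generator
) -> np.ndarray:
    if gini_target < 0.005:
        return np.full(n_clonotypes, MIN_UMI_COUNT + 2, dtype=int)
    shape, tau = _solve_count_params(round(float(gini_target), 3), n_clonotypes)
    k, cdf = _count_cdf(shape, tau)
    return k[np.searchsorted(cdf, rng.random(n_clonotypes))].astype(int)


# ---------------------------------------------------------------------------
# Clonotypes-per-lineage allocation for a Shannon target


@lru_cache(maxsize=512)
def _lineage_sizes(n_lineages: int, n_clonotypes: int, target_r: float) -> tuple:
    """Deterministic clonotype counts per lineage realizing a Shannon target.

    Lineage weights follow a power law in rank; the exponent is solved by
    bisection so the entropy of the largest-remainder allocation matches the
    target. Zero-size lineages are dropped (entropy is over realized sizes).
    """

    ranks = np.arange(1, n_lineages + 1, dtype=float)

    def alloc(s: float) -> np.ndarray:
        w = ranks ** (-s)
        w /= w.sum()
        base = np.floor(w * n_clonotypes).astype(int)
        remainder = n_clonotypes - int(base.sum())
        frac = w * n_clonotypes - base
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
        return base[base > 0]

    def entropy(sizes: np.ndarray) -> float:
        p = sizes / sizes.sum()
        return float(-(p * np.log(p)).sum())

    lo, hi = 0.0, 8.0
    if entropy(alloc(lo)) <= target_r:
        return tuple(alloc(lo))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if entropy(alloc(mid)) > target_r:
            lo = mid
        else:
            hi = mid
    sizes = alloc(0.5 * (lo + hi))
    if abs(entropy(sizes) - target_r) > 0.2:
        raise InfeasibleTargetError(
            f"cannot allocate {n_clonotypes} clonotypes over {n_lineages} "
            f"lineages with Shannon entropy {target_r:.2f}"
        )
    return tuple(sizes)


# ---------------------------------------------------------------------------
# Somatic-hypermutation rate solver


@lru_cache(maxsize=1024)
def _solve_mutation_rate(mean_distinct_r: float, length: int) -> float:
    """Zero-truncated Poisson rate whose expected DISTINCT mutated positions
    (sampling positions with replacement among ``length`` sites) matches the
    requested mean."""
    if mean_distinct_r <= 1.0:
        return 1e-6
    if mean_distinct_r >= 0.99 * length:
        raise InfeasibleTargetError(
            f"mutation target {mean_distinct_r:.1f} too close to the number "
            f"of mutable positions ({length})"
        )

    def expected_distinct(lam: float) -> float:
        kmax = int(lam + 12.0 * math.sqrt(lam) + 25)
        k = np.arange(1, kmax + 1, dtype=float)
        log_pmf = k * math.log(lam) - lam - gammaln(k + 1.0)
        pmf = np.exp(log_pmf) / (1.0 - math.exp(-lam))
        return float((pmf * length * (1.0 - (1.0 - 1.0 / length) ** k)).sum())

    return float(
        optimize.brentq(
            lambda lam: expected_distinct(lam) - mean_distinct_r, 1e-6, 6.0 * length
        )
    )


def _draw_ztp(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    draws = rng.poisson(lam, size)
    for _ in range(200):
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(lam, int(zeros.sum()))
    draws[draws == 0] = 1
    return draws


# ---------------------------------------------------------------------------
# Truncated-normal helpers


def _tn_mean(loc: float, scale: float, low: float, high: float) -> float:
    """Mean of a [low, high]-truncated normal, stable in deep tails."""
    a, b = (low - loc) / scale, (high - loc) / scale
    mass = stats.norm.cdf(b) - stats.norm.cdf(a)
    if mass <= 1e-300:
        return low if a > 0 else high
    return loc + scale * (stats.norm.pdf(a) - stats.norm.pdf(b)) / mass


@lru_cache(maxsize=1024)
def _truncnorm_loc(target_mean: float, scale: float, low: float, high: float) -> float:
    """Location such that the [low, high]-truncated normal has the given mean."""
    lo, hi = low - 10.0 * scale, high + 10.0 * scale
    reach_lo = _tn_mean(lo, scale, low, high)
    reach_hi = _tn_mean(hi, scale, low, high)
    eps = 1e-4 * (high - low)
    target = min(max(target_mean, reach_lo + eps), reach_hi - eps)
    return float(
        optimize.brentq(lambda l: _tn_mean(l, scale, low, high) - target, lo, hi)
    )


def _draw_truncnorm(
    target_mean: float, scale: float, low: float, high: float,
    size: int, rng: np.random.Generator,
) -> np.ndarray:
    loc = _truncnorm_loc(round(float(target_mean), 4), round(float(scale), 4),
                         round(float(low), 4), round(float(high), 4))
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _solve_truncnorm_moments(target_mean: float, target_sd: float,
                             low: float, high: float) -> tuple:
    """Latent (loc, scale) whose [low, high]-truncation has the given moments."""

    def residuals(x):
        l, log_s = x
        s = math.exp(log_s)
        a, b = (low - l) / s, (high - l) / s
        m, v = stats.truncnorm.stats(a, b, loc=l, scale=s, moments="mv")
        return [float(m) - target_mean, math.sqrt(float(v)) - target_sd]

    sol = optimize.root(residuals, [target_mean, math.log(target_sd)], method="hybr")
    if not sol.success:
        raise InfeasibleTargetError(
            f"cannot realize mean {target_mean} / SD {target_sd} on "
            f"[{low}, {high}]"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


@lru_cache(maxsize=64)
def _baseline_sampler_params(mean_r: float, sd_r: float, n: int) -> tuple:
    """(loc, scale) of the baseline truncated normal on BASELINE_RANGE whose
    cohort mean, AFTER conditioning the realized threshold into
    THRESHOLD_BAND, equals the configured baseline mean.

    The conditioning bias is removed by an empirical fixed point: cheap
    vectorized Monte-Carlo on the (mean, SD) sampling distribution with a
    fixed internal seed, iterated until the conditional mean converges.
    """
    low, high = BASELINE_RANGE
    rng = np.random.default_rng(246813579)
    target_mean = mean_r
    loc = scale = None
    for _ in range(5):
        loc, scale = _solve_truncnorm_moments(target_mean, sd_r, low, high)
        a, b = (low - loc) / scale, (high - loc) / scale
        draws = stats.truncnorm.rvs(
            a, b, loc=loc, scale=scale, size=(12000, n), random_state=rng
        )
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        thr = means - 2.0 * sds
        sel = (thr >= THRESHOLD_BAND[0]) & (thr <= THRESHOLD_BAND[1])
        if sel.sum() < 100:
            raise InfeasibleTargetError(
                "threshold band is unreachable from the configured baseline "
                "distribution"
            )
        bias = float(means[sel].mean()) - mean_r
        if abs(bias) < 0.02:
            break
        target_mean -= 0.9 * bias
    return loc, scale


def _draw_baselines(cfg: SimulationConfig, rng: np.random.Generator) -> tuple:
    """Baseline percent-unmutated values plus the realized cohort threshold.

    Vectors are redrawn until mean - 2*SD lies in THRESHOLD_BAND; the
    conditioning bias on the mean is pre-compensated analytically.
    """
    if cfg.n_patients < 2:
        values = np.full(cfg.n_patients, cfg.baseline_unmutated_mean)
        return values, max(0.0, cfg.baseline_unmutated_mean)
    loc, scale = _baseline_sampler_params(
        round(cfg.baseline_unmutated_mean, 3),
        round(cfg.baseline_unmutated_sd, 3),
        cfg.n_patients,
    )
    low, high = BASELINE_RANGE
    a, b = (low - loc) / scale, (high - loc) / scale
    for _ in range(2000):
        values = stats.truncnorm.rvs(
            a, b, loc=loc, scale=scale, size=cfg.n_patients, random_state=rng
        )
        threshold = values.mean() - 2.0 * values.std(ddof=1)
        if THRESHOLD_BAND[0] <= threshold <= THRESHOLD_BAND[1]:
            return values, float(threshold)
    raise InfeasibleTargetError(
        "could not realize a usable depletion threshold from the configured "
        "baseline distribution"
    )


# ---------------------------------------------------------------------------
# Germline pool


@dataclass(slots=True)
class GermlinePool:
    """Synthetic germline alleles (random sequences, no real IGHV embedded)."""

    v_names: list[str]
    v_matrix: np.ndarray  # (n_v, 312) uint8, gap columns hold '.'
    d_names: list[str]
    j_names: list[str]
    j_tails: list[bytes]
    nogap_positions: np.ndarray  # V columns usable for mutations
    germ_cache: dict = field(default_factory=dict)  # (v, junc len, j) -> str

    @classmethod
    def build(
        cls, rng: np.random.Generator, n_v: int = 40, n_d: int = 25, n_j: int = 6
    ) -> "GermlinePool":
        bases = np.frombuffer(_BASES, dtype=np.uint8)
        v_matrix = bases[rng.integers(0, 4, size=(n_v, V_ALIGNED_LENGTH))]
        v_matrix[:, list(V_GAP_COLUMNS)] = ord(".")
        nogap = np.array(
            [i for i in range(V_ALIGNED_LENGTH) if i not in V_GAP_COLUMNS]
        )
        j_tails = [
            bases[rng.integers(0, 4, size=12)].tobytes() for _ in range(n_j)
        ]
        return cls(
            v_names=[f"IGHV{1 + i % 7}-S{i + 1}*01" for i in range(n_v)],
            v_matrix=v_matrix,
            d_names=[f"IGHD{1 + i % 7}-S{i + 1}*01" for i in range(n_d)],
            j_names=[f"IGHJ{i + 1}*01" for i in range(n_j)],
            j_tails=j_tails,
            nogap_positions=nogap,
        )


# ---------------------------------------------------------------------------
# Repertoire synthesis


class _RandRows:
    """Buffered source of (position, alternative-base) random rows.

    Batches generator calls so the per-lineage junction construction does not
    pay a numpy call per member; consumption order is deterministic.
    """

    __slots__ = ("rng", "pos", "alt", "ptr", "width")

    def __init__(self, rng: np.random.Generator, n_rows: int, width: int = 8):
        self.rng = rng
        self.width = width
        self._refill(max(n_rows, 64))

    def _refill(self, n_rows: int) -> None:
        self.pos = self.rng.integers(0, 1 << 30, size=(n_rows, self.width))
        self.alt = self.rng.integers(0, 3, size=(n_rows, self.width))
        self.ptr = 0

    def next_row(self) -> tuple:
        if self.ptr >= self.pos.shape[0]:
            self._refill(self.pos.shape[0])
        row = (self.pos[self.ptr], self.alt[self.ptr])
        self.ptr += 1
        return row


def _member_junctions(root: bytes, size: int, rand: _RandRows) -> list[bytes]:
    """``size`` distinct junctions within single-linkage reach of the root.

    Every member differs from the root at most floor(0.14 * L) positions, so
    all members join the root's cluster at the 0.15 threshold; patterns are
    kept distinct so clonotype keys never collide within a lineage.
    """
    length = len(root)
    juncs = [root]
    if size == 1:
        return juncs
    seen: set = set()
    interior = length - 6  # keep the conserved TGT/TGG caps intact
    max_muts = max(1, int(0.14 * length))
    n_mut, stalls = 1, 0
    arr = bytearray(root)
    while len(juncs) < size:
        pos_row, alt_row = rand.next_row()
        prow = [3 + int(p) % interior for p in pos_row[:n_mut]]
        if n_mut > 1 and len(set(prow)) < n_mut:
            continue
        key = (tuple(sorted(prow)), tuple(int(a) for a in alt_row[:n_mut]))
        if key in seen:
            stalls += 1
            if stalls > 20 and n_mut < max_muts:  # pattern space getting crowded
                n_mut, stalls = n_mut + 1, 0
            continue
        seen.add(key)
        stalls = 0
        for pos, alt in zip(key[0], key[1]):
            options = [b for b in _BASES if b != root[pos]]
            arr[pos] = options[alt]
        juncs.append(bytes(arr))
        for pos in key[0]:
            arr[pos] = root[pos]
    return juncs


def generate_repertoire(
    n_lineages: int,
    n_clonotypes: int,
    unmutated_frac: float,
    gini_target: float,
    mutload_mean: float,
    rng: np.random.Generator,
    *,
    shannon_target: Optional[float] = None,
    germline_pool: Optional[GermlinePool] = None,
    patient_id: str = "P00",
    visit_month: int = 0,
    low_support_fraction: float = LOW_SUPPORT_FRACTION,
) -> list[RearrangementRecord]:
    """One sample's rearrangement records with planted metric targets.

    After the pipeline's >= 3 UMI filter the sample realizes: ``n_clonotypes``
    clonotypes whose UMI counts have expected sample Gini ``gini_target``;
    exactly round(unmutated_frac/100 * n_clonotypes) clonotypes with zero IGHV
    mismatches; mutated clonotypes with zero-truncated-Poisson mismatch counts
    whose rate is solved so the mean mutation frequency over all clonotypes is
    ``mutload_mean``; and lineage sizes allocated to a Shannon entropy of
    ``shannon_target`` (default: the maximal, near-uniform allocation).
    An extra ``low_support_fraction`` of 1-2-UMI records is appended; the UMI
    filter removes them.
    """
    if not 1 <= n_lineages <= n_clonotypes:
        raise ValidationError("need 1 <= n_lineages <= n_clonotypes")
    if not 0.0 <= unmutated_frac <= 100.0:
        raise ValidationError("unmutated_frac must be in [0, 100]")
    pool = germline_pool if germline_pool is not None else GermlinePool.build(rng)
    if shannon_target is None:
        shannon_target = math.log(n_lineages) if n_lineages > 1 else 0.0
    shannon_target = min(shannon_target, math.log(max(n_lineages, 1)))

    sizes = np.array(
        _lineage_sizes(n_lineages, n_clonotypes, round(float(shannon_target), 2))
    )
    sizes = sizes[rng.permutation(sizes.size)]

    length_nogap = pool.nogap_positions.size
    n_v, n_d, n_j = len(pool.v_names), len(pool.d_names), len(pool.j_names)

    # per-lineage identity, per-clonotype junctions (randomness drawn in bulk)
    n_lin = sizes.size
    bases_arr = np.frombuffer(_BASES, dtype=np.uint8)
    lin_v = rng.integers(0, n_v, size=n_lin)
    lin_d = rng.integers(-1, n_d, size=n_lin)  # -1 = no D assignment
    lin_j = rng.integers(0, n_j, size=n_lin)
    lin_jl = np.asarray(_JUNCTION_LENGTHS)[
        rng.integers(0, len(_JUNCTION_LENGTHS), size=n_lin)
    ]
    max_jl = max(_JUNCTION_LENGTHS)
    root_mat = bases_arr[rng.integers(0, 4, size=(n_lin, max_jl))]
    rand_rows = _RandRows(rng, n_clonotypes + n_lin // 4 + 64)

    v_idx = np.repeat(lin_v, sizes)
    d_idx = np.repeat(lin_d, sizes)
    j_idx = np.repeat(lin_j, sizes)
    lineage_of = np.repeat(np.arange(n_lin), sizes)
    junctions: list[bytes] = []
    for lid in range(n_lin):
        root = bytearray(root_mat[lid, : lin_jl[lid]].tobytes())
        root[0:3], root[-3:] = b"TGT", b"TGG"
        junctions.extend(_member_junctions(bytes(root), int(sizes[lid]), rand_rows))

    # UMI counts and unmutated set
    counts = _draw_umi_counts(n_clonotypes, gini_target, rng)
    n_unmut = int(round(unmutated_frac / 100.0 * n_clonotypes))
    mutated = np.ones(n_clonotypes, dtype=bool)
    if n_unmut:
        mutated[rng.choice(n_clonotypes, size=n_unmut, replace=False)] = False
    mut_ids = np.nonzero(mutated)[0]

    # sequence matrix: germline alleles + planted V mutations
    seq_matrix = pool.v_matrix[v_idx].copy()
    if mut_ids.size:
        mutated_frac_eff = mut_ids.size / n_clonotypes
        mean_distinct = mutload_mean * length_nogap / mutated_frac_eff
        lam = _solve_mutation_rate(round(float(mean_distinct), 3), length_nogap)
        n_draws = _draw_ztp(lam, mut_ids.size, rng)
        rows = np.repeat(mut_ids, n_draws)
        cols = pool.nogap_positions[rng.integers(0, length_nogap, size=rows.size)]
        pairs = np.sort(rows * V_ALIGNED_LENGTH + cols)
        keep = np.empty(pairs.size, dtype=bool)
        keep[0], keep[1:] = True, pairs[1:] != pairs[:-1]
        pairs = pairs[keep]
        rows, cols = pairs // V_ALIGNED_LENGTH, pairs % V_ALIGNED_LENGTH
        current = seq_matrix[rows, cols]
        alt_choice = rng.integers(0, 3, size=rows.size)
        alt_table = np.array(
            [[b for b in _BASES if b != ref] for ref in _BASES], dtype=np.uint8
        )
        base_index = np.searchsorted(np.sort(bases_arr), current)
        # map current base byte -> row of alt_table (bases sorted = ACGT order)
        seq_matrix[rows, cols] = alt_table[base_index, alt_choice]

    v_bytes = np.ascontiguousarray(seq_matrix).view(f"S{V_ALIGNED_LENGTH}").ravel()
    germ_bytes = np.ascontiguousarray(pool.v_matrix).view(f"S{V_ALIGNED_LENGTH}").ravel()

    records: list[RearrangementRecord] = []
    germ_cache = pool.germ_cache
    for i in range(n_clonotypes):
        junction = junctions[i]
        tail = pool.j_tails[j_idx[i]]
        seq = (v_bytes[i] + junction + tail).decode()
        gkey = (int(v_idx[i]), len(junction), int(j_idx[i]))
        germ = germ_cache.get(gkey)
        if germ is None:
            germ = (germ_bytes[v_idx[i]] + b"N" * len(junction) + tail).decode()
            germ_cache[gkey] = germ
        records.append(
            RearrangementRecord(
                sequence_id=f"{patient_id}-M{visit_month}-{i:05d}",
                patient_id=patient_id,
                visit_month=visit_month,
                v_call=pool.v_names[v_idx[i]],
                d_call="" if d_idx[i] < 0 else pool.d_names[d_idx[i]],
                j_call=pool.j_names[j_idx[i]],
                junction=junction.decode(),
                sequence_alignment=seq,
                germline_alignment=germ,
                consensus_count=int(counts[i]),
                productive=True,
            )
        )

    # low-UMI-support extras, removed by the pipeline's filter
    n_low = int(round(low_support_fraction * n_clonotypes))
    low_v = rng.integers(0, n_v, size=n_low)
    low_j = rng.integers(0, n_j, size=n_low)
    low_jl = np.asarray(_JUNCTION_LENGTHS)[
        rng.integers(0, len(_JUNCTION_LENGTHS), size=max(n_low, 1))
    ]
    low_junc_mat = bases_arr[rng.integers(0, 4, size=(max(n_low, 1), max_jl))]
    low_counts = rng.integers(1, MIN_UMI_COUNT, size=max(n_low, 1))
    for i in range(n_low):
        vi, ji, jl = int(low_v[i]), int(low_j[i]), int(low_jl[i])
        junction = low_junc_mat[i, :jl].tobytes()
        tail = pool.j_tails[ji]
        seq = (germ_bytes[vi] + junction + tail).decode()
        records.append(
            RearrangementRecord(
                sequence_id=f"{patient_id}-M{visit_month}-L{i:05d}",
                patient_id=patient_id,
                visit_month=visit_month,
                v_call=pool.v_names[vi],
                d_call="",
                j_call=pool.j_names[ji],
                junction=junction.decode(),
                sequence_alignment=seq,
                germline_alignment=seq,
                consensus_count=int(low_counts[i]),
                productive=True,
            )
        )
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# Trajectory planting


def _draw_categorical(probs: dict, rng: np.random.Generator):
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def _plant_endpoints(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple]:
    """(depletion_month, repopulation_month_or_None) per patient.

    The repopulation distribution is renormalized over months strictly after
    the planted depletion month (plus 'never'), keeping the depletion
    marginal exact.
    """
    out = []
    for _ in range(cfg.n_patients):
        d = int(_draw_categorical(cfg.depletion_month_probs, rng))
        allowed = {
            k: v
            for k, v in cfg.repopulation_month_probs.items()
            if k == "never" or int(k) > d
        }
        if not allowed:
            allowed = {"never": 1.0}
        r = _draw_categorical(allowed, rng)
        out.append((d, None if r == "never" else int(r)))
    return out


def _visit_targets(cfg: SimulationConfig, month: int) -> tuple:
    """(gini, shannon, mutation load, n_lineages) targets for a visit month."""
    if month == 0:
        return (
            cfg.baseline_gini_target,
            cfg.baseline_shannon_target,
            cfg.baseline_mutload_mean,
            cfg.n_lineages_baseline,
        )
    if month <= 1:
        return (
            cfg.month1_gini_target,
            MONTH1_SHANNON_TARGET,
            cfg.month1_mutload_mean,
            MONTH1_N_LINEAGES,
        )
    for cutoff in (3, 6):
        if month <= cutoff:
            return FOLLOWUP_METRIC_TARGETS[cutoff]
    return FOLLOWUP_METRIC_TARGETS[12]


def _jitter(
    value: float, spec: tuple, rng: np.random.Generator,
    lower: float, upper: float,
) -> float:
    """Symmetric truncated-normal jitter around a target (mean-preserving)."""
    sd, half = spec
    lo = max(lower, value - half)
    hi = min(upper, value + half)
    if hi - lo < 1e-6:
        return min(max(value, lower), upper)
    half_sym = min(value - lo, hi - value)
    if half_sym <= 1e-6:
        return min(max(value, lo), hi)
    a, b = -half_sym / sd, half_sym / sd
    return float(
        stats.truncnorm.rvs(a, b, loc=value, scale=sd, random_state=rng)
    )


def _solve_month1_means(
    cfg: SimulationConfig, threshold: float, n_depleted_m1: int
) -> tuple:
    """Per-cohort depleted/pending value means whose mixture reproduces the
    configured month-1 cohort mean among samples that yield a repertoire."""
    lo_d, hi_d = THRESHOLD_MARGIN, threshold - THRESHOLD_MARGIN
    lo_p = threshold + THRESHOLD_MARGIN
    n = cfg.n_patients
    target = cfg.month1_unmutated_mean
    # weight month-1 depleters by their probability of yielding a usable sample
    w_d = n_depleted_m1 * (1.0 - cfg.missing_sample_rate)
    w_p = n - n_depleted_m1
    # "natural" depleted mean: the configured month-1 normal truncated below
    # the threshold
    m_d = _tn_mean(cfg.month1_unmutated_mean, cfg.month1_unmutated_sd, lo_d, hi_d)
    if w_p <= 0:
        return m_d, None
    m_p = (target * (w_d + w_p) - w_d * m_d) / w_p
    lo_mp, hi_mp = threshold + 0.6, 30.0
    if m_p < lo_mp or m_p > hi_mp:
        m_p = min(max(m_p, lo_mp), hi_mp)
        if w_d > 0:
            m_d = (target * (w_d + w_p) - w_p * m_p) / w_d
            m_d = min(max(m_d, lo_d + 0.2), hi_d - 0.2)
    return m_d, m_p


def _plant_pct_trajectories(
    cfg: SimulationConfig,
    endpoints: list[tuple],
    baselines: np.ndarray,
    threshold: float,
    rng: np.random.Generator,
) -> list[dict]:
    """Percent-unmutated value per (patient, month), threshold-consistent."""
    n_depleted_m1 = sum(1 for d, _ in endpoints if d == 1)
    m_d, m_p = _solve_month1_means(cfg, threshold, n_depleted_m1)
    lo_d, hi_d = THRESHOLD_MARGIN, threshold - THRESHOLD_MARGIN
    lo_hi = threshold + THRESHOLD_MARGIN
    trajectories = []
    for pidx, (d, r) in enumerate(endpoints):
        values = {}
        for month in cfg.visit_months:
            if month == 0:
                values[0] = float(baselines[pidx])
            elif month < d:
                values[month] = float(
                    _draw_truncnorm(m_p if m_p is not None else lo_hi + 3.0,
                                    PENDING_SD, lo_hi, 100.0, 1, rng)[0]
                )
            elif r is None or month < r:
                values[month] = float(
                    _draw_truncnorm(m_d, cfg.month1_unmutated_sd,
                                    lo_d, hi_d, 1, rng)[0]
                )
            else:
                values[month] = float(
                    _draw_truncnorm(max(REPOP_MEAN, threshold + 3.0), REPOP_SD,
                                    lo_hi, 100.0, 1, rng)[0]
                )
        trajectories.append(values)
    return trajectories


def _plant_sample_status(
    cfg: SimulationConfig, endpoints: list[tuple], rng: np.random.Generator
) -> list[dict]:
    """Sample status per (patient, month): failures only at depleted visits,
    not-collected only at depleted visits strictly inside the planted episode,
    so neither can disturb endpoint recovery."""
    statuses = []
    for d, r in endpoints:
        status = {}
        for month in cfg.visit_months:
            state = "ok"
            depleted = month >= d and (r is None or month < r) and month > 0
            if depleted:
                u = rng.random()
                if u < cfg.missing_sample_rate:
                    state = "failed_amplification"
                elif month > d and u < cfg.missing_sample_rate + NOT_COLLECTED_RATE:
                    state = "not_collected"
            status[month] = state
        statuses.append(status)
    return statuses


def _plant_das28(
    cfg: SimulationConfig, endpoints: list[tuple], rng: np.random.Generator
) -> list[dict]:
    """DAS28 per (patient, month): baseline draw, drifting random walk to
    month 6, then the group-specific month-6 to month-12 increment."""
    out = []
    for d, r in endpoints:
        early = r is not None and r <= 6
        scores = {}
        prev = float(
            np.clip(rng.normal(cfg.das28_baseline_mean, cfg.das28_baseline_sd),
                    0.5, 9.5)
        )
        for month in cfg.visit_months:
            if month == 0:
                scores[0] = prev
                continue
            if month >= 12:
                if early:
                    step = rng.normal(cfg.delta_das28_6to12_early_mean,
                                      cfg.delta_das28_6to12_early_sd)
                else:
                    step = rng.normal(cfg.delta_das28_6to12_late_mean,
                                      cfg.delta_das28_6to12_late_sd)
            else:
                step = rng.normal(*DAS28_STEP)
            prev = float(np.clip(prev + step, 0.0, 10.0))
            scores[month] = prev
        out.append(scores)
    return out


def _plant_ada(
    cfg: SimulationConfig, endpoints: list[tuple], rng: np.random.Generator
) -> list[bool]:
    """ADA status by Bayes inversion of the configured repopulation-given-ADA
    probabilities, conditioned on the planted repopulation status."""
    p_repop = (
        cfg.p_ada * cfg.p_repop_given_ada
        + (1.0 - cfg.p_ada) * cfg.p_repop_given_no_ada
    )
    if 0.0 < p_repop < 1.0:
        p_ada_repop = cfg.p_repop_given_ada * cfg.p_ada / p_repop
        p_ada_norep = (
            (1.0 - cfg.p_repop_given_ada) * cfg.p_ada / (1.0 - p_repop)
        )
    else:
        p_ada_repop = p_ada_norep = cfg.p_ada
    out = []
    for _, r in endpoints:
        p = p_ada_repop if r is not None else p_ada_norep
        out.append(bool(rng.random() < min(max(p, 0.0), 1.0)))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate one cohort entirely in memory.

    Identical config and seed give identical output. Repertoires are built
    only for visits with sample_status 'ok'.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pool = GermlinePool.build(rng)

    endpoints = _plant_endpoints(cfg, rng)
    baselines, threshold = _draw_baselines(cfg, rng)
    trajectories = _plant_pct_trajectories(cfg, endpoints, baselines, threshold, rng)
    statuses = _plant_sample_status(cfg, endpoints, rng)
    das28 = _plant_das28(cfg, endpoints, rng)
    ada = _plant_ada(cfg, endpoints, rng)

    patients, truth, planted_pct = [], [], {}
    for idx in range(cfg.n_patients):
        pid = f"P{idx + 1:02d}"
        d, r = endpoints[idx]
        visits, repertoires = [], {}
        for month in cfg.visit_months:
            status = statuses[idx][month]
            das = das28[idx][month]
            if month > 0 and rng.random() < DAS28_MISSING_RATE:
                das = None
            visits.append(
                ClinicalVisit(
                    patient_id=pid,
                    visit_month=month,
                    das28=None if das is None else round(das, 2),
                    das28_basis="ESR" if rng.random() < 0.15 else "CRP",
                    sample_status=status,
                    retreated_at_this_visit=(
                        month == 6 and rng.random() < RETREAT_RATE
                    ),
                )
            )
            planted_pct[(pid, month)] = trajectories[idx][month]
            if status != "ok":
                continue
            gini_t, shannon_t, mut_t, n_lin = _visit_targets(cfg, month)
            repertoires[month] = generate_repertoire(
                n_lineages=min(n_lin, cfg.clonotypes_per_sample),
                n_clonotypes=cfg.clonotypes_per_sample,
                unmutated_frac=trajectories[idx][month],
                gini_target=round(
                    _jitter(gini_t, GINI_JITTER, rng, 0.02, 0.92), 2
                ),
                mutload_mean=round(
                    _jitter(mut_t, MUTLOAD_JITTER, rng, 0.005, 0.25), 4
                ),
                rng=rng,
                shannon_target=round(
                    _jitter(
                        shannon_t, SHANNON_JITTER, rng, 0.0,
                        math.log(min(n_lin, cfg.clonotypes_per_sample)) - 0.02,
                    ),
                    2,
                ),
                germline_pool=pool,
                patient_id=pid,
                visit_month=month,
            )
        patients.append(
            PatientRecord(
                patient_id=pid,
                visits=visits,
                repertoires=repertoires,
                ada_positive_within_12m=ada[idx],
            )
        )
        truth.append(
            PatientTruth(
                patient_id=pid,
                true_depletion_month=d,
                true_repopulation_month=r,
                repopulator_class_true="early" if (r is not None and r <= 6) else "late",
                ada_positive=ada[idx],
            )
        )
    return SimulatedCohort(
        config=cfg,
        patients=patients,
        truth=truth,
        planted_threshold=threshold,
        planted_pct=planted_pct,
    )


def generate_cohort(config: SimulationConfig, out_dir: str | Path) -> tuple:
    """Simulate a cohort and write it to disk.

    Writes one AIRR TSV per (patient, visit with an 'ok' sample) under
    ``out_dir/airr/``, plus ``clinical.csv`` and ``truth.csv``. Returns
    (manifest, truth) where manifest maps (patient_id, visit_month) to the
    written TSV path. Identical config and seed give byte-identical files.
    Configuration errors are raised before anything is written.
    """
    sim = simulate_cohort(config)
    out = Path(out_dir)
    airr_dir = out / "airr"
    airr_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for patient in sim.patients:
        for month, records in sorted(patient.repertoires.items()):
            path = airr_dir / f"{patient.patient_id}_M{month}.tsv"
            write_rearrangements(records, path)
            manifest[(patient.patient_id, month)] = path
    write_clinical_table(sim.patients, out / "clinical.csv")
    write_truth_table(sim.truth, out / "truth.csv")
    return manifest, sim.truth


# ---------------------------------------------------------------------------
# Truth table I/O


def write_truth_table(truth: Sequence[PatientTruth], path: str | Path) -> None:
    """One CSV row per patient; absent endpoint months are empty cells."""
    import pandas as pd

    rows = [
        {
            "patient_id": t.patient_id,
            "true_depletion_month": (
                "" if t.true_depletion_month is None else t.true_depletion_month
            ),
            "true_repopulation_month": (
                "" if t.true_repopulation_month is None else t.true_repopulation_month
            ),
            "repopulator_class_true": t.repopulator_class_true,
            "ada_positive": "T" if t.ada_positive else "F",
        }
        for t in truth
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "true_depletion_month",
            "true_repopulation_month",
            "repopulator_class_true",
            "ada_positive",
        ],
    ).to_csv(path, index=False, lineterminator="\n")


def read_truth_table(path: str | Path) -> list[PatientTruth]:
    import pandas as pd

    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in table.itertuples(index=False):
        out.append(
            PatientTruth(
                patient_id=str(row.patient_id),
                true_depletion_month=(
                    None
                    if row.true_depletion_month == ""
                    else int(float(row.true_depletion_month))
                ),
                true_repopulation_month=(
                    None
                    if row.true_repopulation_month == ""
                    else int(float(row.true_repopulation_month))
                ),
                repopulator_class_true=str(row.repopulator_class_true),
                ada_positive=str(row.ada_positive).upper() in ("T", "TRUE", "1"),
            )
        )
    return out
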