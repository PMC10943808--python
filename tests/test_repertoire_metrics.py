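"""Clonotype assignment, lineage clustering and the four repertoire indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcelldyn.errors import ParameterError, UndefinedMetricError, ValidationError
from bcelldyn.repertoire_metrics import (
    Clonotype,
    assign_clonotypes,
    cluster_lineages,
    compute_sample_metrics,
    filter_by_umi_support,
    gini_expansion,
    mutation_load,
    pct_unmutated,
    shannon_lineage_diversity,
)

from conftest import make_record

# ---------------------------------------------------------------------------
# UMI filter


def test_umi_filter_keeps_at_least_three_umis():
    records = [make_record(sequence_id=f"S{c}", consensus_count=c) for c in (1, 2, 3, 5)]
    kept = filter_by_umi_support(records)
    assert [r.consensus_count for r in kept] == [3, 5]


def test_umi_filter_min_one_is_identity_and_empty_passthrough():
    records = [make_record(consensus_count=c) for c in (1, 2)]
    assert filter_by_umi_support(records, min_umis=1) == records
    assert filter_by_umi_support([], min_umis=3) == []
    with pytest.raises(ParameterError):
        filter_by_umi_support(records, min_umis=0)


# ---------------------------------------------------------------------------
# Clonotype assignment

GERM = "ACGT" * 80  # 320 columns, long enough to cover the V region


def test_identical_rearrangements_collapse_and_sum_umis():
    a = make_record(sequence_id="A", consensus_count=4, germline_alignment=GERM)
    b = make_record(sequence_id="B", consensus_count=6, germline_alignment=GERM)
    clonotypes = assign_clonotypes([a, b])
    assert len(clonotypes) == 1
    assert clonotypes[0].umi_count == 10
    assert clonotypes[0].abundance_pct == pytest.approx(100.0)


def test_single_nucleotide_difference_separates_clonotypes():
    a = make_record(sequence_id="A", germline_alignment=GERM)
    seq = "T" + GERM[1:]
    b = make_record(sequence_id="B", sequence_alignment=seq, germline_alignment=GERM)
    clonotypes = assign_clonotypes([a, b])
    assert len(clonotypes) == 2
    by_id = {c.mutation_count for c in clonotypes}
    assert by_id == {0, 1}


def test_abundance_percent_arithmetic():
    a = make_record(sequence_id="A", consensus_count=5, germline_alignment=GERM)
    seq = "T" + GERM[1:]
    b = make_record(
        sequence_id="B",
        consensus_count=15,
        sequence_alignment=seq,
        germline_alignment=GERM,
    )
    clonotypes = assign_clonotypes([a, b])
    assert sorted(c.abundance_pct for c in clonotypes) == [25.0, 75.0]
    assert sum(c.abundance_pct for c in clonotypes) == pytest.approx(100.0)


def test_gap_and_n_columns_are_excluded_from_both_counts():
    germ = "AC.GTN" + "A" * 306  # 312 columns
    seq = "GC.GTN" + "A" * 306  # mismatch at column 0 only
    rec = make_record(sequence_alignment=seq, germline_alignment=germ)
    (clonotype,) = assign_clonotypes([rec])
    assert clonotype.mutation_count == 1
    assert clonotype.ighv_aligned_length == 310  # 312 minus gap and N columns


def test_mutations_beyond_v_region_do_not_count():
    germ = "A" * 330
    seq = "A" * 312 + "C" * 18  # differences only after IMGT position 312
    rec = make_record(sequence_alignment=seq, germline_alignment=germ)
    (clonotype,) = assign_clonotypes([rec])
    assert clonotype.mutation_count == 0


def test_representative_is_highest_count_then_smallest_id():
    germ = GERM
    low = make_record(sequence_id="A", consensus_count=3, germline_alignment=germ)
    high = make_record(sequence_id="Z", consensus_count=9, germline_alignment=germ)
    (clonotype,) = assign_clonotypes([low, high])
    # both members identical here, so just check determinism of the junction
    assert clonotype.junction == high.junction
    assert assign_clonotypes([]) == []


# ---------------------------------------------------------------------------
# Gini


def test_gini_examples():
    assert gini_expansion([5, 5, 5, 5]) == pytest.approx(0.0)
    assert gini_expansion([1, 1, 1, 97]) == pytest.approx(0.72)
    with pytest.raises(UndefinedMetricError):
        gini_expansion([])
    with pytest.raises(ValidationError):
        gini_expansion([3, 0, 2])


def _gini_mad_oracle(counts):
    x = np.asarray(counts, dtype=float)
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2 * x.mean()))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=200))
def test_gini_matches_mean_absolute_difference_oracle(counts):
    assert gini_expansion(counts) == pytest.approx(
        _gini_mad_oracle(counts), abs=1e-10
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=1, max_value=1000), min_size=2, max_size=50),
    st.integers(min_value=2, max_value=1000),
)
def test_gini_is_scale_invariant(counts, k):
    assert gini_expansion(counts) == pytest.approx(
        gini_expansion([c * k for c in counts]), abs=1e-12
    )


def test_gini_transfer_principle():
    # moving a UMI from a poorer to a richer clonotype increases inequality
    assert gini_expansion([10, 10, 30]) < gini_expansion([9, 10, 31])
    assert gini_expansion([5, 20]) < gini_expansion([4, 21])


# ---------------------------------------------------------------------------
# Shannon


def test_shannon_examples():
    assert shannon_lineage_diversity([10]) == pytest.approx(0.0)
    assert shannon_lineage_diversity([1, 1, 1, 1]) == pytest.approx(math.log(4))
    assert shannon_lineage_diversity([2, 1, 1]) == pytest.approx(1.5 * math.log(2))
    with pytest.raises(ValidationError):
        shannon_lineage_diversity([1, 0])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=40))
def test_shannon_permutation_invariant_and_bounded(counts):
    h = shannon_lineage_diversity(counts)
    assert h == pytest.approx(shannon_lineage_diversity(counts[::-1]), abs=1e-12)
    assert -1e-12 <= h <= math.log(len(counts)) + 1e-12
    if len(set(counts)) == 1:
        assert h == pytest.approx(math.log(len(counts)))


# ---------------------------------------------------------------------------
# Mutation load and percent unmutated


def _clonotype(mutations, length=300, umis=5, junction="TGTAAATGG"):
    return Clonotype(
        v_call="IGHV1-1*01",
        d_call="",
        j_call="IGHJ4*01",
        sequence="A" * length,
        junction=junction,
        umi_count=umis,
        abundance_pct=0.0,
        mutation_count=mutations,
        ighv_aligned_length=length,
    )


def test_mutation_load_examples():
    assert mutation_load([_clonotype(0), _clonotype(0)]) == 0.0
    assert mutation_load([_clonotype(15)]) == pytest.approx(0.05)
    with pytest.raises(UndefinedMetricError):
        mutation_load([])


def test_pct_unmutated_examples_and_umi_invariance():
    clones = [_clonotype(m) for m in (0, 0, 3, 5, 7)]
    assert pct_unmutated(clones) == pytest.approx(40.0)
    assert pct_unmutated([_clonotype(0)] * 3) == pytest.approx(100.0)
    heavy = [_clonotype(m, umis=u) for m, u in ((0, 1000), (0, 1), (3, 1), (5, 1), (7, 1))]
    assert pct_unmutated(heavy) == pytest.approx(40.0)  # clonotype-weighted
    assert pct_unmutated(clones, max_mutations=3) == pytest.approx(60.0)


# ---------------------------------------------------------------------------
# Lineage clustering


def test_identical_junctions_one_lineage():
    clones = [_clonotype(0, junction="TGTAAAAATGG") for _ in range(3)]
    clustered = cluster_lineages(clones)
    assert len({c.lineage_id for c in clustered}) == 1


def test_fully_different_junctions_distinct_lineages():
    clones = [
        _clonotype(0, junction="A" * 10),
        _clonotype(0, junction="C" * 10),
        _clonotype(0, junction="G" * 10),
    ]
    clustered = cluster_lineages(clones)
    assert len({c.lineage_id for c in clustered}) == 3


def test_single_linkage_chains_through_intermediates():
    # A-B 0.1, B-C 0.1 but A-C 0.2: single linkage joins all three at 0.15
    a = _clonotype(0, junction="AAAAAAAAAA")
    b = _clonotype(0, junction="CAAAAAAAAA")
    c = _clonotype(0, junction="CAAAAAAAAG")
    clustered = cluster_lineages([a, b, c])
    assert len({x.lineage_id for x in clustered}) == 1


def test_lineage_ids_are_dense_and_order_of_first_appearance():
    clones = [
        _clonotype(0, junction="A" * 12),
        _clonotype(0, junction="C" * 12),
        _clonotype(0, junction="A" * 12),
    ]
    clustered = cluster_lineages(clones)
    assert [c.lineage_id for c in clustered] == [0, 1, 0]
    with pytest.raises(ParameterError):
        cluster_lineages(clones, junction_distance_threshold=1.5)


def _brute_force_lineages(clones, threshold):
    """Transitive closure over all pairs (independent oracle)."""
    n = len(clones)
    def linked(i, j):
        a, b = clones[i], clones[j]
        if (
            a.v_call.split("*")[0] != b.v_call.split("*")[0]
            or a.j_call.split("*")[0] != b.j_call.split("*")[0]
            or len(a.junction) != len(b.junction)
        ):
            return False
        d = sum(x != y for x, y in zip(a.junction, b.junction)) / len(a.junction)
        return d <= threshold

    adj = [[linked(i, j) for j in range(n)] for i in range(n)]
    labels = [-1] * n
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        while stack:
            i = stack.pop()
            if labels[i] >= 0:
                continue
            labels[i] = current
            stack.extend(j for j in range(n) if adj[i][j] and labels[j] < 0)
        current += 1
    return labels


def test_single_linkage_agrees_with_brute_force_transitive_closure():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(1, 31))
        clones = []
        for _i in range(n):
            junction = "".join(
                rng.choice(list("ACGT"), size=int(rng.choice([8, 8, 8, 12])))
            )
            clones.append(
                Clonotype(
                    v_call=f"IGHV{rng.integers(1, 3)}-1*01",
                    d_call="",
                    j_call=f"IGHJ{rng.integers(1, 3)}*01",
                    sequence="A",
                    junction=junction,
                    umi_count=3,
                    abundance_pct=0.0,
                    mutation_count=0,
                    ighv_aligned_length=100,
                )
            )
        threshold = float(rng.choice([0.15, 0.3, 0.5]))
        ours = [
            c.lineage_id
            for c in cluster_lineages(clones, junction_distance_threshold=threshold)
        ]
        oracle = _brute_force_lineages(clones, threshold)
        # same partition up to relabeling
        mapping = {}
        for a, b in zip(ours, oracle):
            assert mapping.setdefault(a, b) == b
        assert len(set(ours)) == len(set(oracle))


# ---------------------------------------------------------------------------
# Sample pipeline


def test_uniform_unmutated_sample_metrics():
    germ = "ACGT" * 78 + "A" * 12  # 312 V columns + a 12-column tail
    records = []
    for i, junction in enumerate(["TGTAAATGG"] * 4):
        seq = germ[:312] + "ACGT"[i] * 12  # records differ only beyond the V region
        records.append(
            make_record(
                sequence_id=f"S{i}",
                sequence_alignment=seq,
                germline_alignment=germ,
                junction=junction,
                consensus_count=5,
            )
        )
    metrics = compute_sample_metrics(records)
    assert metrics.n_clonotypes == 4
    assert metrics.n_lineages == 1
    assert metrics.gini == pytest.approx(0.0)
    assert metrics.shannon == pytest.approx(0.0)
    assert metrics.mean_mutation_freq == pytest.approx(0.0)
    assert metrics.pct_unmutated == pytest.approx(100.0)


def test_sample_with_no_umi_support_is_undefined():
    records = [make_record(sequence_id=f"S{i}", consensus_count=2) for i in range(5)]
    metrics = compute_sample_metrics(records)
    assert not metrics.is_defined
    assert metrics.gini is None


def test_synthetic_sample_metrics_near_generator_targets(small_sim):
    sample = small_sim.patients[0].repertoires[0]
    metrics = compute_sample_metrics(sample)
    planted = small_sim.planted_pct[(small_sim.patients[0].patient_id, 0)]
    assert metrics.pct_unmutated == pytest.approx(planted, abs=0.3)
    assert 0.0 <= metrics.gini < 1.0
    assert metrics.shannon <= math.log(metrics.n_lineages) + 1e-9
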