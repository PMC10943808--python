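"""Per-sample repertoire statistics.

A clonotype is a unique IGHV-IGHD-IGHJ rearrangement at the nucleotide
level; its abundance is the number of distinct UMIs (consensus_count sums)
supporting it. From the clonotype table we compute

* clonal expansion   — Gini inequality coefficient of UMIs per clonotype,
* clonal diversity   — Shannon entropy (nats) of clonotypes per lineage,
* SHM load           — mean IGHV mutation frequency (mutations/bp),
* percent unmutated  — share of clonotypes with zero IGHV mismatches.

Mutation counting compares the IMGT-gapped sequence/germline pair over the
V region (alignment columns up to the end of FWR3, IMGT position 312),
skipping columns where either side has a gap or an N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort_io import RearrangementRecord
from .errors import ParameterError, UndefinedMetricError, ValidationError

logger = logging.getLogger(__name__)

#: Last IMGT-gapped alignment column of the IGHV region (end of FWR3).
IMGT_V_REGION_END = 312

#: Minimum distinct UMIs for a consensus sequence to enter the analysis.
DEFAULT_MIN_UMIS = 3

#: Normalized Hamming distance threshold for junction-based lineage clustering.
DEFAULT_JUNCTION_THRESHOLD = 0.15

_GAP_CHARS = frozenset(b".-")


@dataclass(slots=True)
class Clonotype:
    """A unique rearrangement with aggregated UMI support and SHM summary."""

    v_call: str
    d_call: str
    j_call: str
    sequence: str  # ungapped rearrangement nucleotide sequence
    junction: str
    umi_count: int
    abundance_pct: float
    mutation_count: int
    ighv_aligned_length: int
    lineage_id: int = -1

    @property
    def mutation_freq(self) -> float:
        return self.mutation_count / self.ighv_aligned_length


@dataclass(slots=True)
class SampleMetrics:
    """Repertoire summary for one patient visit.

    All metric fields are ``None`` when the sample is undefined (e.g. no
    record survives the UMI filter); ``undefined_reason`` then says why and
    the sample is treated downstream like a failed one.
    """

    patient_id: str
    visit_month: int
    n_clonotypes: int = 0
    n_lineages: int = 0
    total_umis: int = 0
    gini: Optional[float] = None
    shannon: Optional[float] = None
    mean_mutation_freq: Optional[float] = None
    pct_unmutated: Optional[float] = None
    undefined_reason: Optional[str] = None

    @property
    def is_defined(self) -> bool:
        return self.undefined_reason is None


# ---------------------------------------------------------------------------
# Filtering and clonotype assignment


def filter_by_umi_support(
    records: Sequence[RearrangementRecord], min_umis: int = DEFAULT_MIN_UMIS
) -> list[RearrangementRecord]:
    """Keep records supported by at least ``min_umis`` distinct UMIs."""
    if min_umis < 1:
        raise ParameterError(f"min_umis must be >= 1, got {min_umis}")
    return [r for r in records if r.consensus_count >= min_umis]


def _ungap(sequence: str) -> str:
    return sequence.replace(".", "").replace("-", "")


def _count_v_mismatches_batch(
    seqs: Sequence[str], germs: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatches and comparable lengths over the IGHV alignment columns,
    vectorized over records. Alignments shorter than the V region are padded;
    pad columns are skipped like gaps."""
    if not seqs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = np.array(seqs, dtype=f"S{IMGT_V_REGION_END}").view(np.uint8)
    g = np.array(germs, dtype=f"S{IMGT_V_REGION_END}").view(np.uint8)
    s = s.reshape(len(seqs), -1)[:, :IMGT_V_REGION_END]
    g = g.reshape(len(germs), -1)[:, :IMGT_V_REGION_END]
    skip = np.zeros(s.shape, dtype=bool)
    for ch in b".-N\x00":
        skip |= s == ch
        skip |= g == ch
    comparable = (~skip).sum(axis=1).astype(int)
    mismatches = ((s != g) & ~skip).sum(axis=1).astype(int)
    return mismatches, comparable


def _count_v_mismatches(seq: str, germ: str) -> tuple[int, int]:
    """Single-pair convenience wrapper around the batched counter."""
    mm, comp = _count_v_mismatches_batch([seq], [germ])
    return int(mm[0]), int(comp[0])


def assign_clonotypes(records: Sequence[RearrangementRecord]) -> list[Clonotype]:
    """Collapse records into clonotypes keyed by (V, D, J, ungapped sequence).

    UMI counts are summed over member records; mutation statistics come from
    a single representative member — the highest consensus_count, ties broken
    by lexicographically smallest sequence_id — so the result is deterministic
    and matches the clonotype granularity of the percent-unmutated analysis.
    """
    # single pass: aggregate UMIs and track the representative per key
    # (attributes pulled out first: C-level access dominates this hot loop)
    v_calls = [r.v_call for r in records]
    d_calls = [r.d_call for r in records]
    j_calls = [r.j_call for r in records]
    seqs = [_ungap(r.sequence_alignment) for r in records]
    umi_counts = [r.consensus_count for r in records]
    agg: dict[tuple[str, str, str, str], list] = {}
    order: list[tuple[str, str, str, str]] = []
    total_umis = 0
    for rec, v, d, j, s, cc in zip(records, v_calls, d_calls, j_calls, seqs, umi_counts):
        total_umis += cc
        key = (v, d, j, s)
        entry = agg.get(key)
        if entry is None:
            agg[key] = [rec, cc]
            order.append(key)
        else:
            entry[1] += cc
            cur = entry[0]
            if (-cc, rec.sequence_id) < (-cur.consensus_count, cur.sequence_id):
                entry[0] = rec

    reps = [agg[key][0] for key in order]
    mutations, comparable = _count_v_mismatches_batch(
        [r.sequence_alignment for r in reps],
        [r.germline_alignment for r in reps],
    )
    for rep, comp in zip(reps, comparable):
        if comp == 0:
            raise ValidationError(
                f"sequence {rep.sequence_id!r}: no comparable IGHV positions"
            )
    clonotypes: list[Clonotype] = []
    for key, rep, mut, comp in zip(order, reps, mutations, comparable):
        umis = agg[key][1]
        clonotypes.append(
            Clonotype(
                v_call=key[0],
                d_call=key[1],
                j_call=key[2],
                sequence=key[3],
                junction=rep.junction,
                umi_count=umis,
                abundance_pct=100.0 * umis / total_umis,
                mutation_count=int(mut),
                ighv_aligned_length=int(comp),
            )
        )
    return clonotypes


# ---------------------------------------------------------------------------
# Lineage clustering


def _v_gene(call: str) -> str:
    return call.split("*")[0]


def cluster_lineages(
    clonotypes: Sequence[Clonotype],
    junction_distance_threshold: float = DEFAULT_JUNCTION_THRESHOLD,
) -> list[Clonotype]:
    """Assign dense lineage labels by single-linkage junction clustering.

    Clonotypes sharing V gene (allele stripped), J gene and junction length
    are candidates; pairs at normalized Hamming distance <= threshold are
    linked, and connected components share a lineage. Labels are dense
    integers in order of first member appearance. Returns the same clonotype
    objects with ``lineage_id`` set.
    """
    if not 0.0 <= junction_distance_threshold <= 1.0:
        raise ParameterError(
            f"junction_distance_threshold must be in [0, 1], "
            f"got {junction_distance_threshold}"
        )
    for c in clonotypes:
        if not c.junction:
            raise ValidationError("clonotype with empty junction cannot be clustered")

    n = len(clonotypes)
    gene_cache: dict[str, str] = {}

    def gene(call: str) -> str:
        g = gene_cache.get(call)
        if g is None:
            g = gene_cache[call] = call.split("*")[0]
        return g

    junctions = [c.junction for c in clonotypes]
    group_keys = [
        (gene(c.v_call), gene(c.j_call), len(j))
        for c, j in zip(clonotypes, junctions)
    ]
    groups: dict[tuple[str, str, int], list[int]] = {}
    for idx, key in enumerate(group_keys):
        bucket = groups.get(key)
        if bucket is None:
            groups[key] = [idx]
        else:
            bucket.append(idx)

    # candidate groups are disjoint, so components never span groups
    component_of = np.empty(n, dtype=int)
    next_label = 0
    for indices in groups.values():
        if len(indices) == 1:
            component_of[indices[0]] = next_label
            next_label += 1
            continue
        length = len(junctions[indices[0]])
        if len(indices) == 2:  # dominant case: direct pairwise comparison
            a = junctions[indices[0]]
            b = junctions[indices[1]]
            d = sum(x != y for x, y in zip(a, b)) / length
            if d <= junction_distance_threshold:
                component_of[indices[0]] = component_of[indices[1]] = next_label
                next_label += 1
            else:
                component_of[indices[0]] = next_label
                component_of[indices[1]] = next_label + 1
                next_label += 2
            continue
        mat = np.frombuffer(
            "".join(junctions[i] for i in indices).encode(), dtype=np.uint8
        ).reshape(len(indices), length)
        m = len(indices)
        cutoff = junction_distance_threshold * length
        adjacency = np.empty((m, m), dtype=bool)
        for start in range(0, m, 512):  # bound the broadcast intermediate
            block = (mat[start : start + 512, None, :] != mat[None, :, :]).sum(axis=2)
            adjacency[start : start + 512] = block <= cutoff
        # transitive closure by breadth-first expansion over the adjacency
        local = np.full(m, -1, dtype=int)
        n_comp = 0
        while True:
            seeds = np.nonzero(local < 0)[0]
            if seeds.size == 0:
                break
            comp = adjacency[seeds[0]].copy()
            comp[seeds[0]] = True
            while True:
                grown = adjacency[comp].any(axis=0)
                if (grown & ~comp).any():
                    comp |= grown
                else:
                    break
            local[comp] = n_comp
            n_comp += 1
        component_of[np.asarray(indices)] = local + next_label
        next_label += n_comp

    # dense lineage ids in order of first member appearance
    labels: dict[int, int] = {}
    for idx, c in enumerate(clonotypes):
        comp = int(component_of[idx])
        if comp not in labels:
            labels[comp] = len(labels)
        c.lineage_id = labels[comp]
    return list(clonotypes)


# ---------------------------------------------------------------------------
# Indices


def gini_expansion(umi_counts: Sequence[int]) -> float:
    """Lorenz-curve Gini inequality coefficient of UMIs per clonotype.

    With counts sorted ascending x1..xn:
    G = (2 * sum(i * x_i)) / (n * sum(x)) - (n + 1) / n, in [0, 1).
    """
    counts = np.asarray(umi_counts, dtype=float)
    if counts.size == 0:
        raise UndefinedMetricError("Gini is undefined on an empty sample")
    if np.any(counts <= 0):
        raise ValidationError("UMI counts must all be positive")
    counts = np.sort(counts)
    n = counts.size
    ranks = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.sum(ranks * counts) / (n * counts.sum()) - (n + 1.0) / n)


def shannon_lineage_diversity(clonotypes_per_lineage: Sequence[int]) -> float:
    """Shannon entropy (natural log) of the clonotypes-per-lineage distribution."""
    counts = np.asarray(clonotypes_per_lineage, dtype=float)
    if counts.size == 0:
        raise UndefinedMetricError("Shannon index is undefined with no lineages")
    if np.any(counts <= 0):
        raise ValidationError("lineage sizes must all be positive")
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def mutation_load(clonotypes: Sequence[Clonotype]) -> float:
    """Unweighted mean mutation frequency (mutations/bp) over clonotypes."""
    if not clonotypes:
        raise UndefinedMetricError("mutation load is undefined on an empty sample")
    return float(np.mean([c.mutation_freq for c in clonotypes]))


def pct_unmutated(clonotypes: Sequence[Clonotype], max_mutations: int = 0) -> float:
    """Percent of clonotypes with at most ``max_mutations`` IGHV mismatches.

    Clonotype-weighted (each clonotype counts once regardless of UMIs): the
    quantity proxies the fraction of distinct naive-like rearrangements.
    """
    if not clonotypes:
        raise UndefinedMetricError("percent unmutated is undefined on an empty sample")
    hits = sum(1 for c in clonotypes if c.mutation_count <= max_mutations)
    return 100.0 * hits / len(clonotypes)


# ---------------------------------------------------------------------------
# Sample pipeline


def compute_sample_metrics(
    records: Sequence[RearrangementRecord],
    min_umis: int = DEFAULT_MIN_UMIS,
    junction_distance_threshold: float = DEFAULT_JUNCTION_THRESHOLD,
) -> SampleMetrics:
    """UMI filter -> clonotypes -> lineages -> all four indices for one sample."""
    if not records:
        return SampleMetrics(
            patient_id="", visit_month=-1, undefined_reason="no records in sample"
        )
    pid = records[0].patient_id
    month = records[0].visit_month
    kept = filter_by_umi_support(records, min_umis=min_umis)
    if not kept:
        logger.info(
            "sample %s month %s: no record with >= %d UMIs; metrics undefined",
            pid,
            month,
            min_umis,
        )
        return SampleMetrics(
            patient_id=pid,
            visit_month=month,
            undefined_reason=f"no record with >= {min_umis} UMIs",
        )
    clonotypes = assign_clonotypes(kept)
    clonotypes = cluster_lineages(
        clonotypes, junction_distance_threshold=junction_distance_threshold
    )
    lineage_sizes = np.bincount([c.lineage_id for c in clonotypes])
    lineage_sizes = lineage_sizes[lineage_sizes > 0]
    return SampleMetrics(
        patient_id=pid,
        visit_month=month,
        n_clonotypes=len(clonotypes),
        n_lineages=int(lineage_sizes.size),
        total_umis=sum(c.umi_count for c in clonotypes),
        gini=gini_expansion([c.umi_count for c in clonotypes]),
        shannon=shannon_lineage_diversity(lineage_sizes),
        mean_mutation_freq=mutation_load(clonotypes),
        pct_unmutated=pct_unmutated(clonotypes),
    )


def sample_pct_unmutated(
    records: Sequence[RearrangementRecord], min_umis: int = DEFAULT_MIN_UMIS
) -> Optional[float]:
    """Percent unmutated through the UMI-filter -> clonotype path only.

    Endpoint calling needs no lineage clustering, so this avoids it; returns
    None when no record survives the filter (sample treated as failed).
    """
    kept = filter_by_umi_support(records, min_umis=min_umis)
    if not kept:
        return None
    return pct_unmutated(assign_clonotypes(kept))


def compute_cohort_pct(cohort) -> "pd.DataFrame":  # noqa: F821
    """pct_unmutated per (patient, visit) — the minimal endpoint-calling input."""
    import pandas as pd

    rows = []
    for patient in cohort:
        for month in sorted(patient.repertoires):
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "visit_month": month,
                    "pct_unmutated": sample_pct_unmutated(
                        patient.repertoires[month]
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "visit_month", "pct_unmutated"]
    )


def compute_cohort_metrics(cohort) -> "pd.DataFrame":  # noqa: F821
    """SampleMetrics for every (patient, visit) with a repertoire, as a table."""
    import pandas as pd

    rows = []
    for patient in cohort:
        for month in sorted(patient.repertoires):
            m = compute_sample_metrics(patient.repertoires[month])
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "visit_month": month,
                    "n_clonotypes": m.n_clonotypes,
                    "n_lineages": m.n_lineages,
                    "total_umis": m.total_umis,
                    "gini": m.gini,
                    "shannon": m.shannon,
                    "mean_mutation_freq": m.mean_mutation_freq,
                    "pct_unmutated": m.pct_unmutated,
                    "undefined_reason": m.undefined_reason or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "visit_month",
            "n_clonotypes",
            "n_lineages",
            "total_umis",
            "gini",
            "shannon",
            "mean_mutation_freq",
            "pct_unmutated",
            "undefined_reason",
        ],
    )
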