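"""Shared fixtures: small synthetic cohorts and hand-built AIRR fixtures."""

from __future__ import annotations

import pytest

from bcelldyn.cohort_io import RearrangementRecord
from bcelldyn.synthetic_cohort import SimulationConfig, simulate_cohort

#: A reduced cohort: same structure as the default study conditions but small
#: enough for unit tests.
SMALL_KWARGS = dict(
    n_patients=6,
    clonotypes_per_sample=400,
    n_lineages_baseline=150,
    baseline_shannon_target=4.6,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, **SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


def make_record(
    sequence_id="S1",
    patient_id="P01",
    visit_month=0,
    v_call="IGHV1-1*01",
    d_call="IGHD1-1*01",
    j_call="IGHJ4*01",
    junction="TGTGCGAGATGG",
    sequence_alignment=None,
    germline_alignment=None,
    consensus_count=5,
    productive=True,
):
    germ = germline_alignment if germline_alignment is not None else "ACGT" * 10
    seq = sequence_alignment if sequence_alignment is not None else germ
    return RearrangementRecord(
        sequence_id=sequence_id,
        patient_id=patient_id,
        visit_month=visit_month,
        v_call=v_call,
        d_call=d_call,
        j_call=j_call,
        junction=junction,
        sequence_alignment=seq,
        germline_alignment=germ,
        consensus_count=consensus_count,
        productive=productive,
    )


AIRR_HEADER = (
    "sequence_id\tv_call\td_call\tj_call\tjunction\t"
    "sequence_alignment\tgermline_alignment\tconsensus_count\tproductive"
)


def write_airr(path, rows):
    """Write an AIRR TSV from (id, v, d, j, junction, seq, germ, count, prod)."""
    lines = [AIRR_HEADER]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path
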