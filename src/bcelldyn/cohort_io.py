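"""Reading, writing and assembling the longitudinal cohort data model.

Repertoire input follows the AIRR Rearrangement standard (tab-separated,
header row, AIRR v1 field names); the clinical visit table is a plain CSV.
All downstream stages consume the :class:`PatientRecord` objects built here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Visit schedule in months since the first infusion.
VISIT_MONTHS = (0, 1, 3, 6, 12)

SAMPLE_STATUSES = ("ok", "failed_amplification", "not_collected")

#: Columns required in an AIRR rearrangement TSV.
AIRR_REQUIRED_COLUMNS = (
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "sequence_alignment",
    "germline_alignment",
    "consensus_count",
    "productive",
)

CLINICAL_COLUMNS = (
    "patient_id",
    "visit_month",
    "das28",
    "das28_basis",
    "sample_status",
    "retreated",
    "ada_positive_within_12m",
)


@dataclass(slots=True)
class RearrangementRecord:
    """One germline-aligned BCR heavy-chain consensus sequence with UMI support."""

    sequence_id: str
    patient_id: str
    visit_month: int
    v_call: str
    d_call: str
    j_call: str
    junction: str
    sequence_alignment: str
    germline_alignment: str
    consensus_count: int
    productive: bool

    def validate(self) -> None:
        if len(self.sequence_alignment) != len(self.germline_alignment):
            raise ValidationError(
                f"sequence {self.sequence_id!r}: sequence_alignment and "
                f"germline_alignment have different lengths "
                f"({len(self.sequence_alignment)} vs {len(self.germline_alignment)})"
            )
        if self.consensus_count < 1:
            raise ValidationError(
                f"sequence {self.sequence_id!r}: consensus_count must be >= 1"
            )
        if not self.v_call or not self.j_call:
            raise ValidationError(
                f"sequence {self.sequence_id!r}: v_call and j_call must be non-empty"
            )


@dataclass(slots=True)
class ClinicalVisit:
    """One scheduled assessment: disease activity plus sample bookkeeping."""

    patient_id: str
    visit_month: int
    das28: Optional[float]  # None = missing, never imputed here
    das28_basis: str  # "CRP" or "ESR"
    sample_status: str
    retreated_at_this_visit: bool = False

    def validate(self) -> None:
        if self.visit_month not in VISIT_MONTHS:
            raise ValidationError(
                f"patient {self.patient_id!r}: visit_month {self.visit_month} "
                f"not in schedule {VISIT_MONTHS}"
            )
        if self.das28 is not None and not (0.0 <= self.das28 <= 10.0):
            raise ValidationError(
                f"patient {self.patient_id!r} month {self.visit_month}: "
                f"das28 {self.das28} outside [0, 10]"
            )
        if self.sample_status not in SAMPLE_STATUSES:
            raise ValidationError(
                f"patient {self.patient_id!r} month {self.visit_month}: "
                f"unknown sample_status {self.sample_status!r}"
            )


@dataclass(slots=True)
class PatientRecord:
    """All visits of one patient plus the repertoires of visits with a usable sample."""

    patient_id: str
    visits: list[ClinicalVisit] = field(default_factory=list)
    repertoires: dict[int, list[RearrangementRecord]] = field(default_factory=dict)
    ada_positive_within_12m: Optional[bool] = None

    def visit(self, month: int) -> Optional[ClinicalVisit]:
        for v in self.visits:
            if v.visit_month == month:
                return v
        return None

    def validate(self) -> None:
        months = [v.visit_month for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError(
                f"patient {self.patient_id!r}: visit months not strictly increasing"
            )
        for month in self.repertoires:
            v = self.visit(month)
            if v is None or v.sample_status != "ok":
                raise ValidationError(
                    f"patient {self.patient_id!r}: repertoire present for month "
                    f"{month} whose sample_status is not 'ok'"
                )


# ---------------------------------------------------------------------------
# AIRR rearrangement I/O


def _parse_airr_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().upper()
    if text in ("T", "TRUE", "1"):
        return True
    if text in ("F", "FALSE", "0"):
        return False
    raise ValidationError(f"cannot interpret {value!r} as an AIRR boolean")


def read_rearrangements(
    path: str | Path, patient_id: str, visit_month: int
) -> list[RearrangementRecord]:
    """Read one AIRR Rearrangement TSV into records for a single patient visit.

    Rows with ``productive == False`` are dropped at read time so every
    downstream metric sees functional rearrangements only. Row order is
    preserved for the remaining rows.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required AIRR column(s): {', '.join(missing)}"
        )
    records: list[RearrangementRecord] = []
    for row in table.itertuples(index=False):
        if not _parse_airr_bool(row.productive):
            continue
        rec = RearrangementRecord(
            sequence_id=row.sequence_id,
            patient_id=patient_id,
            visit_month=visit_month,
            v_call=row.v_call,
            d_call=row.d_call,
            j_call=row.j_call,
            junction=row.junction,
            sequence_alignment=row.sequence_alignment,
            germline_alignment=row.germline_alignment,
            consensus_count=int(row.consensus_count),
            productive=True,
        )
        rec.validate()
        records.append(rec)
    return records


def write_rearrangements(
    records: Sequence[RearrangementRecord], path: str | Path
) -> None:
    """Write records to an AIRR Rearrangement TSV (round-trips losslessly)."""
    table = pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in records],
            "v_call": [r.v_call for r in records],
            "d_call": [r.d_call for r in records],
            "j_call": [r.j_call for r in records],
            "junction": [r.junction for r in records],
            "sequence_alignment": [r.sequence_alignment for r in records],
            "germline_alignment": [r.germline_alignment for r in records],
            "consensus_count": [r.consensus_count for r in records],
            "productive": ["T" if r.productive else "F" for r in records],
        }
    )
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Clinical table


def _parse_optional_float(value) -> Optional[float]:
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return None
    return float(text)


def _parse_optional_bool(value) -> Optional[bool]:
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return None
    return _parse_airr_bool(text)


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the clinical visit CSV into per-patient skeletons (visits only).

    Empty DAS28 cells become missing values (``None``), never zeros; they are
    excluded per analysis downstream.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required clinical column(s): {', '.join(missing)}"
        )
    seen: set[tuple[str, int]] = set()
    patients: dict[str, PatientRecord] = {}
    for row in table.itertuples(index=False):
        pid = str(row.patient_id)
        month = int(row.visit_month)
        key = (pid, month)
        if key in seen:
            raise ValidationError(
                f"duplicate clinical row for patient {pid!r} month {month}"
            )
        seen.add(key)
        visit = ClinicalVisit(
            patient_id=pid,
            visit_month=month,
            das28=_parse_optional_float(row.das28),
            das28_basis=str(row.das28_basis),
            sample_status=str(row.sample_status),
            retreated_at_this_visit=_parse_airr_bool(row.retreated),
        )
        visit.validate()
        patient = patients.setdefault(pid, PatientRecord(patient_id=pid))
        patient.visits.append(visit)
        ada = _parse_optional_bool(row.ada_positive_within_12m)
        if ada is not None:
            patient.ada_positive_within_12m = ada
    for patient in patients.values():
        patient.visits.sort(key=lambda v: v.visit_month)
        patient.validate()
    return list(patients.values())


def write_clinical_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        for v in p.visits:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "visit_month": v.visit_month,
                    "das28": "" if v.das28 is None else f"{v.das28:.2f}",
                    "das28_basis": v.das28_basis,
                    "sample_status": v.sample_status,
                    "retreated": "T" if v.retreated_at_this_visit else "F",
                    "ada_positive_within_12m": (
                        ""
                        if p.ada_positive_within_12m is None
                        else ("T" if p.ada_positive_within_12m else "F")
                    ),
                }
            )
    pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS)).to_csv(
        path, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Cohort assembly


def assemble_cohort(
    clinical: Sequence[PatientRecord],
    rearrangement_files: Mapping[tuple[str, int], str | Path],
) -> list[PatientRecord]:
    """Attach repertoires to clinical skeletons and apply the baseline rule.

    Patients with no baseline (month 0) repertoire are excluded from the
    cohort, mirroring the exclusion of patients whose baseline sample was
    never collected; missing follow-up repertoires are retained as absent
    with their sample status.
    """
    by_patient = {p.patient_id: p for p in clinical}
    for (pid, month), fpath in rearrangement_files.items():
        patient = by_patient.get(pid)
        if patient is None:
            raise ConsistencyError(f"repertoire file for unknown patient {pid!r}")
        visit = patient.visit(month)
        if visit is None:
            raise ConsistencyError(
                f"repertoire file for patient {pid!r} month {month} "
                f"with no matching clinical visit"
            )
        if visit.sample_status == "not_collected":
            raise ConsistencyError(
                f"repertoire supplied for patient {pid!r} month {month} "
                f"whose sample is marked not_collected"
            )
        patient.repertoires[month] = read_rearrangements(fpath, pid, month)

    cohort: list[PatientRecord] = []
    for patient in clinical:
        if 0 not in patient.repertoires:
            logger.info(
                "excluding patient %s: no baseline (month 0) repertoire",
                patient.patient_id,
            )
            continue
        patient.validate()
        cohort.append(patient)
    return cohort
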