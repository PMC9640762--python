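"""Facility survey records: data model, validation, and CSV/JSON I/O.

A dataset is a list of :class:`FacilityRecord`. Each record describes one
public health facility surveyed about its capacity to perform contraceptive
implant removals: a general-service checklist (infection-prevention items and
weekly service schedule), staffing counts (providers trained in removal and in
ultrasound use), an equipment/consumables checklist, and the facility this one
refers difficult cases to, if any.

Facilities known only as referral destinations (never surveyed) carry
``assessed=False`` and may omit the checklists; they stay in the dataset
because they participate in referral networks and geographic modeling.

Coordinates are planar meters in a projected CRS throughout the package; no
geodesic computation is performed anywhere (the study areas are
district-scale).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class District(str, Enum):
    DAKAR_CENTRE = "DAKAR_CENTRE"
    KOLDA = "KOLDA"


class FacilityType(str, Enum):
    HEALTH_POST = "HEALTH_POST"
    HEALTH_CENTER_I = "HEALTH_CENTER_I"
    HEALTH_CENTER_II = "HEALTH_CENTER_II"
    HOSPITAL = "HOSPITAL"


#: Equipment checklist item names, in canonical order. ``autoclave`` is
#: optional and reporting-only: it never enters readiness scoring.
EQUIPMENT_ITEMS: tuple[str, ...] = (
    "syringes",
    "local_anesthetic",
    "sterile_band_aids",
    "scalpel_with_blade",
    "curved_forceps",
    "straight_forceps",
    "antiseptic",
    "cotton_balls",
    "sterile_gauze",
    "vasectomy_forceps",
    "ultrasound_machine",
    "sterile_towels",
    "examination_table",
    "sterile_surgical_drape",
    "sterile_equipment_tray",
)


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


class DatasetError(ValueError):
    """Dataset-level contract violation (duplicate ids, dangling referrals)."""


@dataclass(frozen=True)
class GeneralServiceProfile:
    """Infection-prevention items and removal service schedule.

    ``removal_days_per_week`` must lie in [0, 7]; out-of-range values are
    surfaced by :func:`validate_dataset` rather than at construction, so a
    malformed survey row can still be loaded and reported.
    """

    running_water: bool
    decontamination_buckets: bool
    safety_boxes: bool
    soap: bool
    removal_days_per_week: int


@dataclass(frozen=True)
class StaffingProfile:
    """Counts of staff trained in implant removal and in ultrasound use."""

    n_trained_removal: int
    n_trained_ultrasound: int

    def __post_init__(self) -> None:
        if self.n_trained_removal < 0 or self.n_trained_ultrasound < 0:
            raise ValueError("staff counts must be non-negative")


@dataclass(frozen=True)
class EquipmentChecklist:
    """Observed availability of equipment and consumables (one boolean each)."""

    syringes: bool
    local_anesthetic: bool
    sterile_band_aids: bool
    scalpel_with_blade: bool
    curved_forceps: bool
    straight_forceps: bool
    antiseptic: bool
    cotton_balls: bool
    sterile_gauze: bool
    vasectomy_forceps: bool
    ultrasound_machine: bool
    sterile_towels: bool
    examination_table: bool
    sterile_surgical_drape: bool
    sterile_equipment_tray: bool
    autoclave: bool | None = None

    def __getitem__(self, item: str) -> bool:
        if item not in EQUIPMENT_ITEMS and item != "autoclave":
            raise KeyError(item)
        return getattr(self, item)


@dataclass(frozen=True)
class FacilityRecord:
    """One facility in the survey dataset."""

    facility_id: str
    district: District
    facility_type: FacilityType
    location: tuple[float, float]  # (x, y) meters, projected CRS
    general: GeneralServiceProfile | None = None
    staffing: StaffingProfile | None = None
    equipment: EquipmentChecklist | None = None
    refers_to: str | None = None
    assessed: bool = True

    def __post_init__(self) -> None:
        if self.refers_to is not None and self.refers_to == self.facility_id:
            raise ValueError(f"{self.facility_id}: refers_to must not be self")
        if self.assessed and (
            self.general is None or self.staffing is None or self.equipment is None
        ):
            raise ValueError(
                f"{self.facility_id}: assessed facility must carry all checklists"
            )


@dataclass
class ValidationIssue:
    facility_id: str | None
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.issues


# ---------------------------------------------------------------------------
# construction / validation
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "facility_id",
    "district",
    "facility_type",
    "x",
    "y",
    "assessed",
)
_GENERAL_FIELDS = (
    "running_water",
    "decontamination_buckets",
    "safety_boxes",
    "soap",
    "removal_days_per_week",
)
_STAFF_FIELDS = ("n_trained_removal", "n_trained_ultrasound")


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no"}:
        return False
    raise SchemaError(f"cannot interpret {value!r} as a boolean (use 0/1)")


def record_from_mapping(row: dict) -> FacilityRecord:
    """Build one :class:`FacilityRecord` from a flat row/object."""
    for col in _REQUIRED_COLUMNS:
        if col not in row or row[col] in ("", None):
            raise SchemaError(f"missing required column {col!r}")
    assessed = _parse_bool(row["assessed"])
    general = staffing = equipment = None
    if assessed:
        missing = [
            c
            for c in (*_GENERAL_FIELDS, *_STAFF_FIELDS, *EQUIPMENT_ITEMS)
            if c not in row or row[c] in ("", None)
        ]
        if missing:
            raise SchemaError(
                f"assessed facility {row['facility_id']!r} missing column(s): "
                + ", ".join(missing)
            )
        general = GeneralServiceProfile(
            running_water=_parse_bool(row["running_water"]),
            decontamination_buckets=_parse_bool(row["decontamination_buckets"]),
            safety_boxes=_parse_bool(row["safety_boxes"]),
            soap=_parse_bool(row["soap"]),
            removal_days_per_week=int(row["removal_days_per_week"]),
        )
        staffing = StaffingProfile(
            n_trained_removal=int(row["n_trained_removal"]),
            n_trained_ultrasound=int(row["n_trained_ultrasound"]),
        )
        autoclave = row.get("autoclave")
        equipment = EquipmentChecklist(
            **{item: _parse_bool(row[item]) for item in EQUIPMENT_ITEMS},
            autoclave=None if autoclave in ("", None) else _parse_bool(autoclave),
        )
    refers_to = row.get("refers_to") or None
    return FacilityRecord(
        facility_id=str(row["facility_id"]),
        district=District(row["district"]),
        facility_type=FacilityType(row["facility_type"]),
        location=(float(row["x"]), float(row["y"])),
        general=general,
        staffing=staffing,
        equipment=equipment,
        refers_to=refers_to,
        assessed=assessed,
    )


def record_to_mapping(f: FacilityRecord) -> dict:
    """Flatten a record to a dict of scalar, file-ready values."""
    row: dict[str, object] = {
        "facility_id": f.facility_id,
        "district": f.district.value,
        "facility_type": f.facility_type.value,
        "x": f.location[0],
        "y": f.location[1],
        "assessed": int(f.assessed),
        "refers_to": f.refers_to or "",
    }
    if f.assessed:
        assert f.general and f.staffing and f.equipment
        for name in _GENERAL_FIELDS:
            v = getattr(f.general, name)
            row[name] = int(v) if isinstance(v, bool) else v
        for name in _STAFF_FIELDS:
            row[name] = getattr(f.staffing, name)
        for item in EQUIPMENT_ITEMS:
            row[item] = int(f.equipment[item])
        row["autoclave"] = "" if f.equipment.autoclave is None else int(f.equipment.autoclave)
    else:
        for name in (*_GENERAL_FIELDS, *_STAFF_FIELDS, *EQUIPMENT_ITEMS, "autoclave"):
            row[name] = ""
    return row


def check_dataset(facilities: Sequence[FacilityRecord]) -> None:
    """Raise :class:`DatasetError` on duplicate ids or dangling referrals."""
    seen: set[str] = set()
    dupes: list[str] = []
    for f in facilities:
        if f.facility_id in seen:
            dupes.append(f.facility_id)
        seen.add(f.facility_id)
    if dupes:
        raise DatasetError(f"duplicate facility_id(s): {sorted(set(dupes))}")
    dangling = [
        f.facility_id
        for f in facilities
        if f.refers_to is not None and f.refers_to not in seen
    ]
    if dangling:
        raise DatasetError(
            f"refers_to points outside dataset for facility(ies): {dangling}"
        )


def validate_dataset(facilities: Sequence[FacilityRecord]) -> ValidationReport:
    """Report every invariant violation; empty report iff the dataset is valid.

    Violations are report content, not exceptions. An unassessed facility with
    an outgoing referral is legal but surprising, so it is a warning.
    """
    report = ValidationReport()
    ids = [f.facility_id for f in facilities]
    known = set(ids)
    seen: set[str] = set()
    for f in facilities:
        if f.facility_id in seen:
            report.issues.append(
                ValidationIssue(f.facility_id, "error", "duplicate facility_id")
            )
        seen.add(f.facility_id)
        if f.refers_to is not None and f.refers_to not in known:
            report.issues.append(
                ValidationIssue(
                    f.facility_id, "error", f"refers_to {f.refers_to!r} not in dataset"
                )
            )
        if f.assessed:
            assert f.general is not None
            if not 0 <= f.general.removal_days_per_week <= 7:
                report.issues.append(
                    ValidationIssue(
                        f.facility_id, "error", "removal_days_per_week out of [0, 7]"
                    )
                )
        elif f.refers_to is not None:
            report.issues.append(
                ValidationIssue(
                    f.facility_id, "warning", "unassessed facility has refers_to set"
                )
            )
    return report


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_ALL_COLUMNS = (
    *_REQUIRED_COLUMNS,
    "refers_to",
    *_GENERAL_FIELDS,
    *_STAFF_FIELDS,
    *EQUIPMENT_ITEMS,
    "autoclave",
)


def read_facilities(path: str | Path, format: str | None = None) -> list[FacilityRecord]:
    """Read a facility dataset from CSV or JSON.

    CSV: one header row with the documented column names, booleans as 0/1.
    JSON: an array of flat objects with the same keys. ``format`` defaults to
    the file extension. Record order is preserved. Raises
    :class:`SchemaError` on malformed rows and :class:`DatasetError` on
    duplicate ids or referrals that point outside the dataset.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "CSV":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for col in _REQUIRED_COLUMNS:
                if col not in header:
                    raise SchemaError(f"missing required column {col!r}")
            rows = [dict(r) for r in reader]
    elif fmt == "JSON":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("JSON facility file must be an array of objects")
        rows = data
    else:
        raise ValueError(f"unknown format {fmt!r} (expected CSV or JSON)")
    records = [record_from_mapping(row) for row in rows]
    check_dataset(records)
    return records


def write_facilities(
    facilities: Iterable[FacilityRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records to CSV or JSON; round-trips with :func:`read_facilities`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    rows = [record_to_mapping(f) for f in facilities]
    if fmt == "CSV":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_ALL_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "JSON":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected CSV or JSON)")


def facilities_to_frame(facilities: Sequence[FacilityRecord]):
    """Flat :class:`pandas.DataFrame` view of a dataset (one row per facility)."""
    import pandas as pd

    return pd.DataFrame([record_to_mapping(f) for f in facilities])
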