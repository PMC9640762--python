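"""Facility readiness classification for implant removal services.

A facility is scored on three components — general service readiness,
human resources, and observed minimum equipment — and assigned one of three
levels:

* ``NOT_READY`` — at least one regular-removal condition fails;
* ``REGULAR`` — every condition for regular (uncomplicated) removals holds;
* ``DIFFICULT`` — additionally, every condition for difficult removals
  (deeply embedded or non-palpable implants) holds: an ultrasound-trained
  provider plus the specialised instrument set.

The scheme is a SARA-style conjunctive checklist: no weighting, no partial
credit. The conditions are data, not code — a :class:`CriteriaTable` drives
the evaluator, so alternative checklists (or alternative readings of a
written criterion) can be swapped in from a YAML/JSON file.

Default criteria
----------------
General service readiness: running water, decontamination buckets, safety
boxes and soap all present, and removals offered at least five days per week.
Human resources: at least one provider trained in removal (regular), plus at
least one trained in ultrasound use (difficult). Minimum equipment (regular):
syringes, local anesthetic, sterile band aids, scalpel with blade, curved and
straight forceps, and sterile gauze or (antiseptic and cotton balls).
Difficult adds modified vasectomy forceps, an ultrasound machine, sterile
towels, an examination table, a sterile surgical drape and a sterile
equipment tray.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .survey_data import District, FacilityRecord


class Level(IntEnum):
    """Readiness level; ordering reflects nesting (DIFFICULT ⊃ REGULAR)."""

    NOT_READY = 0
    REGULAR = 1
    DIFFICULT = 2


class NotAssessableError(ValueError):
    """Raised when a readiness question is asked of an unassessed facility."""


@dataclass(frozen=True)
class EquipmentCriteria:
    """Required equipment items plus one optional OR-of-ANDs clause.

    ``any_of`` is a list of alternative conjunctions; the criterion passes if
    every ``required`` item is present and at least one ``any_of`` clause is
    fully present. An empty ``any_of`` means no disjunctive term.
    """

    required: tuple[str, ...]
    any_of: tuple[tuple[str, ...], ...] = ()

    def evaluate(self, f: FacilityRecord) -> bool:
        eq = f.equipment
        assert eq is not None
        if not all(eq[item] for item in self.required):
            return False
        if self.any_of and not any(
            all(eq[item] for item in clause) for clause in self.any_of
        ):
            return False
        return True


@dataclass(frozen=True)
class CriteriaTable:
    """Declarative readiness criteria (the default matches the study scheme)."""

    general_items: tuple[str, ...] = (
        "running_water",
        "decontamination_buckets",
        "safety_boxes",
        "soap",
    )
    min_removal_days: int = 5
    min_trained_removal: int = 1
    min_trained_ultrasound: int = 1
    equipment_regular: EquipmentCriteria = EquipmentCriteria(
        required=(
            "syringes",
            "local_anesthetic",
            "sterile_band_aids",
            "scalpel_with_blade",
            "curved_forceps",
            "straight_forceps",
        ),
        any_of=(("sterile_gauze",), ("antiseptic", "cotton_balls")),
    )
    equipment_difficult_extra: tuple[str, ...] = (
        "vasectomy_forceps",
        "ultrasound_machine",
        "sterile_towels",
        "examination_table",
        "sterile_surgical_drape",
        "sterile_equipment_tray",
    )

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "general_items": list(self.general_items),
            "min_removal_days": self.min_removal_days,
            "min_trained_removal": self.min_trained_removal,
            "min_trained_ultrasound": self.min_trained_ultrasound,
            "equipment_regular": {
                "required": list(self.equipment_regular.required),
                "any_of": [list(c) for c in self.equipment_regular.any_of],
            },
            "equipment_difficult_extra": list(self.equipment_difficult_extra),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaTable":
        er = d.get("equipment_regular", {})
        return cls(
            general_items=tuple(d.get("general_items", cls.general_items)),
            min_removal_days=int(d.get("min_removal_days", cls.min_removal_days)),
            min_trained_removal=int(d.get("min_trained_removal", cls.min_trained_removal)),
            min_trained_ultrasound=int(
                d.get("min_trained_ultrasound", cls.min_trained_ultrasound)
            ),
            equipment_regular=EquipmentCriteria(
                required=tuple(er.get("required", cls.equipment_regular.required)),
                any_of=tuple(tuple(c) for c in er.get("any_of", ())),
            )
            if er
            else cls.equipment_regular,
            equipment_difficult_extra=tuple(
                d.get("equipment_difficult_extra", cls.equipment_difficult_extra)
            ),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "CriteriaTable":
        """Load a criteria table from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


DEFAULT_CRITERIA = CriteriaTable()


@dataclass(frozen=True)
class ReadinessResult:
    """Per-facility component outcomes and overall level."""

    facility_id: str
    general_ok: bool
    hr_regular_ok: bool
    hr_difficult_ok: bool
    equip_regular_ok: bool
    equip_difficult_ok: bool
    level: Level


def _require_assessed(f: FacilityRecord) -> None:
    if not f.assessed:
        raise NotAssessableError(
            f"facility {f.facility_id!r} was not assessed; readiness is undefined"
        )


def general_service_ready(
    f: FacilityRecord, criteria: CriteriaTable = DEFAULT_CRITERIA
) -> bool:
    """All infection-prevention items present and removals offered often enough."""
    _require_assessed(f)
    g = f.general
    assert g is not None
    return (
        all(getattr(g, item) for item in criteria.general_items)
        and g.removal_days_per_week >= criteria.min_removal_days
    )


def human_resources_ready(
    f: FacilityRecord, level: Level, criteria: CriteriaTable = DEFAULT_CRITERIA
) -> bool:
    """Staffing criterion at the given level.

    Regular removals need a removal-trained provider; difficult removals
    additionally need an ultrasound-trained one (to localise non-palpable
    implants).
    """
    _require_assessed(f)
    s = f.staffing
    assert s is not None
    ok = s.n_trained_removal >= criteria.min_trained_removal
    if level >= Level.DIFFICULT:
        ok = ok and s.n_trained_ultrasound >= criteria.min_trained_ultrasound
    return ok


def equipment_ready(
    f: FacilityRecord, level: Level, criteria: CriteriaTable = DEFAULT_CRITERIA
) -> bool:
    """Minimum equipment criterion at the given level (difficult ⊇ regular)."""
    _require_assessed(f)
    ok = criteria.equipment_regular.evaluate(f)
    if level >= Level.DIFFICULT:
        eq = f.equipment
        assert eq is not None
        ok = ok and all(eq[item] for item in criteria.equipment_difficult_extra)
    return ok


def classify_readiness(
    f: FacilityRecord, criteria: CriteriaTable = DEFAULT_CRITERIA
) -> ReadinessResult:
    """Assign a facility its readiness level with component breakdown."""
    _require_assessed(f)
    general_ok = general_service_ready(f, criteria)
    hr_reg = human_resources_ready(f, Level.REGULAR, criteria)
    hr_diff = human_resources_ready(f, Level.DIFFICULT, criteria)
    eq_reg = equipment_ready(f, Level.REGULAR, criteria)
    eq_diff = equipment_ready(f, Level.DIFFICULT, criteria)
    if general_ok and hr_diff and eq_diff:
        level = Level.DIFFICULT
    elif general_ok and hr_reg and eq_reg:
        level = Level.REGULAR
    else:
        level = Level.NOT_READY
    return ReadinessResult(
        facility_id=f.facility_id,
        general_ok=general_ok,
        hr_regular_ok=hr_reg,
        hr_difficult_ok=hr_diff,
        equip_regular_ok=eq_reg,
        equip_difficult_ok=eq_diff,
        level=level,
    )


def classify_all(
    facilities: Sequence[FacilityRecord], criteria: CriteriaTable = DEFAULT_CRITERIA
) -> dict[str, ReadinessResult]:
    """Classify every assessed facility; unassessed ones are skipped."""
    return {
        f.facility_id: classify_readiness(f, criteria)
        for f in facilities
        if f.assessed
    }


# ---------------------------------------------------------------------------
# summary (the two-district components table)
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    """Round half away from zero (the convention of the summary tables)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(k: int, n: int) -> int:
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * k / n)


#: (row label, predicate kind, payload) driving the summary layout.
_SUMMARY_ROWS: tuple[tuple[str, str, object], ...] = (
    ("Regular removals", "level", Level.REGULAR),
    ("General service readiness", "component", "general"),
    ("Running water", "general_item", "running_water"),
    ("Decontamination buckets", "general_item", "decontamination_buckets"),
    ("Safety boxes", "general_item", "safety_boxes"),
    ("Soap", "general_item", "soap"),
    ("Facility offers implant removals 5+ days per week", "component", "days"),
    ("Human resources: 1+ staff trained in implant removal", "component", "hr_regular"),
    ("Minimum equipment (regular)", "component", "equip_regular"),
    ("Syringes", "equip_item", "syringes"),
    ("Local anesthetic", "equip_item", "local_anesthetic"),
    ("Sterile band aids", "equip_item", "sterile_band_aids"),
    ("Scalpel with blade", "equip_item", "scalpel_with_blade"),
    ("Curved forceps", "equip_item", "curved_forceps"),
    ("Straight forceps", "equip_item", "straight_forceps"),
    ("Sterile gauze, or antiseptic and cotton balls", "component", "gauze_clause"),
    ("Difficult removals", "level", Level.DIFFICULT),
    ("General service readiness (difficult)", "component", "general"),
    ("Human resources: 1+ staff trained to use ultrasound", "component", "hr_ultrasound"),
    ("Minimum equipment (difficult)", "component", "equip_difficult"),
    ("Modified vasectomy forceps", "equip_item", "vasectomy_forceps"),
    ("Ultrasound", "equip_item", "ultrasound_machine"),
    ("Sterile towels", "equip_item", "sterile_towels"),
    ("Examination table", "equip_item", "examination_table"),
    ("Sterile dry surgical drape", "equip_item", "sterile_surgical_drape"),
)


def _row_predicate(kind: str, payload, criteria: CriteriaTable):
    if kind == "level":
        return lambda f, r: r.level >= payload
    if kind == "general_item":
        return lambda f, r: getattr(f.general, payload)
    if kind == "equip_item":
        return lambda f, r: f.equipment[payload]
    if kind == "component":
        return {
            "general": lambda f, r: r.general_ok,
            "days": lambda f, r: f.general.removal_days_per_week
            >= criteria.min_removal_days,
            "hr_regular": lambda f, r: r.hr_regular_ok,
            "hr_ultrasound": lambda f, r: f.staffing.n_trained_ultrasound
            >= criteria.min_trained_ultrasound,
            "equip_regular": lambda f, r: r.equip_regular_ok,
            "equip_difficult": lambda f, r: r.equip_difficult_ok,
            "gauze_clause": lambda f, r: (
                not criteria.equipment_regular.any_of
                or any(
                    all(f.equipment[i] for i in clause)
                    for clause in criteria.equipment_regular.any_of
                )
            ),
        }[payload]
    raise ValueError(kind)


@dataclass
class ReadinessSummary:
    """District-by-district percentages for every checklist row and level."""

    table: pd.DataFrame  # index = row label, columns = district names + "Total"
    n_by_district: dict[str, int]
    results: dict[str, ReadinessResult]

    def percent_of(self, row: str, column: str = "Total") -> int:
        return int(self.table.loc[row, column])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def summarize_readiness(
    facilities: Sequence[FacilityRecord],
    criteria: CriteriaTable = DEFAULT_CRITERIA,
) -> ReadinessSummary:
    """Summarise readiness by district and overall.

    Only assessed facilities enter the denominators. Percentages are whole
    percent, rounded half away from zero. Raises ``ValueError`` if no
    facility was assessed.
    """
    assessed = [f for f in facilities if f.assessed]
    if not assessed:
        raise ValueError("no assessed facilities to summarise")
    results = classify_all(assessed, criteria)
    district_names = [d.value for d in District]
    groups: dict[str, list[FacilityRecord]] = {name: [] for name in district_names}
    for f in assessed:
        groups.setdefault(f.district.value, []).append(f)
    groups = {k: v for k, v in groups.items() if v}
    columns = list(groups) + ["Total"]
    data: dict[str, list[int]] = {c: [] for c in columns}
    for label, kind, payload in _SUMMARY_ROWS:
        pred = _row_predicate(kind, payload, criteria)
        total_k = total_n = 0
        for name, members in groups.items():
            k = sum(bool(pred(f, results[f.facility_id])) for f in members)
            data[name].append(percent(k, len(members)))
            total_k += k
            total_n += len(members)
        data["Total"].append(percent(total_k, total_n))
    table = pd.DataFrame(data, index=[label for label, _, _ in _SUMMARY_ROWS])
    table.index.name = "Component"
    n_by = {name: len(members) for name, members in groups.items()}
    n_by["Total"] = len(assessed)
    return ReadinessSummary(table=table, n_by_district=n_by, results=results)


def additional_indicators(facilities: Sequence[FacilityRecord]) -> pd.Series:
    """Reporting-only indicators that never enter the readiness level:
    autoclave availability and presence of at least two removal-trained
    providers."""
    assessed = [f for f in facilities if f.assessed]
    if not assessed:
        raise ValueError("no assessed facilities")
    n = len(assessed)
    autoclave = sum(1 for f in assessed if f.equipment and f.equipment.autoclave)
    two_trained = sum(
        1 for f in assessed if f.staffing and f.staffing.n_trained_removal >= 2
    )
    return pd.Series(
        {
            "Functioning autoclave": percent(autoclave, n),
            "2+ staff trained in implant removal": percent(two_trained, n),
        },
        name="Total %",
    )
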