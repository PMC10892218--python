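"""Domain types and I/O for reimbursed-dispensation registries.

A dispensation record is one filled, reimbursed prescription: who received
it, when, which product (ATC code) and how much active substance.  The study
calendar carves the index period into consecutive 7-day weeks; week ``k``
covers the half-open day span ``[index_start + 7(k-1), index_start + 7k)``
and is labelled by the date ``index_start + 7k``.

All tables are plain CSV (UTF-8, ISO-8601 dates):

* dispensations: ``subject_id,sex,birth_date,dispensation_date,atc_code,
  drug_name,n_packages,units_per_package,strength_per_unit``
* population: ``year,count`` (optionally ``count_f,count_m``)
* drug registry: ``atc_code,ddd_mg,default_pack_units,default_strength_mg``
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`week_of_date` for dates outside the week grid
OUT_OF_RANGE = 0

ATC_CLASSES = ("N06AA", "N06AB", "N06AX")


@dataclass(frozen=True)
class StudyCalendar:
    """Week grid of the index period, split at an interruption date.

    Defaults encode a 200-week window (2018-01-01 to 2021-11-01) interrupted
    on 2020-03-09: weeks 1-114 are the pre-interruption segment, weeks
    115-200 the post segment.  ``burn_in_weeks`` initial weeks carry no
    episode look-back and are excluded from model fitting downstream.
    """

    index_start: dt.date = dt.date(2018, 1, 1)
    index_end: dt.date = dt.date(2021, 11, 1)
    interruption_date: dt.date = dt.date(2020, 3, 9)
    burn_in_weeks: int = 12

    def __post_init__(self) -> None:
        if not (self.index_start < self.interruption_date < self.index_end):
            raise ValueError("require index_start < interruption_date < index_end")
        if self.burn_in_weeks < 0:
            raise ValueError("burn_in_weeks must be non-negative")

    @property
    def n_weeks(self) -> int:
        """Number of whole weeks in the index period."""
        return (self.index_end - self.index_start).days // 7

    @property
    def interruption_week(self) -> int:
        """First week whose span starts on/after the interruption date."""
        return (self.interruption_date - self.index_start).days // 7 + 1

    @property
    def pre_weeks(self) -> range:
        return range(1, self.interruption_week)

    @property
    def post_weeks(self) -> range:
        return range(self.interruption_week, self.n_weeks + 1)


def week_of_date(d: dt.date, calendar: StudyCalendar) -> int:
    """Map a date to its week index (1..W), or :data:`OUT_OF_RANGE`."""
    offset = (d - calendar.index_start).days
    if offset < 0 or offset >= 7 * calendar.n_weeks:
        return OUT_OF_RANGE
    return offset // 7 + 1


def label_of_week(k: int, calendar: StudyCalendar) -> dt.date:
    """Label date of week ``k``: the first day after its span."""
    if not 1 <= k <= calendar.n_weeks:
        raise ValueError(f"week index {k} outside 1..{calendar.n_weeks}")
    return calendar.index_start + dt.timedelta(days=7 * k)


@dataclass(frozen=True)
class DrugSpec:
    """One study drug: ATC code, WHO defined daily dose and default pack."""

    atc_code: str
    ddd_mg: float
    default_pack_units: int
    default_strength_mg: float
    drug_name: str = ""

    def __post_init__(self) -> None:
        if len(self.atc_code) != 7:
            raise ValueError(f"ATC code must have 7 characters: {self.atc_code!r}")
        if self.ddd_mg <= 0 or self.default_strength_mg <= 0:
            raise ValueError("DDD and strength must be positive")
        if self.default_pack_units < 1:
            raise ValueError("default_pack_units must be >= 1")

    @property
    def atc_class(self) -> str:
        return self.atc_code[:5]


# WHO DDDs for the antidepressants (N06A) reimbursed in Italy during the
# study window; pack defaults reflect common Italian retail presentations.
DEFAULT_DRUG_REGISTRY: tuple[DrugSpec, ...] = (
    DrugSpec("N06AA04", 100.0, 28, 25.0, "clomipramine"),
    DrugSpec("N06AA09", 75.0, 28, 25.0, "amitriptyline"),
    DrugSpec("N06AA21", 100.0, 30, 30.0, "maprotiline"),
    DrugSpec("N06AB03", 20.0, 28, 20.0, "fluoxetine"),
    DrugSpec("N06AB04", 20.0, 28, 20.0, "citalopram"),
    DrugSpec("N06AB05", 20.0, 28, 20.0, "paroxetine"),
    DrugSpec("N06AB06", 50.0, 30, 50.0, "sertraline"),
    DrugSpec("N06AB08", 100.0, 30, 100.0, "fluvoxamine"),
    DrugSpec("N06AB10", 10.0, 28, 10.0, "escitalopram"),
    DrugSpec("N06AX05", 300.0, 30, 75.0, "trazodone"),
    DrugSpec("N06AX11", 30.0, 30, 30.0, "mirtazapine"),
    DrugSpec("N06AX12", 300.0, 30, 150.0, "bupropion"),
    DrugSpec("N06AX16", 100.0, 28, 75.0, "venlafaxine"),
    DrugSpec("N06AX21", 60.0, 28, 60.0, "duloxetine"),
)


def registry_by_atc(registry: Iterable[DrugSpec]) -> dict[str, DrugSpec]:
    out: dict[str, DrugSpec] = {}
    for spec in registry:
        if spec.atc_code in out:
            raise ValueError(f"duplicate ATC code in registry: {spec.atc_code}")
        out[spec.atc_code] = spec
    return out


@dataclass(frozen=True)
class DispensationRecord:
    """One reimbursed dispensation."""

    subject_id: str
    sex: str
    birth_date: dt.date
    dispensation_date: dt.date
    atc_code: str
    drug_name: str
    n_packages: int
    units_per_package: int
    strength_per_unit: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.n_packages < 1 or self.units_per_package < 1:
            raise ValueError("pack counts must be >= 1")
        if self.strength_per_unit <= 0:
            raise ValueError("strength_per_unit must be positive")

    @property
    def amount_mg(self) -> float:
        """Total dispensed active substance in milligrams."""
        return self.n_packages * self.units_per_package * self.strength_per_unit


@dataclass(frozen=True)
class PopulationTable:
    """Reference-population head counts on 1 January of each calendar year.

    ``by_sex`` is optional; when absent, sex-stratified rates fall back to
    the total denominator (callers flag this in their output).
    """

    total: Mapping[int, int]
    by_sex: Mapping[str, Mapping[int, int]] | None = None

    def count(self, year: int, stratum: str = "all") -> int:
        if stratum != "all" and self.by_sex is not None:
            table = self.by_sex[stratum]
        else:
            table = self.total
        if year not in table:
            raise KeyError(f"no population count for calendar year {year}")
        return table[year]

    def has_sex_counts(self) -> bool:
        return self.by_sex is not None

    def mean_count(self, years: Iterable[int], stratum: str = "all") -> int:
        ys = list(years)
        return round(sum(self.count(y, stratum) for y in ys) / len(ys))


DISPENSATION_COLUMNS = [
    "subject_id", "sex", "birth_date", "dispensation_date", "atc_code",
    "drug_name", "n_packages", "units_per_package", "strength_per_unit",
]


def _parse_date(text: str, row_num: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"row {row_num}: unparseable {column} {text!r}") from exc


def read_dispensations(
    path: str | Path,
    drug_registry: Iterable[DrugSpec] = DEFAULT_DRUG_REGISTRY,
    strict: bool = False,
) -> list[DispensationRecord]:
    """Read and validate a dispensation CSV.

    Rows whose ATC code is not in the drug registry are a hard error in
    strict mode, otherwise logged and skipped.  Output is sorted by
    (subject_id, dispensation_date).
    """
    by_atc = registry_by_atc(drug_registry)
    records: list[DispensationRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in DISPENSATION_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        for row_num, row in enumerate(reader, start=2):
            atc = row["atc_code"].strip()
            if atc not in by_atc:
                msg = f"row {row_num}: ATC code {atc!r} not in study drug registry"
                if strict:
                    raise ValueError(msg)
                logger.info("skipping %s", msg)
                continue
            records.append(DispensationRecord(
                subject_id=row["subject_id"],
                sex=row["sex"].strip(),
                birth_date=_parse_date(row["birth_date"], row_num, "birth_date"),
                dispensation_date=_parse_date(
                    row["dispensation_date"], row_num, "dispensation_date"),
                atc_code=atc,
                drug_name=row["drug_name"],
                n_packages=int(row["n_packages"]),
                units_per_package=int(row["units_per_package"]),
                strength_per_unit=float(row["strength_per_unit"]),
            ))
    records.sort(key=lambda r: (r.subject_id, r.dispensation_date))
    return records


def write_dispensations(records: Sequence[DispensationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DISPENSATION_COLUMNS)
        for r in records:
            writer.writerow([
                r.subject_id, r.sex, r.birth_date.isoformat(),
                r.dispensation_date.isoformat(), r.atc_code, r.drug_name,
                r.n_packages, r.units_per_package,
                f"{r.strength_per_unit:g}",
            ])


def read_population(path: str | Path) -> PopulationTable:
    total: dict[int, int] = {}
    by_sex: dict[str, dict[int, int]] = {"F": {}, "M": {}}
    has_sex = False
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if "year" not in header or "count" not in header:
            raise ValueError("population table needs columns 'year' and 'count'")
        sex_cols = "count_f" in header and "count_m" in header
        for row in reader:
            year = int(row["year"])
            total[year] = int(row["count"])
            if sex_cols and row["count_f"] and row["count_m"]:
                has_sex = True
                by_sex["F"][year] = int(row["count_f"])
                by_sex["M"][year] = int(row["count_m"])
    return PopulationTable(total=total, by_sex=by_sex if has_sex else None)


def write_population(table: PopulationTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if table.by_sex is not None:
            writer.writerow(["year", "count", "count_f", "count_m"])
            for year in sorted(table.total):
                writer.writerow([year, table.total[year],
                                 table.by_sex["F"][year], table.by_sex["M"][year]])
        else:
            writer.writerow(["year", "count"])
            for year in sorted(table.total):
                writer.writerow([year, table.total[year]])


def read_drug_registry(path: str | Path) -> list[DrugSpec]:
    specs: list[DrugSpec] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            specs.append(DrugSpec(
                atc_code=row["atc_code"],
                ddd_mg=float(row["ddd_mg"]),
                default_pack_units=int(row["default_pack_units"]),
                default_strength_mg=float(row["default_strength_mg"]),
                drug_name=row.get("drug_name", ""),
            ))
    return specs


def age_at(birth_date: dt.date, on: dt.date) -> int:
    """Whole years completed at ``on``."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def filter_cohort(
    records: Sequence[DispensationRecord],
    calendar: StudyCalendar,
    age_min: int = 18,
    age_max: int = 22,
) -> list[DispensationRecord]:
    """Keep subjects aged ``age_min``..``age_max`` at their index date.

    The index date is a subject's first dispensation filled within the index
    period; eligibility is fixed there, so an eligible subject keeps all of
    their records (including look-back fills before the period).
    """
    if age_min > age_max:
        raise ValueError("age_min must not exceed age_max")
    index_date: dict[str, dt.date] = {}
    for r in records:  # records need not be sorted; track the minimum
        if calendar.index_start <= r.dispensation_date < calendar.index_end:
            prev = index_date.get(r.subject_id)
            if prev is None or r.dispensation_date < prev:
                index_date[r.subject_id] = r.dispensation_date
    eligible = set()
    birth: dict[str, dt.date] = {r.subject_id: r.birth_date for r in records}
    for sid, idx in index_date.items():
        if age_min <= age_at(birth[sid], idx) <= age_max:
            eligible.add(sid)
    return [r for r in records if r.subject_id in eligible]
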