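"""Treatment-episode construction from dispensation histories.

Each dispensation contributes ``amount_mg / DDD`` days of supply.  Scanning
a subject's fills in date order within a drug group, a fill continues the
current episode when the gap since the previous fill does not exceed
``grace_factor`` times that previous fill's supply; otherwise a new episode
starts.  The episode ends ``supply`` days after its last fill.  Same-day
fills within a group are merged (supplies summed) before scanning.

The grace window is anchored at the fill date by default.  Setting
``anchor="exhaustion"`` instead allows a gap of ``supply + grace_factor *
supply`` days, counting the tolerance from the day the supply runs out —
a convention some episode definitions in the dispensing-data literature use.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .claims import DispensationRecord, DrugSpec, registry_by_atc

Grouping = Literal["per_atc_class", "per_drug", "umbrella"]

UMBRELLA = "N06A"


@dataclass(frozen=True)
class EpisodeConfig:
    grace_factor: float = 1.5
    grouping: Grouping = "umbrella"
    anchor: Literal["dispensation", "exhaustion"] = "dispensation"

    def __post_init__(self) -> None:
        if self.grace_factor <= 0:
            raise ValueError("grace_factor must be positive")

    def allowed_gap(self, supply_days: float) -> float:
        """Maximum fill-to-fill gap (days) that continues an episode."""
        if self.anchor == "dispensation":
            return self.grace_factor * supply_days
        return supply_days + self.grace_factor * supply_days


@dataclass(frozen=True)
class TreatmentEpisode:
    """A per-subject, per-group interval of presumed continuous exposure.

    ``end_date`` is exclusive: the subject is exposed on every day in
    ``[start_date, end_date)``.
    """

    subject_id: str
    group: str
    start_date: dt.date
    end_date: dt.date
    n_dispensations: int

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise ValueError("episode must have start_date < end_date")
        if self.n_dispensations < 1:
            raise ValueError("episode needs at least one dispensation")


def days_of_supply(record: DispensationRecord, spec: DrugSpec) -> float:
    """Days of supply: dispensed active substance divided by the WHO DDD."""
    if spec.atc_code != record.atc_code:
        raise ValueError(
            f"spec {spec.atc_code} does not match record {record.atc_code}")
    amount = record.amount_mg
    if amount <= 0:
        raise ValueError("dispensed amount must be positive")
    return amount / spec.ddd_mg


def group_key(atc_code: str, grouping: Grouping) -> str:
    if grouping == "umbrella":
        return UMBRELLA
    if grouping == "per_atc_class":
        return atc_code[:5]
    return atc_code


def build_episodes(
    records: Sequence[DispensationRecord],
    registry: Iterable[DrugSpec] | Mapping[str, DrugSpec],
    config: EpisodeConfig = EpisodeConfig(),
) -> list[TreatmentEpisode]:
    """Stitch one subject's dispensations into treatment episodes.

    ``records`` must belong to a single subject and be sorted by date.
    Returns episodes for every group under ``config.grouping``, sorted by
    (group, start_date).
    """
    if not records:
        return []
    by_atc = registry if isinstance(registry, Mapping) else registry_by_atc(registry)
    subject = records[0].subject_id
    for a, b in zip(records, records[1:]):
        if a.subject_id != b.subject_id:
            raise ValueError("build_episodes expects records of a single subject")
        if a.dispensation_date > b.dispensation_date:
            raise ValueError(f"records of subject {subject} are not date-sorted")
    for r in records:
        if r.atc_code not in by_atc:
            raise KeyError(f"unknown ATC code {r.atc_code} (subject {subject})")

    episodes: list[TreatmentEpisode] = []
    groups: dict[str, list[DispensationRecord]] = {}
    for r in records:
        groups.setdefault(group_key(r.atc_code, config.grouping), []).append(r)

    for group in sorted(groups):
        # merge same-day fills: (date, summed supply, fill count)
        fills: list[tuple[dt.date, float, int]] = []
        for r in groups[group]:
            supply = days_of_supply(r, by_atc[r.atc_code])
            if fills and fills[-1][0] == r.dispensation_date:
                d, s, c = fills[-1]
                fills[-1] = (d, s + supply, c + 1)
            else:
                fills.append((r.dispensation_date, supply, 1))

        start, prev_date, prev_supply, count = fills[0][0], fills[0][0], fills[0][1], fills[0][2]
        for date, supply, c in fills[1:]:
            gap = (date - prev_date).days
            if gap > config.allowed_gap(prev_supply):
                # partial final day of supply still counts as exposed; clip
                # at the next start so episodes stay disjoint even when
                # grace_factor < 1
                end = prev_date + dt.timedelta(days=math.ceil(prev_supply))
                episodes.append(TreatmentEpisode(
                    subject, group, start, min(end, date), count))
                start, count = date, 0
            prev_date, prev_supply = date, supply
            count += c
        episodes.append(TreatmentEpisode(
            subject, group, start,
            prev_date + dt.timedelta(days=math.ceil(prev_supply)), count))
    return episodes


def episodes_for_cohort(
    records: Sequence[DispensationRecord],
    registry: Iterable[DrugSpec] | Mapping[str, DrugSpec],
    config: EpisodeConfig = EpisodeConfig(),
) -> dict[str, list[TreatmentEpisode]]:
    """Build episodes for every subject; row order of the input is irrelevant."""
    by_atc = registry if isinstance(registry, Mapping) else registry_by_atc(registry)
    per_subject: dict[str, list[DispensationRecord]] = {}
    for r in records:
        per_subject.setdefault(r.subject_id, []).append(r)
    out: dict[str, list[TreatmentEpisode]] = {}
    for sid in sorted(per_subject):
        rows = sorted(per_subject[sid], key=lambda r: r.dispensation_date)
        try:
            out[sid] = build_episodes(rows, by_atc, config)
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"subject {sid}: {exc}") from exc
    return out


EPISODE_COLUMNS = ["subject_id", "group", "start_date", "end_date", "n_dispensations"]


def write_episodes(
    episodes: Mapping[str, Sequence[TreatmentEpisode]] | Sequence[TreatmentEpisode],
    path: str | Path,
) -> None:
    rows: list[TreatmentEpisode] = []
    if isinstance(episodes, Mapping):
        for sid in sorted(episodes):
            rows.extend(episodes[sid])
    else:
        rows = list(episodes)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPISODE_COLUMNS)
        for e in rows:
            writer.writerow([e.subject_id, e.group, e.start_date.isoformat(),
                             e.end_date.isoformat(), e.n_dispensations])


def read_episodes(path: str | Path) -> dict[str, list[TreatmentEpisode]]:
    out: dict[str, list[TreatmentEpisode]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            e = TreatmentEpisode(
                subject_id=row["subject_id"], group=row["group"],
                start_date=dt.date.fromisoformat(row["start_date"]),
                end_date=dt.date.fromisoformat(row["end_date"]),
                n_dispensations=int(row["n_dispensations"]))
            out.setdefault(e.subject_id, []).append(e)
    return out
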