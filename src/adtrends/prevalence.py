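"""Prevalence-of-users estimation with exact binomial intervals.

Rates are reported per 10,000 inhabitants with central exact
(Clopper-Pearson) confidence intervals.  Sex contrasts are expressed as odds
ratios with Wald intervals on the log scale and two-sided Fisher exact
p-values (probability-mass convention).
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .claims import ATC_CLASSES, DispensationRecord, PopulationTable, StudyCalendar, label_of_week
from .episodes import UMBRELLA, TreatmentEpisode

PER_10K = 10_000.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention used for printed rates)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact central binomial CI for a proportion, via beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside 0..{n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


@dataclass(frozen=True)
class PrevalenceEstimate:
    numerator: int
    denominator: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator outside 0..denominator")

    @property
    def rate_per_10k(self) -> float:
        return PER_10K * self.numerator / self.denominator

    @property
    def ci_per_10k(self) -> tuple[float, float]:
        lo, hi = clopper_pearson(self.numerator, self.denominator, self.alpha)
        return PER_10K * lo, PER_10K * hi


@dataclass(frozen=True)
class PrevalenceSeries:
    """Weekly prevalence estimates over a study calendar."""

    calendar: StudyCalendar
    group: str
    stratum: Literal["all", "F", "M"]
    estimates: tuple[PrevalenceEstimate, ...]
    denominator_is_total: bool = False  # sex stratum rated against total pop

    def __post_init__(self) -> None:
        if len(self.estimates) != self.calendar.n_weeks:
            raise ValueError("series length must equal the calendar's week count")

    @property
    def rates(self) -> np.ndarray:
        return np.array([e.rate_per_10k for e in self.estimates])

    @property
    def numerators(self) -> np.ndarray:
        return np.array([e.numerator for e in self.estimates])

    @property
    def denominators(self) -> np.ndarray:
        return np.array([e.denominator for e in self.estimates])


def overall_prevalence(
    users: Iterable[str],
    population: PopulationTable,
    calendar: StudyCalendar = StudyCalendar(),
    stratum: str = "all",
    reference_year_rule: Literal["mean", "first", "per_year"] = "mean",
    alpha: float = 0.05,
) -> PrevalenceEstimate:
    """Period prevalence: distinct users over the reference population.

    The reference population covers several calendar years; by default the
    denominator is the rounded mean of the yearly 1-January counts.
    """
    numerator = len(set(users))
    years = range(calendar.index_start.year, calendar.index_end.year + 1)
    if reference_year_rule == "first":
        denominator = population.count(calendar.index_start.year, stratum)
    else:
        denominator = population.mean_count(years, stratum)
    return PrevalenceEstimate(numerator, denominator, alpha)


def _weeks_covered(
    episode: TreatmentEpisode, calendar: StudyCalendar
) -> range:
    """Week indices whose day span overlaps the episode interval."""
    w = calendar.n_weeks
    first_off = (episode.start_date - calendar.index_start).days
    last_off = (episode.end_date - calendar.index_start).days - 1  # inclusive
    if last_off < 0 or first_off >= 7 * w:
        return range(0)
    lo = max(first_off // 7 + 1, 1)
    hi = min(last_off // 7 + 1, w)
    return range(lo, hi + 1)


def weekly_prevalence(
    episodes: Mapping[str, Sequence[TreatmentEpisode]],
    group: str,
    calendar: StudyCalendar,
    population: PopulationTable,
    stratum: Literal["all", "F", "M"] = "all",
    sex_of_subject: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> PrevalenceSeries:
    """Weekly user prevalence for one drug group.

    Week ``k``'s numerator is the number of distinct subjects with at least
    one episode of ``group`` overlapping week ``k``'s day span.  The
    denominator is the reference population of the calendar year containing
    the week's first day; sex strata use the sex-specific count when the
    population table has one, otherwise the total (flagged on the result).
    """
    if stratum != "all" and sex_of_subject is None:
        raise ValueError("sex stratification requires a sex_of_subject mapping")
    w = calendar.n_weeks
    active = np.zeros(w + 1, dtype=np.int64)  # 1-based
    for sid, eps in episodes.items():
        if stratum != "all" and sex_of_subject.get(sid) != stratum:
            continue
        weeks: set[int] = set()
        for e in eps:
            if e.group != group:
                continue
            weeks.update(_weeks_covered(e, calendar))
        for k in weeks:
            active[k] += 1

    use_total = stratum != "all" and not population.has_sex_counts()
    estimates = []
    for k in range(1, w + 1):
        first_day = calendar.index_start + dt.timedelta(days=7 * (k - 1))
        denom = population.count(first_day.year, "all" if use_total else stratum)
        estimates.append(PrevalenceEstimate(int(active[k]), denom, alpha))
    return PrevalenceSeries(calendar, group, stratum, tuple(estimates),
                            denominator_is_total=use_total)


@dataclass(frozen=True)
class TwoByTwoResult:
    """Odds ratio for a 2x2 table (a,b / c,d) with Wald CI and Fisher p."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    continuity_corrected: bool


def two_by_two(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> TwoByTwoResult:
    """OR = (a*d)/(b*c) with a Wald log-scale CI and Fisher exact p.

    When any cell is zero the Haldane-Anscombe 0.5 correction is applied to
    all four cells for the OR and its CI (flagged on the result); the Fisher
    p-value always uses the uncorrected table.
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("two_by_two requires all margins positive")
    corrected = any(v == 0 for v in cells)
    aa, bb, cc, dd = ((v + 0.5 for v in cells) if corrected else cells)
    odds_ratio = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = float(np.exp(np.log(odds_ratio) - z * se))
    ci_high = float(np.exp(np.log(odds_ratio) + z * se))
    p_value = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return TwoByTwoResult(a, b, c, d, float(odds_ratio), ci_low, ci_high,
                          p_value, alpha, corrected)


@dataclass(frozen=True)
class ProfileRow:
    """One row of the usage profile: a drug class or a single drug."""

    key: str
    label: str
    n_users: int
    prevalence: PrevalenceEstimate
    sex_or: TwoByTwoResult | None


@dataclass(frozen=True)
class UsageProfile:
    class_rows: tuple[ProfileRow, ...]
    drug_rows: tuple[ProfileRow, ...]
    n_users_total: int
    n_multi_class: int

    @property
    def multi_class_share(self) -> float:
        return self.n_multi_class / self.n_users_total if self.n_users_total else 0.0


def class_and_drug_profile(
    records: Sequence[DispensationRecord],
    population: PopulationTable,
    calendar: StudyCalendar = StudyCalendar(),
    alpha: float = 0.05,
    drug_names: Mapping[str, str] | None = None,
) -> UsageProfile:
    """Per-class and per-drug user counts, prevalence and F-vs-M odds ratios.

    A subject using drugs from two or three ATC classes appears in every
    class row used and once in the multi-class count.  The sex odds ratio
    contrasts users against non-users within each sex; without sex-specific
    population counts the total population is split evenly.
    """
    users_by_class: dict[str, set[str]] = {}
    users_by_drug: dict[str, set[str]] = {}
    classes_of_subject: dict[str, set[str]] = {}
    sex_of: dict[str, str] = {}
    for r in records:
        cls = r.atc_code[:5]
        users_by_class.setdefault(cls, set()).add(r.subject_id)
        users_by_drug.setdefault(r.atc_code, set()).add(r.subject_id)
        classes_of_subject.setdefault(r.subject_id, set()).add(cls)
        sex_of[r.subject_id] = r.sex

    all_users = set(sex_of)
    years = range(calendar.index_start.year, calendar.index_end.year + 1)
    denom_all = population.mean_count(years, "all")
    if population.has_sex_counts():
        denom_sex = {s: population.mean_count(years, s) for s in ("F", "M")}
    else:
        denom_sex = {"F": denom_all // 2, "M": denom_all - denom_all // 2}

    def make_row(key: str, label: str, users: set[str]) -> ProfileRow:
        est = PrevalenceEstimate(len(users), denom_all, alpha)
        n_f = sum(1 for u in users if sex_of[u] == "F")
        n_m = len(users) - n_f
        try:
            orr = two_by_two(n_f, denom_sex["F"] - n_f, n_m, denom_sex["M"] - n_m, alpha)
        except ValueError:
            orr = None
        return ProfileRow(key, label, len(users), est, orr)

    class_rows = [make_row(UMBRELLA, "all study drugs", all_users)]
    for cls in ATC_CLASSES:
        class_rows.append(make_row(cls, cls, users_by_class.get(cls, set())))
    drug_rows = [
        make_row(atc, (drug_names or {}).get(atc, atc), users_by_drug[atc])
        for atc in sorted(users_by_drug)
    ]
    n_multi = sum(1 for cs in classes_of_subject.values() if len(cs) >= 2)
    return UsageProfile(tuple(class_rows), tuple(drug_rows), len(all_users), n_multi)


SERIES_COLUMNS = ["week", "label_date", "group", "stratum", "numerator",
                  "denominator", "rate_per_10k", "ci_low", "ci_high"]


def write_series(series: PrevalenceSeries, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SERIES_COLUMNS)
        for k, est in enumerate(series.estimates, start=1):
            lo, hi = est.ci_per_10k
            writer.writerow([
                k, label_of_week(k, series.calendar).isoformat(),
                series.group, series.stratum, est.numerator, est.denominator,
                round_half_up(est.rate_per_10k), round_half_up(lo), round_half_up(hi),
            ])


def write_profile(profile: UsageProfile, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "key", "label", "n_users", "rate_per_10k",
                         "ci_low", "ci_high", "or_f_vs_m", "or_low", "or_high",
                         "fisher_p", "or_corrected"])
        for level, rows in (("class", profile.class_rows), ("drug", profile.drug_rows)):
            for row in rows:
                lo, hi = row.prevalence.ci_per_10k
                orr = row.sex_or
                writer.writerow([
                    level, row.key, row.label, row.n_users,
                    round_half_up(row.prevalence.rate_per_10k),
                    round_half_up(lo), round_half_up(hi),
                    "" if orr is None else f"{orr.odds_ratio:.2f}",
                    "" if orr is None else f"{orr.ci_low:.2f}",
                    "" if orr is None else f"{orr.ci_high:.2f}",
                    "" if orr is None else f"{orr.p_value:.4f}",
                    "" if orr is None else str(orr.continuity_corrected).lower(),
                ])
        writer.writerow(["summary", "multi_class", "subjects using >=2 classes",
                         profile.n_multi_class, "", "", "", "", "", "", "", ""])
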