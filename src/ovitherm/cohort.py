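"""Domain types and CSV interchange for egg-cohort laboratory data, daily
temperature series and winter field records.

The laboratory unit of observation is the egg *cluster*: a batch of eggs laid
within 24 h and incubated at one constant temperature under one relative-
humidity (RH) regime, examined once per day. Cluster tables record, per day,
how many eggs are alive (split by external colour stage: yellow, brown, head
capsule visible / black) and the cumulative numbers hatched and dead.
:func:`derive_fates` converts those daily tables into per-egg outcomes
suitable for survival and development-time analysis.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import SchemaError, ValidationError

__all__ = [
    "RH_REGIMES",
    "RH_BOUNDS",
    "OUTCOMES",
    "FIELD_KINDS",
    "Condition",
    "ClusterObservation",
    "EggFate",
    "TemperatureSeries",
    "FieldRecord",
    "load_cluster_observations",
    "write_cluster_observations",
    "load_temperature_series",
    "write_temperature_series",
    "load_field_records",
    "write_field_records",
    "load_fates",
    "write_fates",
    "derive_fates",
]

#: The three relative-humidity regimes, with the RH band (%) each one denotes.
RH_BOUNDS: Mapping[str, tuple[float, float]] = {
    "high": (90.0, 100.0),
    "medium": (50.0, 75.0),
    "low": (10.0, 35.0),
}
RH_REGIMES: tuple[str, ...] = ("low", "medium", "high")

OUTCOMES: tuple[str, ...] = ("hatched", "died", "censored")

FIELD_KINDS: tuple[str, ...] = (
    "larva",
    "egg_yellow",
    "egg_brown",
    "egg_blackhead",
    "adult_reproductive",
    "adult_nonreproductive",
)

#: Upper bound on plausible initial cluster size (study clusters held 10–15).
MAX_CLUSTER_SIZE = 10_000


@dataclass(frozen=True, order=True)
class Condition:
    """One incubation condition: constant temperature × RH regime."""

    temperature_c: float
    rh_regime: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature_c):
            raise ValidationError(f"non-finite temperature: {self.temperature_c!r}")
        if self.rh_regime not in RH_REGIMES:
            raise ValidationError(
                f"unknown RH regime {self.rh_regime!r}; expected one of {RH_REGIMES}"
            )

    @property
    def rh_bounds(self) -> tuple[float, float]:
        return RH_BOUNDS[self.rh_regime]


@dataclass(frozen=True)
class ClusterObservation:
    """Daily census of one egg cluster.

    ``n_alive`` is partitioned by colour stage; ``n_hatched_cum`` and
    ``n_dead_cum`` are cumulative since age 0.
    """

    cluster_id: str
    condition: Condition
    age_days: int
    n_alive: int
    n_yellow: int
    n_brown: int
    n_blackhead: int
    n_hatched_cum: int
    n_dead_cum: int

    def __post_init__(self) -> None:
        counts = (
            self.age_days,
            self.n_alive,
            self.n_yellow,
            self.n_brown,
            self.n_blackhead,
            self.n_hatched_cum,
            self.n_dead_cum,
        )
        if any(c < 0 for c in counts):
            raise ValidationError(
                f"cluster {self.cluster_id} age {self.age_days}: negative count"
            )
        if self.n_yellow + self.n_brown + self.n_blackhead != self.n_alive:
            raise ValidationError(
                f"cluster {self.cluster_id} age {self.age_days}: colour counts "
                f"{self.n_yellow}+{self.n_brown}+{self.n_blackhead} != n_alive={self.n_alive}"
            )
        n0 = self.initial_count
        if not 1 <= n0 <= MAX_CLUSTER_SIZE:
            raise ValidationError(
                f"cluster {self.cluster_id} age {self.age_days}: implausible "
                f"initial egg count {n0}"
            )

    @property
    def initial_count(self) -> int:
        return self.n_alive + self.n_hatched_cum + self.n_dead_cum


@dataclass(frozen=True)
class EggFate:
    """Resolved outcome of a single egg.

    ``stage_durations`` (yellow, brown, blackhead days) is present only for
    hatched eggs with a fully observed colour trajectory; the three durations
    sum to ``event_age_days``.
    """

    egg_id: str
    cluster_id: str
    condition: Condition
    outcome: str
    event_age_days: int
    stage_durations: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"egg {self.egg_id}: unknown outcome {self.outcome!r}")
        if self.event_age_days < 1:
            raise ValidationError(
                f"egg {self.egg_id}: event age must be >= 1 day, got {self.event_age_days}"
            )
        if self.stage_durations is not None:
            if self.outcome != "hatched":
                raise ValidationError(
                    f"egg {self.egg_id}: stage durations only valid for hatched eggs"
                )
            if any(d < 0 for d in self.stage_durations):
                raise ValidationError(f"egg {self.egg_id}: negative stage duration")
            if sum(self.stage_durations) != self.event_age_days:
                raise ValidationError(
                    f"egg {self.egg_id}: stage durations {self.stage_durations} do not "
                    f"sum to event age {self.event_age_days}"
                )


@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily mean temperatures for one geographic area."""

    area: str
    dates: tuple[dt.date, ...]
    tmean_c: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.tmean_c):
            raise ValidationError(f"area {self.area}: dates/temperatures length mismatch")
        if not self.dates:
            raise ValidationError(f"area {self.area}: empty temperature series")
        for prev, cur in zip(self.dates, self.dates[1:]):
            if (cur - prev).days != 1:
                raise ValidationError(
                    f"area {self.area}: dates must be consecutive days, "
                    f"found gap {prev} -> {cur}"
                )
        if any(not math.isfinite(t) for t in self.tmean_c):
            raise ValidationError(f"area {self.area}: non-finite temperature")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]

    def index_of(self, date: dt.date) -> int:
        offset = (date - self.start).days
        if not 0 <= offset < len(self.dates):
            raise KeyError(f"{date} outside series [{self.start}, {self.end}]")
        return offset

    def temperature_on(self, date: dt.date) -> float:
        return self.tmean_c[self.index_of(date)]


@dataclass(frozen=True)
class FieldRecord:
    """One dated count from winter stem dissections or autumn adult sampling."""

    date: dt.date
    area: str
    record_kind: str
    count: int

    def __post_init__(self) -> None:
        if self.record_kind not in FIELD_KINDS:
            raise ValidationError(
                f"unknown record kind {self.record_kind!r}; expected one of {FIELD_KINDS}"
            )
        if self.count < 1:
            raise ValidationError(
                f"{self.area} {self.date} {self.record_kind}: count must be >= 1"
            )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "cluster_id",
    "temperature_c",
    "rh_regime",
    "age_days",
    "n_alive",
    "n_yellow",
    "n_brown",
    "n_blackhead",
    "n_hatched_cum",
    "n_dead_cum",
]
TEMPS_COLUMNS = ["area", "date", "tmean_c"]
FIELD_COLUMNS = ["date", "area", "record_kind", "count"]
FATES_COLUMNS = [
    "egg_id",
    "cluster_id",
    "temperature_c",
    "rh_regime",
    "outcome",
    "event_age_days",
    "yellow_days",
    "brown_days",
    "blackhead_days",
]


def _read_rows(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        return list(reader)


def load_cluster_observations(path: str | Path) -> list[ClusterObservation]:
    """Read and validate a cluster-observation table.

    Returns records sorted by ``(cluster_id, age_days)``. Besides per-row
    invariants, checks that each cluster keeps a constant condition and a
    constant initial egg count and that cumulative counts never decrease.
    """
    rows = _read_rows(path, COHORT_COLUMNS)
    observations = []
    for row in rows:
        try:
            obs = ClusterObservation(
                cluster_id=row["cluster_id"],
                condition=Condition(float(row["temperature_c"]), row["rh_regime"]),
                age_days=int(row["age_days"]),
                n_alive=int(row["n_alive"]),
                n_yellow=int(row["n_yellow"]),
                n_brown=int(row["n_brown"]),
                n_blackhead=int(row["n_blackhead"]),
                n_hatched_cum=int(row["n_hatched_cum"]),
                n_dead_cum=int(row["n_dead_cum"]),
            )
        except ValueError as exc:
            raise ValidationError(
                f"cluster {row.get('cluster_id')} age {row.get('age_days')}: {exc}"
            ) from exc
        observations.append(obs)
    observations.sort(key=lambda o: (o.cluster_id, o.age_days))
    _validate_cluster_consistency(observations)
    return observations


def _validate_cluster_consistency(observations: Sequence[ClusterObservation]) -> None:
    by_cluster: dict[str, list[ClusterObservation]] = defaultdict(list)
    for obs in observations:
        by_cluster[obs.cluster_id].append(obs)
    for cid, group in by_cluster.items():
        group.sort(key=lambda o: o.age_days)
        first = group[0]
        for obs in group[1:]:
            if obs.condition != first.condition:
                raise ValidationError(
                    f"cluster {cid} age {obs.age_days}: condition changes within cluster"
                )
            if obs.initial_count != first.initial_count:
                raise ValidationError(
                    f"cluster {cid} age {obs.age_days}: initial egg count "
                    f"{obs.initial_count} != {first.initial_count} at age {first.age_days}"
                )
        for prev, cur in zip(group, group[1:]):
            if cur.n_hatched_cum < prev.n_hatched_cum or cur.n_dead_cum < prev.n_dead_cum:
                raise ValidationError(
                    f"cluster {cid} age {cur.age_days}: cumulative count decreased"
                )


def write_cluster_observations(
    observations: Iterable[ClusterObservation], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for o in observations:
            writer.writerow(
                [
                    o.cluster_id,
                    _fmt_float(o.condition.temperature_c),
                    o.condition.rh_regime,
                    o.age_days,
                    o.n_alive,
                    o.n_yellow,
                    o.n_brown,
                    o.n_blackhead,
                    o.n_hatched_cum,
                    o.n_dead_cum,
                ]
            )


def load_temperature_series(path: str | Path) -> list[TemperatureSeries]:
    """Read ``temps.csv`` and return one series per area, sorted by area."""
    rows = _read_rows(path, TEMPS_COLUMNS)
    by_area: dict[str, list[tuple[dt.date, float]]] = defaultdict(list)
    for row in rows:
        by_area[row["area"]].append(
            (dt.date.fromisoformat(row["date"]), float(row["tmean_c"]))
        )
    out = []
    for area in sorted(by_area):
        recs = sorted(by_area[area])
        out.append(
            TemperatureSeries(
                area=area,
                dates=tuple(d for d, _ in recs),
                tmean_c=tuple(t for _, t in recs),
            )
        )
    return out


def write_temperature_series(series: Iterable[TemperatureSeries], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TEMPS_COLUMNS)
        for s in series:
            for date, t in zip(s.dates, s.tmean_c):
                writer.writerow([s.area, date.isoformat(), _fmt_float(t)])


def load_field_records(path: str | Path) -> list[FieldRecord]:
    rows = _read_rows(path, FIELD_COLUMNS)
    records = [
        FieldRecord(
            date=dt.date.fromisoformat(row["date"]),
            area=row["area"],
            record_kind=row["record_kind"],
            count=int(row["count"]),
        )
        for row in rows
    ]
    records.sort(key=lambda r: (r.area, r.date, r.record_kind))
    return records


def write_field_records(records: Iterable[FieldRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FIELD_COLUMNS)
        for r in records:
            writer.writerow([r.date.isoformat(), r.area, r.record_kind, r.count])


def load_fates(path: str | Path) -> list[EggFate]:
    """Read a per-egg long-format fate table (the ground-truth format)."""
    rows = _read_rows(path, FATES_COLUMNS)
    fates = []
    for row in rows:
        stages = None
        if row["yellow_days"] not in ("", None):
            stages = (
                int(row["yellow_days"]),
                int(row["brown_days"]),
                int(row["blackhead_days"]),
            )
        fates.append(
            EggFate(
                egg_id=row["egg_id"],
                cluster_id=row["cluster_id"],
                condition=Condition(float(row["temperature_c"]), row["rh_regime"]),
                outcome=row["outcome"],
                event_age_days=int(row["event_age_days"]),
                stage_durations=stages,
            )
        )
    fates.sort(key=lambda f: (f.cluster_id, f.egg_id))
    return fates


def write_fates(fates: Iterable[EggFate], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FATES_COLUMNS)
        for f in fates:
            stages = f.stage_durations or ("", "", "")
            writer.writerow(
                [
                    f.egg_id,
                    f.cluster_id,
                    _fmt_float(f.condition.temperature_c),
                    f.condition.rh_regime,
                    f.outcome,
                    f.event_age_days,
                    *stages,
                ]
            )


def _fmt_float(x: float) -> str:
    return repr(float(x)) if x != int(x) else str(int(x))


# ---------------------------------------------------------------------------
# Per-egg fate derivation
# ---------------------------------------------------------------------------

def derive_fates(
    observations: Sequence[ClusterObservation],
    horizon_days: int | None = None,
) -> list[EggFate]:
    """Resolve daily cluster tables into one :class:`EggFate` per initial egg.

    An egg whose cumulative hatch (death) count increments between ages
    ``t-1`` and ``t`` hatched (died) at age ``t`` — the day of first
    detection. Eggs still alive at the observation horizon are censored
    there. Per-cluster tallies reconcile exactly with the final cumulative
    counts.

    Colour-stage durations are attached to hatched eggs only when the
    cluster-level colour trajectory determines them unambiguously: every
    observed age has all live eggs in a single colour stage and all hatches
    occur at one age.
    """
    by_cluster: dict[str, list[ClusterObservation]] = defaultdict(list)
    for obs in observations:
        by_cluster[obs.cluster_id].append(obs)

    fates: list[EggFate] = []
    for cid in sorted(by_cluster):
        group = sorted(by_cluster[cid], key=lambda o: o.age_days)
        ages = [o.age_days for o in group]
        for expected, (prev, cur) in enumerate(zip(ages, ages[1:]), start=ages[0] + 1):
            if cur != prev + 1:
                raise ValidationError(
                    f"cluster {cid}: missing daily observation at age {prev + 1}"
                )
        if ages[0] != 0:
            raise ValidationError(f"cluster {cid}: observations must start at age 0")
        _validate_cluster_consistency(group)

        condition = group[0].condition
        n0 = group[0].initial_count
        last = group[-1]
        horizon = horizon_days if horizon_days is not None else last.age_days
        if horizon < last.age_days:
            raise ValidationError(
                f"cluster {cid}: horizon {horizon} earlier than last observed age "
                f"{last.age_days}"
            )

        stage_alloc = _lockstep_stage_durations(group)

        counter = 0

        def _next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{cid}:e{counter:03d}"

        for prev, cur in zip(group, group[1:]):
            t = cur.age_days
            for _ in range(cur.n_hatched_cum - prev.n_hatched_cum):
                fates.append(
                    EggFate(
                        egg_id=_next_id(),
                        cluster_id=cid,
                        condition=condition,
                        outcome="hatched",
                        event_age_days=t,
                        stage_durations=stage_alloc.get(t),
                    )
                )
            for _ in range(cur.n_dead_cum - prev.n_dead_cum):
                fates.append(
                    EggFate(
                        egg_id=_next_id(),
                        cluster_id=cid,
                        condition=condition,
                        outcome="died",
                        event_age_days=t,
                    )
                )
        # hatches/deaths recorded at age 0 cannot be dated more precisely
        # than "within the first day"; they are assigned event age 1.
        for _ in range(group[0].n_hatched_cum):
            fates.append(
                EggFate(
                    egg_id=_next_id(),
                    cluster_id=cid,
                    condition=condition,
                    outcome="hatched",
                    event_age_days=max(1, group[0].age_days),
                )
            )
        for _ in range(group[0].n_dead_cum):
            fates.append(
                EggFate(
                    egg_id=_next_id(),
                    cluster_id=cid,
                    condition=condition,
                    outcome="died",
                    event_age_days=max(1, group[0].age_days),
                )
            )
        for _ in range(last.n_alive):
            fates.append(
                EggFate(
                    egg_id=_next_id(),
                    cluster_id=cid,
                    condition=condition,
                    outcome="censored",
                    event_age_days=max(1, horizon),
                )
            )
        produced = counter
        if produced != n0:
            raise ValidationError(  # pragma: no cover - guarded by validation above
                f"cluster {cid}: derived {produced} fates for {n0} initial eggs"
            )
    fates.sort(key=lambda f: (f.cluster_id, f.egg_id))
    return fates


def _lockstep_stage_durations(
    group: Sequence[ClusterObservation],
) -> dict[int, tuple[int, int, int]]:
    """Stage durations per hatch age for the unambiguous lockstep case.

    Returns ``{hatch_age: (yellow, brown, blackhead)}`` — non-empty only when
    at every age all live eggs occupy one colour stage and all hatches happen
    at a single age, so each egg's colour history is the cluster's.
    """
    hatch_ages = set()
    for prev, cur in zip(group, group[1:]):
        if cur.n_hatched_cum > prev.n_hatched_cum:
            hatch_ages.add(cur.age_days)
    if len(hatch_ages) != 1:
        return {}
    hatch_age = next(iter(hatch_ages))

    stage_by_age: dict[int, str] = {}
    for obs in group:
        if obs.n_alive == 0:
            continue
        occupied = [
            name
            for name, n in (
                ("yellow", obs.n_yellow),
                ("brown", obs.n_brown),
                ("blackhead", obs.n_blackhead),
            )
            if n > 0
        ]
        if len(occupied) != 1:
            return {}
        stage_by_age[obs.age_days] = occupied[0]
    counts = {"yellow": 0, "brown": 0, "blackhead": 0}
    for age in range(hatch_age):
        stage = stage_by_age.get(age)
        if stage is None:
            return {}
        counts[stage] += 1
    return {hatch_age: (counts["yellow"], counts["brown"], counts["blackhead"])}
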