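"""Synthetic laboratory cohorts, temperature series and field records.

The generator emulates a factorial incubation experiment on weevil egg
clusters: 8 constant temperatures (8–36 °C in 4 °C steps) crossed with three
relative-humidity regimes, 20 replicate clusters of 10–15 eggs per condition,
observed daily until hatch or death. Hatched eggs draw an integer development
duration whose mean follows the linear degree-day law ``K / (T - T0)`` for
the condition's RH regime, inflated above the thermal optimum where the
linear law no longer holds; the duration is partitioned into yellow, brown
and black-head colour stages with brown the longest. Egg survival follows a
per-condition hatch-probability surface whose defaults encode the ordinal
humidity-by-temperature patterns seen in the laboratory study: medium RH
best at the thermal extremes (8 and 36 °C), high RH best at 12–20 °C, low RH
clearly worst at 24–32 °C, and overall survival falling off sharply above
28 °C.

Everything is driven by a single :class:`numpy.random.Generator` seed;
identical parameters and seed give byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import (
    ClusterObservation,
    Condition,
    EggFate,
    FieldRecord,
    TemperatureSeries,
)
from .errors import ParameterError

__all__ = [
    "DEFAULT_TEMPERATURES_C",
    "GeneratorParams",
    "default_design",
    "default_survival_surface",
    "generate_experiment",
    "generate_temperature_series",
    "generate_field_records",
]

DEFAULT_TEMPERATURES_C: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0)

#: Linear-model truths per RH regime: lower development threshold T0 (°C)
#: and thermal constant K (degree-days).
DEFAULT_T0: Mapping[str, float] = {"high": 3.82, "medium": 3.40, "low": 3.30}
DEFAULT_K: Mapping[str, float] = {"high": 209.05, "medium": 230.83, "low": 246.14}

_STAGES = ("yellow", "brown", "blackhead")


def default_survival_surface(
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES_C,
) -> dict[tuple[float, str], float]:
    """Per-condition hatch probabilities encoding the ordinal RH patterns.

    Medium RH is best at 8 and 36 °C (all three regimes distinct there);
    high RH is best at 12–20 °C with medium ≈ low; low RH is worst at
    24–32 °C with medium ≈ high; survival declines steeply at 32–36 °C.
    """
    table = {
        8.0: {"high": 0.80, "medium": 0.95, "low": 0.50},
        12.0: {"high": 0.95, "medium": 0.85, "low": 0.83},
        16.0: {"high": 0.95, "medium": 0.85, "low": 0.84},
        20.0: {"high": 0.93, "medium": 0.84, "low": 0.82},
        24.0: {"high": 0.85, "medium": 0.83, "low": 0.55},
        28.0: {"high": 0.74, "medium": 0.72, "low": 0.45},
        32.0: {"high": 0.45, "medium": 0.43, "low": 0.15},
        36.0: {"high": 0.10, "medium": 0.35, "low": 0.05},
    }
    surface = {}
    for t in temperatures:
        if t not in table:
            raise ParameterError(f"no default hatch probability for {t} °C")
        for regime, p in table[t].items():
            surface[(t, regime)] = p
    return surface


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the cohort generator.

    duration_cv is the coefficient of variation of the (pre-rounding)
    development duration; stage_fractions apportion each duration into
    yellow/brown/blackhead days and must sum to 1 with brown the largest;
    supraoptimal_inflation multiplies mean durations above ``optimum_c``,
    reproducing the slow-down observed beyond the linear range.
    """

    true_T0: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_T0))
    true_K: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_K))
    survival_surface: Mapping[tuple[float, str], float] = field(
        default_factory=default_survival_surface
    )
    duration_cv: float = 0.1
    stage_fractions: tuple[float, float, float] = (0.30, 0.45, 0.25)
    supraoptimal_inflation: float = 1.35
    optimum_c: float = 32.0
    non_developing: frozenset[tuple[float, str]] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.survival_surface.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"hatch probability out of [0,1] at {key}: {p}")
        if self.duration_cv < 0:
            raise ParameterError(f"duration_cv must be >= 0, got {self.duration_cv}")
        if abs(sum(self.stage_fractions) - 1.0) > 1e-9:
            raise ParameterError(
                f"stage fractions {self.stage_fractions} must sum to 1"
            )
        if any(f <= 0 for f in self.stage_fractions):
            raise ParameterError("stage fractions must be positive")
        if self.supraoptimal_inflation < 1.0:
            raise ParameterError("supraoptimal_inflation must be >= 1")

    def mean_duration(self, condition: Condition) -> float:
        """Expected development duration (days) under the linear law."""
        t0 = self.true_T0[condition.rh_regime]
        k = self.true_K[condition.rh_regime]
        if condition.temperature_c <= t0:
            raise ParameterError(
                f"temperature {condition.temperature_c} °C at or below the lower "
                f"threshold {t0} °C for regime {condition.rh_regime!r}"
            )
        mean = k / (condition.temperature_c - t0)
        if condition.temperature_c > self.optimum_c:
            mean *= self.supraoptimal_inflation
        return mean


def default_design(
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES_C,
    regimes: Sequence[str] = ("high", "medium", "low"),
) -> list[Condition]:
    """The full factorial design: every temperature crossed with every regime."""
    return [Condition(t, r) for t in temperatures for r in regimes]


def _largest_remainder(total: int, fractions: Sequence[float]) -> tuple[int, ...]:
    """Apportion ``total`` days among stages by largest-remainder rounding."""
    quotas = [total * f for f in fractions]
    floors = [int(math.floor(q)) for q in quotas]
    remainder = total - sum(floors)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return tuple(floors)


def _draw_duration(rng: np.random.Generator, mean: float, cv: float) -> int:
    if cv <= 1e-12:
        return max(1, round(mean))
    shape = 1.0 / (cv * cv)
    raw = rng.gamma(shape, mean / shape)
    return max(1, round(raw))


def generate_experiment(
    design: Sequence[Condition] | None = None,
    clusters_per_condition: int = 20,
    eggs_per_cluster_range: tuple[int, int] = (10, 15),
    params: GeneratorParams | None = None,
) -> tuple[list[ClusterObservation], list[EggFate]]:
    """Simulate the factorial incubation experiment.

    Per egg: a Bernoulli draw from the survival surface decides hatch vs
    death; hatched eggs draw a discretised-gamma duration with mean
    ``K/(T - T0)`` (times the supraoptimal inflation above the optimum) and
    the configured CV, partitioned into colour stages; dying eggs die at an
    age uniform on [1, would-be duration]. Daily cluster tables are the
    exact tally of the per-egg ground truth, which is returned alongside.
    """
    if design is None:
        design = default_design()
    if params is None:
        params = GeneratorParams()
    lo, hi = eggs_per_cluster_range
    if not 1 <= lo <= hi:
        raise ParameterError(f"invalid eggs-per-cluster range [{lo}, {hi}]")
    if clusters_per_condition < 1:
        raise ParameterError("clusters_per_condition must be >= 1")

    rng = np.random.default_rng(params.seed)
    observations: list[ClusterObservation] = []
    fates: list[EggFate] = []

    for cond in design:
        key = (cond.temperature_c, cond.rh_regime)
        developing = cond.temperature_c > params.true_T0[cond.rh_regime]
        if not developing and key not in params.non_developing:
            raise ParameterError(
                f"{cond.temperature_c} °C is at or below the {cond.rh_regime}-regime "
                f"threshold; flag the condition as non-developing to simulate it"
            )
        try:
            p_hatch = params.survival_surface[key]
        except KeyError:
            raise ParameterError(f"survival surface has no entry for {key}") from None
        mean = params.mean_duration(cond) if developing else 60.0

        for c in range(clusters_per_condition):
            cid = f"T{cond.temperature_c:g}-{cond.rh_regime}-c{c + 1:02d}"
            n_eggs = int(rng.integers(lo, hi + 1))
            eggs = []  # (hatched, event_age, planned stage cut points)
            for e in range(n_eggs):
                hatched = developing and (rng.random() < p_hatch)
                duration = _draw_duration(rng, mean, params.duration_cv)
                stages = _largest_remainder(duration, params.stage_fractions)
                if hatched:
                    event_age = duration
                else:
                    event_age = int(rng.integers(1, duration + 1))
                eggs.append((hatched, event_age, stages))
                fates.append(
                    EggFate(
                        egg_id=f"{cid}:e{e + 1:03d}",
                        cluster_id=cid,
                        condition=cond,
                        outcome="hatched" if hatched else "died",
                        event_age_days=event_age,
                        stage_durations=stages if hatched else None,
                    )
                )
            observations.extend(_tabulate_cluster(cid, cond, eggs))

    return observations, fates


def _tabulate_cluster(
    cid: str,
    cond: Condition,
    eggs: Sequence[tuple[bool, int, tuple[int, int, int]]],
) -> list[ClusterObservation]:
    """Daily census rows for one cluster from per-egg ground truth."""
    max_age = max(age for _, age, _ in eggs)
    rows = []
    for age in range(max_age + 1):
        n_hatched = sum(1 for h, a, _ in eggs if h and a <= age)
        n_dead = sum(1 for h, a, _ in eggs if not h and a <= age)
        colour = {"yellow": 0, "brown": 0, "blackhead": 0}
        for hatched, event_age, (y, b, bh) in eggs:
            if event_age <= age:
                continue
            if age < y:
                colour["yellow"] += 1
            elif age < y + b:
                colour["brown"] += 1
            else:
                colour["blackhead"] += 1
        rows.append(
            ClusterObservation(
                cluster_id=cid,
                condition=cond,
                age_days=age,
                n_alive=len(eggs) - n_hatched - n_dead,
                n_yellow=colour["yellow"],
                n_brown=colour["brown"],
                n_blackhead=colour["blackhead"],
                n_hatched_cum=n_hatched,
                n_dead_cum=n_dead,
            )
        )
    return rows


def generate_temperature_series(
    area: str,
    start_date: dt.date,
    n_days: int,
    annual_mean: float = 15.0,
    annual_amplitude: float = 9.5,
    noise_sd: float = 2.0,
    ar1_rho: float = 0.7,
    seed: int = 0,
    coldest_doy: int = 15,
) -> TemperatureSeries:
    """Sinusoidal annual cycle plus AR(1) weather noise.

    The deterministic part is
    ``annual_mean - annual_amplitude * cos(2π (doy - coldest_doy)/365.25)``,
    coldest in mid-January by default — an Ebro-Valley-like inland
    Mediterranean climate. The AR(1) noise has stationary standard deviation
    ``noise_sd`` and lag-one correlation ``ar1_rho``.
    """
    if n_days < 1:
        raise ParameterError("n_days must be >= 1")
    if annual_amplitude < 0 or noise_sd < 0:
        raise ParameterError("amplitude and noise_sd must be non-negative")
    if not 0.0 <= ar1_rho < 1.0:
        raise ParameterError("ar1_rho must be in [0, 1)")

    rng = np.random.default_rng(seed)
    dates = tuple(start_date + dt.timedelta(days=i) for i in range(n_days))
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = annual_mean - annual_amplitude * np.cos(
        2.0 * np.pi * (doy - coldest_doy) / 365.25
    )
    noise = np.zeros(n_days)
    if noise_sd > 0:
        z = rng.standard_normal(n_days)
        noise[0] = noise_sd * z[0]
        innov_sd = noise_sd * math.sqrt(1.0 - ar1_rho * ar1_rho)
        for i in range(1, n_days):
            noise[i] = ar1_rho * noise[i - 1] + innov_sd * z[i]
    temps = tuple(float(t) for t in seasonal + noise)
    return TemperatureSeries(area=area, dates=dates, tmean_c=temps)


def generate_field_records(
    true_window: tuple[dt.date, dt.date],
    stage_durations_ref: tuple[int, int, int],
    sampling_dates: Sequence[dt.date],
    area: str = "A",
    eggs_per_day: int = 3,
    adult_count: int = 5,
) -> list[FieldRecord]:
    """Field stage records implied by a known oviposition window.

    ``eggs_per_day`` egg clusters are laid on every day of ``true_window``
    and progress yellow → brown → black-head → larva at the reference-
    temperature stage durations; each sampling date reports the stages
    present. Reproductive-adult records span the window's sampling dates.
    """
    if not sampling_dates:
        raise ParameterError("sampling_dates must not be empty")
    start, end = true_window
    if start > end:
        raise ParameterError(f"oviposition window {start}..{end} is empty")
    y, b, bh = stage_durations_ref
    if min(y, b, bh) < 1:
        raise ParameterError("reference stage durations must be >= 1 day")

    records: list[FieldRecord] = []
    lay_dates = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    for s in sorted(sampling_dates):
        counts = {"egg_yellow": 0, "egg_brown": 0, "egg_blackhead": 0, "larva": 0}
        for lay in lay_dates:
            if lay > s:
                continue
            age = (s - lay).days
            if age < y:
                counts["egg_yellow"] += eggs_per_day
            elif age < y + b:
                counts["egg_brown"] += eggs_per_day
            elif age < y + b + bh:
                counts["egg_blackhead"] += eggs_per_day
            else:
                counts["larva"] += eggs_per_day
        for kind, n in counts.items():
            if n > 0:
                records.append(FieldRecord(date=s, area=area, record_kind=kind, count=n))
        if start <= s <= end:
            records.append(
                FieldRecord(
                    date=s, area=area, record_kind="adult_reproductive", count=adult_count
                )
            )
    return records


def write_ground_truth(
    params: GeneratorParams, fates: Iterable[EggFate], path: str | Path
) -> None:
    """Persist generator truths (parameters + per-egg fates) as JSON."""
    payload = {
        "params": {
            "true_T0": dict(params.true_T0),
            "true_K": dict(params.true_K),
            "survival_surface": {
                f"{t:g}:{r}": p for (t, r), p in sorted(params.survival_surface.items())
            },
            "duration_cv": params.duration_cv,
            "stage_fractions": list(params.stage_fractions),
            "supraoptimal_inflation": params.supraoptimal_inflation,
            "optimum_c": params.optimum_c,
            "seed": params.seed,
        },
        "fates": [
            {
                "egg_id": f.egg_id,
                "cluster_id": f.cluster_id,
                "temperature_c": f.condition.temperature_c,
                "rh_regime": f.condition.rh_regime,
                "outcome": f.outcome,
                "event_age_days": f.event_age_days,
                "stage_durations": list(f.stage_durations) if f.stage_durations else None,
            }
            for f in fates
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
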