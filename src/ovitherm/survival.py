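"""Product-limit survival estimation and k-sample log-rank tests.

Implements the age-specific survival rate lx — the probability at laying of
still being alive at age x — for egg cohorts. Death in the egg is the event;
hatching removes the egg from the stage alive and is treated as right-
censoring, as is truncation at the observation horizon. Both the Kaplan–
Meier estimator and the log-rank statistic are computed from first
principles on integer event ages, with deaths processed before censorings at
tied ages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
from scipy import stats

from .cohort import EggFate
from .errors import ParameterError

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "kaplan_meier",
    "logrank_test",
    "pairwise_logrank",
]

GroupBy = str | Callable[[EggFate], Hashable]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate of lx for one group of eggs.

    Arrays are aligned on the distinct death ages; ``lx[i]`` is the estimate
    just after ``event_ages[i]``. Before the first death age lx = 1.
    """

    group: Hashable
    event_ages: tuple[int, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    lx: tuple[float, ...]

    def survival_at(self, age: float) -> float:
        """lx evaluated at ``age`` (right-continuous step function)."""
        value = 1.0
        for t, s in zip(self.event_ages, self.lx):
            if t <= age:
                value = s
            else:
                break
        return value


@dataclass(frozen=True)
class LogRankResult:
    """k-sample log-rank statistic with its chi-square reference."""

    chi2: float
    df: int
    p: float


def _group_key(group_by: GroupBy) -> Callable[[EggFate], Hashable]:
    if callable(group_by):
        return group_by
    if group_by == "condition":
        return lambda f: (f.condition.temperature_c, f.condition.rh_regime)
    if group_by == "temperature":
        return lambda f: f.condition.temperature_c
    if group_by == "rh_regime":
        return lambda f: f.condition.rh_regime
    raise ParameterError(
        f"unknown grouping {group_by!r}; expected 'condition', 'temperature', "
        f"'rh_regime' or a callable"
    )


def _split(fates: Sequence[EggFate], group_by: GroupBy) -> dict[Hashable, list[EggFate]]:
    key = _group_key(group_by)
    groups: dict[Hashable, list[EggFate]] = {}
    for f in fates:
        groups.setdefault(key(f), []).append(f)
    return dict(sorted(groups.items(), key=lambda kv: repr(kv[0])))


def kaplan_meier(fates: Sequence[EggFate], group_by: GroupBy = "condition") -> list[SurvivalCurve]:
    """Kaplan–Meier curves of egg survival, one per group.

    The risk set at age t contains every egg whose event (death, hatch or
    censoring) age is >= t, so eggs leaving at t still count toward deaths
    at t.
    """
    if not fates:
        raise ParameterError("no fates supplied")
    curves = []
    for label, members in _split(fates, group_by).items():
        times = np.array([f.event_age_days for f in members])
        died = np.array([f.outcome == "died" for f in members])
        death_ages = np.unique(times[died])
        at_risk, events, lx = [], [], []
        s = 1.0
        for t in death_ages:
            n = int(np.sum(times >= t))
            d = int(np.sum(died & (times == t)))
            s *= 1.0 - d / n
            at_risk.append(n)
            events.append(d)
            lx.append(s)
        curves.append(
            SurvivalCurve(
                group=label,
                event_ages=tuple(int(t) for t in death_ages),
                at_risk=tuple(at_risk),
                events=tuple(events),
                lx=tuple(lx),
            )
        )
    return curves


def logrank_test(fates: Sequence[EggFate], group_by: GroupBy = "condition") -> LogRankResult:
    """k-sample log-rank test that the groups share one survival curve.

    At each distinct death age the deaths are compared with their
    expectation under the hypergeometric model given the margins; the
    statistic is U' V⁻ U over the first k−1 groups (generalized inverse),
    referred to chi-square with k−1 degrees of freedom.
    """
    groups = _split(fates, group_by)
    k = len(groups)
    if k < 2:
        raise ParameterError(f"log-rank test needs >= 2 groups, got {k}")

    labels = list(groups)
    times_by_group = [np.array([f.event_age_days for f in groups[g]]) for g in labels]
    died_by_group = [
        np.array([f.outcome == "died" for f in groups[g]]) for g in labels
    ]

    all_death_ages = np.unique(
        np.concatenate(
            [t[d] for t, d in zip(times_by_group, died_by_group)]
            or [np.array([], dtype=int)]
        )
    )
    if all_death_ages.size == 0:
        return LogRankResult(chi2=0.0, df=k - 1, p=1.0)

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in all_death_ages:
        n_j = np.array([np.sum(times >= t) for times in times_by_group], dtype=float)
        d_j = np.array(
            [np.sum(d & (times == t)) for times, d in zip(times_by_group, died_by_group)],
            dtype=float,
        )
        n = n_j.sum()
        d = d_j.sum()
        if n <= 1 or d == 0:
            observed += d_j
            expected += d * n_j / n if n > 0 else 0.0
            continue
        observed += d_j
        expected += d * n_j / n
        frac = n_j / n
        hyper = d * (n - d) / (n - 1.0)
        cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    u = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def pairwise_logrank(
    fates: Sequence[EggFate], group_by: GroupBy = "rh_regime"
) -> dict[tuple[Hashable, Hashable], LogRankResult]:
    """Two-group log-rank tests for every unordered pair of groups (df = 1).

    Raw p-values are reported without multiplicity adjustment.
    """
    groups = _split(fates, group_by)
    if len(groups) < 2:
        raise ParameterError("pairwise log-rank needs >= 2 groups")
    results = {}
    for a, b in itertools.combinations(groups, 2):
        subset = groups[a] + groups[b]
        results[(a, b)] = logrank_test(subset, group_by)
    return results
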