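"""Development-time analysis: summaries, Poisson GLM and post-hoc groupings.

Hatch age in integer days is modelled as a Poisson count with a log link —
the convention in incubation studies even though a duration is not a true
count; the Pearson dispersion is reported so overdispersion is visible.
Per-term chi-squares come from Type-II analysis of deviance (each term
dropped from the model holding every other term that does not contain it).
Post-hoc comparisons use Tukey's HSD with studentized-range critical values
on the linear-predictor scale, summarised as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import chi2 as chi2_dist
from scipy.stats import studentized_range

from .cohort import EggFate
from .errors import FitError, ParameterError

__all__ = [
    "GlmResult",
    "PosthocGroups",
    "fates_frame",
    "stage_duration_frame",
    "summarize_development",
    "fit_duration_glm",
    "posthoc_groups",
    "colour_stage_durations",
]

_STAGE_NAMES = ("yellow", "brown", "blackhead")


def fates_frame(fates: Sequence[EggFate]) -> pd.DataFrame:
    """Hatched eggs as a modelling frame: duration, temperature, rh."""
    rows = [
        {
            "egg_id": f.egg_id,
            "cluster_id": f.cluster_id,
            "temperature": f.condition.temperature_c,
            "rh": f.condition.rh_regime,
            "duration": f.event_age_days,
        }
        for f in fates
        if f.outcome == "hatched"
    ]
    return pd.DataFrame(rows)


def stage_duration_frame(fates: Sequence[EggFate]) -> pd.DataFrame:
    """Long-format frame of colour-stage durations for hatched eggs.

    One row per egg × stage with columns duration, temperature, rh, colour.
    Eggs without stage data are omitted.
    """
    rows = []
    for f in fates:
        if f.outcome != "hatched" or f.stage_durations is None:
            continue
        for name, days in zip(_STAGE_NAMES, f.stage_durations):
            rows.append(
                {
                    "egg_id": f.egg_id,
                    "temperature": f.condition.temperature_c,
                    "rh": f.condition.rh_regime,
                    "colour": name,
                    "duration": days,
                }
            )
    return pd.DataFrame(rows)


def summarize_development(fates: Sequence[EggFate]) -> pd.DataFrame:
    """Mean, standard error and n of hatch age per condition.

    Only eggs that completed development contribute; conditions without any
    hatched egg are absent from the table rather than reported as zero.
    """
    frame = fates_frame(fates)
    if frame.empty:
        return pd.DataFrame(
            columns=["temperature_c", "rh_regime", "mean_days", "se_days", "n"]
        )
    grouped = frame.groupby(["temperature", "rh"], sort=True)["duration"]
    out = grouped.agg(mean_days="mean", sd="std", n="count").reset_index()
    out["se_days"] = out["sd"] / np.sqrt(out["n"])
    out = out.rename(columns={"temperature": "temperature_c", "rh": "rh_regime"})
    return out[["temperature_c", "rh_regime", "mean_days", "se_days", "n"]]


@dataclass
class GlmResult:
    """Fitted Poisson log-link model with Type-II analysis of deviance."""

    terms: tuple[str, ...]
    deviance_chi2: Mapping[str, float]
    df: Mapping[str, int]
    p: Mapping[str, float]
    coefficients: pd.Series
    fitted_means: pd.DataFrame
    deviance: float
    df_resid: int
    dispersion: float
    _model: object = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)

    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "deviance_chi2": [self.deviance_chi2[t] for t in self.terms],
                "df": [self.df[t] for t in self.terms],
                "p": [self.p[t] for t in self.terms],
            }
        )


def _term_formula(terms: Sequence[str], response: str) -> str:
    if not terms:
        return f"{response} ~ 1"
    parts = []
    for term in terms:
        factors = term.split(":")
        parts.append(":".join(f"C({f})" for f in factors))
    return f"{response} ~ " + " + ".join(parts)


def _fit(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, data=data, family=sm.families.Poisson())
        res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise FitError(f"Poisson GLM did not converge: {formula}")
    return res


def fit_duration_glm(
    data: pd.DataFrame | Sequence[EggFate],
    terms: Sequence[str] = ("temperature", "rh", "temperature:rh"),
    response: str = "duration",
) -> GlmResult:
    """Fit the Poisson log-link duration model and test each term.

    ``data`` is either a modelling frame or a fate list (hatched eggs are
    extracted). All factors are treated as categorical. Each term's
    chi-square is the deviance drop from adding it to the model containing
    every other term that does not include it (Type II), with the matching
    df, referred to the chi-square distribution.
    """
    if not isinstance(data, pd.DataFrame):
        data = fates_frame(data)
    if data.empty:
        raise ParameterError("no observations to fit")
    y = data[response]
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ParameterError(f"response {response!r} must be non-negative integers")
    for term in terms:
        for f in term.split(":"):
            if f not in data.columns:
                raise ParameterError(f"factor {f!r} not in data")
            if data[f].nunique() < 2:
                raise ParameterError(f"factor {f!r} has fewer than 2 observed levels")

    full = _fit(_term_formula(terms, response), data)

    deviance_chi2, df, pvals = {}, {}, {}
    for term in terms:
        t_factors = set(term.split(":"))
        # Type II: exclude the term and every term containing it.
        base_terms = [
            t for t in terms if t != term and not t_factors <= set(t.split(":"))
        ]
        with_term = base_terms + [term]
        res_without = _fit(_term_formula(base_terms, response), data)
        res_with = _fit(_term_formula(with_term, response), data)
        chi2 = max(0.0, res_without.deviance - res_with.deviance)
        d = int(res_without.df_resid - res_with.df_resid)
        deviance_chi2[term] = chi2
        df[term] = d
        pvals[term] = float(chi2_dist.sf(chi2, d)) if d > 0 else float("nan")

    factors = sorted({f for t in terms for f in t.split(":")})
    grid = (
        data[factors]
        .drop_duplicates()
        .sort_values(factors)
        .reset_index(drop=True)
    )
    grid["fitted_mean_days"] = np.asarray(full.predict(grid))

    return GlmResult(
        terms=tuple(terms),
        deviance_chi2=deviance_chi2,
        df=df,
        p=pvals,
        coefficients=full.params,
        fitted_means=grid,
        deviance=float(full.deviance),
        df_resid=int(full.df_resid),
        dispersion=float(full.pearson_chi2 / full.df_resid) if full.df_resid > 0 else float("nan"),
        _model=full,
        _data=data,
    )


@dataclass(frozen=True)
class PosthocGroups:
    """Tukey-HSD compact letter display for one factor.

    Levels sharing a letter are not significantly different at ``alpha``.
    Means are reported on the response scale (days).
    """

    factor: str
    levels: tuple
    means: tuple[float, ...]
    letters: tuple[str, ...]
    alpha: float


def posthoc_groups(glm: GlmResult, factor: str, alpha: float = 0.05) -> PosthocGroups:
    """All-pairs Tukey HSD over the levels of ``factor`` in a fitted GLM.

    Level means are estimated marginal means on the linear-predictor scale
    (averaged over the observed levels of the other factors); pairwise
    differences are compared against studentized-range critical values at
    the model's residual df. The letter display is built greedily from the
    sorted means: maximal runs of mutually non-significant levels share a
    letter.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    res = glm._model
    data = glm._data
    if factor not in data.columns:
        raise ParameterError(f"factor {factor!r} not in the fitted data")
    levels = sorted(data[factor].unique())
    k = len(levels)
    if k < 2:
        raise ParameterError(f"factor {factor!r} has a single level")

    other = [
        f
        for t in glm.terms
        for f in t.split(":")
        if f != factor and f in data.columns
    ]
    other = sorted(set(other))
    base_grid = data[other].drop_duplicates() if other else pd.DataFrame(index=[0])

    design_info = res.model.data.design_info
    contrast = np.zeros((k, len(res.params)))
    for i, level in enumerate(levels):
        grid = base_grid.copy()
        grid[factor] = level
        (x,) = patsy.build_design_matrices([design_info], grid)
        contrast[i] = np.asarray(x).mean(axis=0)

    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    eta = contrast @ beta
    vcv = contrast @ cov @ contrast.T

    df_resid = glm.df_resid
    if df_resid < 1:
        raise FitError("no residual degrees of freedom for post-hoc comparison")
    q_crit = studentized_range.ppf(1.0 - alpha, k, df_resid)

    def significant(i: int, j: int) -> bool:
        se = np.sqrt(max(vcv[i, i] + vcv[j, j] - 2.0 * vcv[i, j], 0.0))
        if se == 0.0:
            return False
        return abs(eta[i] - eta[j]) / se > q_crit / np.sqrt(2.0)

    order = np.argsort(eta)
    intervals = []  # maximal runs [lo, hi] of mutually non-significant levels
    for lo in range(k):
        hi = lo
        while hi + 1 < k and all(
            not significant(order[a], order[hi + 1]) for a in range(lo, hi + 1)
        ):
            hi += 1
        intervals.append((lo, hi))
    maximal = [
        iv
        for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    maximal = sorted(set(maximal))
    letters_sorted = ["" for _ in range(k)]
    for letter_idx, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx)
        for pos in range(lo, hi + 1):
            letters_sorted[pos] += letter

    letters = ["" for _ in range(k)]
    for pos, idx in enumerate(order):
        letters[idx] = letters_sorted[pos]

    return PosthocGroups(
        factor=factor,
        levels=tuple(levels),
        means=tuple(float(np.exp(e)) for e in eta),
        letters=tuple(letters),
        alpha=alpha,
    )


def colour_stage_durations(fates: Sequence[EggFate]) -> pd.DataFrame:
    """Mean yellow/brown/blackhead stage durations per condition.

    Uses hatched eggs carrying stage data; stage means sum to the mean total
    duration by construction. Returns an empty frame when no stage data are
    available.
    """
    frame = stage_duration_frame(fates)
    if frame.empty:
        return pd.DataFrame(
            columns=[
                "temperature_c",
                "rh_regime",
                "yellow_mean",
                "brown_mean",
                "blackhead_mean",
                "total_mean",
                "n",
            ]
        )
    wide = (
        frame.pivot_table(
            index=["temperature", "rh"],
            columns="colour",
            values="duration",
            aggfunc="mean",
        )
        .reset_index()
        .rename(
            columns={
                "temperature": "temperature_c",
                "rh": "rh_regime",
                "yellow": "yellow_mean",
                "brown": "brown_mean",
                "blackhead": "blackhead_mean",
            }
        )
    )
    counts = (
        frame[frame["colour"] == "yellow"]
        .groupby(["temperature", "rh"])
        .size()
        .reset_index(name="n")
        .rename(columns={"temperature": "temperature_c", "rh": "rh_regime"})
    )
    wide = wide.merge(counts, on=["temperature_c", "rh_regime"])
    wide["total_mean"] = wide["yellow_mean"] + wide["brown_mean"] + wide["blackhead_mean"]
    return wide[
        [
            "temperature_c",
            "rh_regime",
            "yellow_mean",
            "brown_mean",
            "blackhead_mean",
            "total_mean",
            "n",
        ]
    ]
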