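"""Elispot survival analytics.

Plasma-cell survival in culture is read out by IgG Elispot: each spot is
one antibody-secreting cell. Per-day spot counts are normalized to the
maximum of the day-1-to-3 means (the peak of functional recovery after
sorting), and culture conditions are compared by ordinary least squares of
the normalized percentages on day with a media indicator as covariate, or
by fixed-effects ANOVA across conditions with Benjamini–Hochberg
adjustment of pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .degs import bh_fdr


@dataclass
class ElispotSeries:
    """Per-well spot counts for one culture condition over days."""

    condition: str
    observations: pd.DataFrame  # columns: day, well, spots

    def __post_init__(self) -> None:
        obs = pd.DataFrame(self.observations)
        for col in ("day", "well", "spots"):
            if col not in obs.columns:
                raise ValueError(f"Elispot observations need a {col!r} column")
        if (obs["spots"] < 0).any():
            raise ValueError("spot counts must be non-negative")
        self.observations = obs

    def day_means(self) -> pd.Series:
        return self.observations.groupby("day")["spots"].mean().sort_index()


@dataclass
class NormalizedSurvival:
    condition: str
    percent: pd.Series  # day -> percent of maximum
    reference_day: int
    reference_mean: float


def normalize_survival(series: ElispotSeries) -> NormalizedSurvival:
    """Percent of maximal Elispots, referenced to the day-1..3 peak.

    Wells are averaged per day; the reference is the largest of the day-1,
    -2, -3 means (ties go to the earliest day). A zero reference means no
    surviving cells to normalize against and raises.
    """
    means = series.day_means()
    ref_days = [d for d in (1, 2, 3) if d in means.index]
    if not ref_days:
        raise ValueError(
            f"series {series.condition!r} has no observations on days 1-3"
        )
    ref = means.loc[ref_days]
    ref_day = int(ref.idxmax())  # idxmax takes the first (earliest) maximum
    ref_mean = float(ref.max())
    if ref_mean <= 0:
        raise ValueError(
            f"series {series.condition!r}: day-1..3 maximum is zero; "
            "no surviving ASC to normalize against"
        )
    percent = 100.0 * means / ref_mean
    percent.name = "percent"
    return NormalizedSurvival(series.condition, percent, ref_day, ref_mean)


@dataclass
class MediaComparisonResults:
    """OLS comparison of two conditions: percent ~ day + media indicator."""

    coef: float
    pvalue: float
    ols: object | None  # statsmodels results when the fit is non-degenerate
    condition_a: str
    condition_b: str
    log_scale: bool

    def summary(self) -> str:
        lines = [
            "Media-covariate survival comparison",
            "===================================",
            f"conditions : {self.condition_a} vs {self.condition_b}",
            f"scale      : {'log1p percent' if self.log_scale else 'percent'}",
            f"media coefficient ({self.condition_a} - {self.condition_b}) : "
            f"{self.coef:+.3f}",
            f"p-value    : {self.pvalue:.3g}",
        ]
        return "\n".join(lines)


class MediaComparison:
    """Model comparing survival between two media conditions."""

    def __init__(self, series_a: ElispotSeries, series_b: ElispotSeries,
                 log_scale: bool = False, normalize: bool = True):
        self.series_a = series_a
        self.series_b = series_b
        self.log_scale = log_scale
        self.normalize = normalize

    def fit(self) -> MediaComparisonResults:
        rows = []
        for series, media in ((self.series_a, 1.0), (self.series_b, 0.0)):
            if self.normalize:
                percent = normalize_survival(series).percent
            else:
                # input already on the percent scale (per-day means)
                percent = series.day_means()
            for day, pct in percent.items():
                rows.append({"day": float(day), "media": media, "percent": pct})
        na_days = self.series_a.day_means().index
        nb_days = self.series_b.day_means().index
        df = pd.DataFrame(rows)
        if len(df) < 3 or na_days.nunique() < 2 or nb_days.nunique() < 2:
            raise ValueError(
                "media comparison needs >=3 pooled points and >=2 days per series"
            )
        y = np.log1p(df["percent"]) if self.log_scale else df["percent"]
        x = sm.add_constant(df[["day", "media"]])
        fit = sm.OLS(y, x).fit()
        coef = float(fit.params["media"])
        p = float(fit.pvalues["media"])
        if not np.isfinite(p):
            # zero residual variance: the fit is exact
            p = 1.0 if abs(coef) < 1e-12 else 0.0
        if fit.ssr <= 1e-12 * max(1.0, float(np.sum(np.asarray(y) ** 2))):
            p = 1.0 if abs(coef) < 1e-12 else 0.0
        return MediaComparisonResults(
            coef=coef, pvalue=p, ols=fit,
            condition_a=self.series_a.condition,
            condition_b=self.series_b.condition,
            log_scale=self.log_scale,
        )


def compare_media(
    series_a: ElispotSeries,
    series_b: ElispotSeries,
    log_scale: bool = False,
    normalize: bool = True,
) -> tuple[float, float]:
    """Media coefficient (series_a minus series_b) and its p-value."""
    res = MediaComparison(series_a, series_b, log_scale, normalize).fit()
    return res.coef, res.pvalue


def anova_conditions(
    series_list: list[ElispotSeries],
    include_day: bool = True,
    pairwise: bool = False,
):
    """Fixed-effects ANOVA of normalized survival across conditions.

    With ``include_day`` the model has day and condition as fixed effects
    (two-way, no interaction); otherwise one-way on condition alone.
    Returns (F, p) for the condition effect; with ``pairwise=True`` also a
    table of BH-adjusted pairwise media comparisons.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two conditions")
    rows = []
    for s in series_list:
        norm = normalize_survival(s)
        for day, pct in norm.percent.items():
            rows.append({"condition": s.condition, "day": float(day), "percent": pct})
    df = pd.DataFrame(rows)

    conds = sorted(df["condition"].unique())
    cond_dummies = pd.get_dummies(df["condition"], drop_first=True, dtype=float)
    parts = [np.ones(len(df))]
    if include_day:
        day_dummies = pd.get_dummies(df["day"], drop_first=True, dtype=float)
        parts.append(day_dummies.to_numpy())
    x_reduced = np.column_stack(parts)
    x_full = np.column_stack([x_reduced, cond_dummies.to_numpy()])
    y = df["percent"].to_numpy(dtype=float)

    rss_r = _rss(x_reduced, y)
    rss_f = _rss(x_full, y)
    df_num = cond_dummies.shape[1]
    df_den = len(df) - x_full.shape[1]
    if df_den <= 0:
        raise ValueError("not enough observations for the requested model")
    if rss_r - rss_f <= 1e-12 * max(1.0, rss_r):
        f_stat, p = 0.0, 1.0
    elif rss_f <= 1e-12 * max(1.0, rss_r):
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    if not pairwise:
        return f_stat, p
    pairs = []
    by_name = {s.condition: s for s in series_list}
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            coef, pv = compare_media(by_name[a], by_name[b])
            pairs.append({"condition_a": a, "condition_b": b, "coef": coef, "p": pv})
    pair_table = pd.DataFrame(pairs)
    pair_table["q"] = bh_fdr(pair_table["p"].to_numpy())
    return f_stat, p, pair_table


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)
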