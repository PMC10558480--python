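"""Season coding, group statistics, and cosinor periodicity inference.

Acquisition seasons are quarters: spring Feb 1 – Apr 30, summer May 1 –
Jul 31, autumn Aug 1 – Oct 31, winter Nov 1 – Jan 31 (a winter spans the
year boundary and is attributed to its starting year). For rhythm fitting
the quarters are coded t = 0, 1, 2, 3 (winter → autumn) with period T = 4,
and each measure is modeled as

    y(t) = A·cos(ωt + ϑ) + c  =  a·sin(ωt) + b·cos(ωt) + c,   ω = 2π/T,

fit by ordinary least squares with one observation per subject. The joint
F-test of (a, b) against the intercept-only model, with (2, n−3) degrees
of freedom, quantifies the significance of annual periodicity. Amplitude
and phase follow from b = A·cos ϑ, a = −A·sin ϑ.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SEASONS = ("winter", "spring", "summer", "autumn")
SEASON_TO_T = {s: i for i, s in enumerate(SEASONS)}
PERIOD = 4
OMEGA = 2.0 * np.pi / PERIOD

#: month → season; winter months carry over the year boundary.
_MONTH_SEASON = {
    2: "spring", 3: "spring", 4: "spring",
    5: "summer", 6: "summer", 7: "summer",
    8: "autumn", 9: "autumn", 10: "autumn",
    11: "winter", 12: "winter", 1: "winter",
}


def season_of_date(date: _dt.date | str) -> tuple[str, int]:
    """Map an acquisition date to (season, cohort year).

    January belongs to the winter that started the previous November, so
    its cohort year is the preceding calendar year.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if not isinstance(date, _dt.date):
        raise TypeError("expected a datetime.date or ISO date string")
    season = _MONTH_SEASON[date.month]
    year = date.year - 1 if date.month == 1 else date.year
    return season, year


def _as_groups(values, seasons) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    seasons = list(seasons)
    if len(values) != len(seasons):
        raise ValueError("values and seasons lengths differ")
    unknown = sorted(set(seasons) - set(SEASONS))
    if unknown:
        raise ValueError(f"unknown season label(s): {unknown}")
    return {
        s: values[[i for i, g in enumerate(seasons) if g == s]]
        for s in SEASONS
        if s in seasons
    }


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA across season groups."""

    F: float
    p: float
    cohens_f: float
    df: tuple[int, int]
    group_stats: pd.DataFrame

    def __post_init__(self) -> None:
        if self.F < 0 or self.cohens_f < 0:
            raise ValueError("F and Cohen's f must be nonnegative")


@dataclass
class PairwiseResult:
    """Pooled-variance two-sample t contrast between two seasons."""

    season_a: str
    season_b: str
    t_stat: float
    p: float
    cohens_d: float
    df: int


@dataclass
class SeasonalFit:
    """Cosinor fit of a measure on quarter-coded season."""

    a: float
    b: float
    c: float
    amplitude: float
    phase: float
    F_stat: float
    p_value: float
    df: tuple[int, int]
    effect_f: float
    band: pd.DataFrame = field(repr=False)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * np.sin(OMEGA * t) + self.b * np.cos(OMEGA * t) + self.c

    @property
    def peak_quarter(self) -> int:
        """Quarter t in {0..3} at which the fitted mean is largest."""
        return int(np.argmax(self.predict(np.arange(PERIOD))))


@dataclass
class EnvRegressionResult:
    """OLS of an adjusted measure on temperature, daylength and intercept."""

    coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    F_stat: float
    p_value: float
    effect_f: float
    r_squared: float


def anova_seasons(values, seasons) -> AnovaResult:
    """One-way ANOVA of a per-subject measure across season groups.

    Cohen's f is derived from the explained-variance fraction,
    f = sqrt(η² / (1 − η²)) with η² = SS_between / SS_total.
    """
    groups = _as_groups(values, seasons)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two nonempty season groups")
    y = np.concatenate(list(groups.values()))
    n, k = y.size, len(groups)
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = y.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    ss_total = ss_between + ss_within
    if ss_total <= 0:
        raise ValueError("zero total variance; ANOVA undefined")
    df = (k - 1, n - k)
    if ss_within == 0:
        F, p = np.inf, 0.0
    else:
        F = (ss_between / df[0]) / (ss_within / df[1])
        p = float(stats.f.sf(F, *df))
    eta2 = ss_between / ss_total
    cohens_f = float(np.sqrt(eta2 / (1.0 - eta2))) if eta2 < 1 else np.inf
    rows = []
    for s, g in groups.items():
        sem = g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else np.nan
        rows.append({"season": s, "n": g.size, "mean": g.mean(), "sem": sem})
    return AnovaResult(float(F), float(p), cohens_f, df, pd.DataFrame(rows))


def pairwise_seasons(values, seasons, season_a: str, season_b: str) -> PairwiseResult:
    """Pooled-variance Student t contrast with pooled-SD Cohen's d.

    No multiple-comparison correction is applied; callers comparing many
    pairs can correct the returned p-values themselves.
    """
    groups = _as_groups(values, seasons)
    for s in (season_a, season_b):
        if s not in groups or groups[s].size < 2:
            raise ValueError(f"season {s!r} needs at least 2 subjects")
    g1, g2 = groups[season_a], groups[season_b]
    n1, n2 = g1.size, g2.size
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance; contrast undefined")
    t_stat, p = stats.ttest_ind(g1, g2, equal_var=True)
    d = (g1.mean() - g2.mean()) / np.sqrt(pooled_var)
    return PairwiseResult(season_a, season_b, float(t_stat), float(p), float(d), n1 + n2 - 2)


def _design(t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t), np.sin(OMEGA * t), np.cos(OMEGA * t)])


def fit_seasonal_sinusoid(values, seasons, alpha: float = 0.05) -> SeasonalFit:
    """Quarter-coded cosinor fit with periodicity F-test and confidence band.

    Subjects are the observation unit. Requires observations spanning at
    least three distinct seasons so the sin/cos/intercept design has full
    rank. The confidence band is the standard OLS pointwise band for the
    mean response over continuous t ∈ [0, 4).
    """
    values = np.asarray(values, dtype=float)
    groups = _as_groups(values, seasons)
    if len(groups) < 3:
        raise ValueError("cosinor fit needs subjects in at least 3 distinct seasons")
    if values.size < 4:
        raise ValueError("cosinor fit needs at least 4 observations")
    t = np.array([SEASON_TO_T[s] for s in seasons], dtype=float)
    X = _design(t)
    if np.linalg.matrix_rank(X) < 3:  # pragma: no cover - guarded above
        raise ValueError("rank-deficient cosinor design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits trigger division warnings
        res = sm.OLS(values, X).fit()
    c, a, b = res.params
    A = float(np.hypot(a, b))
    phase = float(np.arctan2(-a, b)) if A > 0 else 0.0
    if phase <= -np.pi:
        phase = np.pi
    df = (2, int(res.df_resid))
    if res.ssr <= 1e-12 * max(res.centered_tss, 1.0):
        if res.centered_tss <= 1e-300:
            F, p = 0.0, 1.0  # constant input: no seasonal signal at all
        else:
            F, p = np.inf, 0.0
    else:
        F, p = float(res.fvalue), float(res.f_pvalue)
    r2 = float(res.rsquared) if res.centered_tss > 0 else 0.0
    effect_f = float(np.sqrt(r2 / (1 - r2))) if r2 < 1 else np.inf
    t_grid = np.arange(0.0, PERIOD, 0.05)
    Xg = _design(t_grid)
    fit_mean = Xg @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, res.cov_params(), Xg))
    crit = stats.t.ppf(1 - alpha / 2, df[1]) if df[1] > 0 else np.nan
    band = pd.DataFrame(
        {"t": t_grid, "fit": fit_mean, "lo": fit_mean - crit * se, "hi": fit_mean + crit * se}
    )
    return SeasonalFit(float(a), float(b), float(c), A, phase, F, p, df, effect_f, band)


def environmental_regression(
    values,
    season_years,
    env,
    lag_quarters: int = 0,
    max_condition: float = 1e10,
) -> EnvRegressionResult:
    """OLS of adjusted measures on environmental covariates.

    Each subject contributes its season-year's mean temperature and
    daylength (optionally lagged backwards by whole quarters) as
    regressors; per-coefficient t-tests and the overall F-test quantify
    the environmental association. A condition-number guard rejects
    (near-)collinear temperature/daylength designs.
    """
    values = np.asarray(values, dtype=float)
    season_years = list(season_years)
    if len(values) != len(season_years):
        raise ValueError("values and season_years lengths differ")
    temp = np.empty(len(values))
    day = np.empty(len(values))
    for i, (season, year) in enumerate(season_years):
        q = year * PERIOD + SEASON_TO_T[season] - lag_quarters
        row = env.lookup(q % PERIOD, q // PERIOD)
        temp[i] = row.mean_temperature
        day[i] = row.mean_daylength
    X = np.column_stack([temp, day, np.ones_like(temp)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient environmental design (temperature/daylength constant "
            "or perfectly collinear)"
        )
    cond = np.linalg.cond(X)
    if cond > max_condition:
        raise ValueError(
            f"ill-conditioned environmental design (condition number {cond:.3g}); "
            "temperature and daylength are nearly collinear"
        )
    res = sm.OLS(values, X).fit()
    names = ("temperature", "daylength", "intercept")
    r2 = float(res.rsquared)
    effect_f = float(np.sqrt(r2 / (1 - r2))) if r2 < 1 else np.inf
    return EnvRegressionResult(
        coefficients=dict(zip(names, map(float, res.params))),
        coefficient_p=dict(zip(names, map(float, res.pvalues))),
        F_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        effect_f=effect_f,
        r_squared=r2,
    )


def season_group_summary(values, seasons) -> pd.DataFrame:
    """Per-season mean and SEM (sd/√n), ordered winter → autumn.

    Groups of one subject have no SEM; it is reported missing with a
    warning rather than as zero.
    """
    groups = _as_groups(values, seasons)
    rows = []
    for s in SEASONS:
        if s not in groups:
            continue
        g = groups[s]
        if g.size == 1:
            warnings.warn(f"season {s!r} has a single subject; SEM undefined", stacklevel=2)
            sem = np.nan
        else:
            sem = g.std(ddof=1) / np.sqrt(g.size)
        rows.append({"season": s, "n": g.size, "mean": g.mean(), "sem": sem})
    return pd.DataFrame(rows)
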