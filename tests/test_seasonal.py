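"""Season coding, ANOVA, pairwise contrasts, cosinor fit, env regression."""

import numpy as np
import pandas as pd
import pytest

import seasonfc as sf
from seasonfc.seasonal import OMEGA, SEASON_TO_T
from seasonfc.synthetic import EnvironmentTable


@pytest.mark.parametrize(
    "date, season, year",
    [
        ("2014-03-15", "spring", 2014),
        ("2014-02-01", "spring", 2014),
        ("2014-04-30", "spring", 2014),
        ("2014-05-01", "summer", 2014),
        ("2014-07-31", "summer", 2014),
        ("2014-08-01", "autumn", 2014),
        ("2014-10-31", "autumn", 2014),
        ("2013-11-01", "winter", 2013),
        ("2013-12-25", "winter", 2013),
        ("2014-01-31", "winter", 2013),  # January belongs to the preceding winter
    ],
)
def test_season_of_date(date, season, year):
    assert sf.season_of_date(date) == (season, year)


def test_season_of_date_rejects_invalid():
    with pytest.raises(ValueError):
        sf.season_of_date("2014-13-01")
    with pytest.raises(TypeError):
        sf.season_of_date(20140301)


def test_anova_equal_means_is_zero():
    vals = [1, 2, 1, 2, 1, 2, 1, 2]
    seasons = ["winter"] * 2 + ["spring"] * 2 + ["summer"] * 2 + ["autumn"] * 2
    res = sf.anova_seasons(vals, seasons)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.cohens_f == pytest.approx(0.0, abs=1e-12)


def test_anova_matches_sum_of_squares_oracle():
    vals = np.array([1, 2, 1, 2, 5, 6, 5, 6], dtype=float)
    seasons = ["winter"] * 2 + ["spring"] * 2 + ["summer"] * 2 + ["autumn"] * 2
    res = sf.anova_seasons(vals, seasons)
    # independent oracle: explicit SS decomposition
    grand = vals.mean()
    groups = [vals[0:2], vals[2:4], vals[4:6], vals[6:8]]
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    F = (ssb / 3) / (ssw / 4)
    from scipy.stats import f as fdist

    assert res.F == pytest.approx(F, rel=1e-12)
    assert res.p == pytest.approx(fdist.sf(F, 3, 4), rel=1e-12)
    eta2 = ssb / (ssb + ssw)
    assert res.cohens_f == pytest.approx(np.sqrt(eta2 / (1 - eta2)), rel=1e-12)
    assert res.df == (3, 4)


def test_anova_null_rejection_rate_under_permutation(rng):
    """Permuting season labels makes p approximately uniform."""
    vals = rng.standard_normal(40)
    seasons = np.repeat(sf.SEASONS, 10)
    rej = 0
    reps = 2000
    for _ in range(reps):
        rej += sf.anova_seasons(vals, rng.permutation(seasons)).p < 0.05
    assert abs(rej / reps - 0.05) <= 0.01


def test_anova_requires_variance_and_groups():
    with pytest.raises(ValueError):
        sf.anova_seasons([1.0, 1.0, 1.0], ["winter"] * 3)
    with pytest.raises(ValueError):
        sf.anova_seasons([2.0, 2.0, 2.0, 2.0], ["winter", "winter", "summer", "summer"])


def test_pairwise_hand_computed_example():
    vals = [1.0, 2.0, 3.0, 4.0]
    seasons = ["autumn", "autumn", "summer", "summer"]
    res = sf.pairwise_seasons(vals, seasons, "autumn", "summer")
    assert res.cohens_d == pytest.approx(-2 / np.sqrt(0.5), rel=1e-12)
    assert res.t_stat == pytest.approx(-2.8284271247461903, rel=1e-10)
    assert res.df == 2
    assert np.sign(res.cohens_d) == np.sign(1.5 - 3.5)


def test_pairwise_identical_groups_and_antisymmetry(rng):
    vals = np.concatenate([rng.standard_normal(10)] * 2)
    seasons = ["winter"] * 10 + ["spring"] * 10
    res = sf.pairwise_seasons(vals, seasons, "winter", "spring")
    assert res.t_stat == pytest.approx(0.0, abs=1e-12)
    assert res.cohens_d == pytest.approx(0.0, abs=1e-12)
    vals2 = rng.standard_normal(20)
    a = sf.pairwise_seasons(vals2, seasons, "winter", "spring")
    b = sf.pairwise_seasons(vals2, seasons, "spring", "winter")
    assert a.cohens_d == pytest.approx(-b.cohens_d, rel=1e-12)
    assert a.t_stat == pytest.approx(-b.t_stat, rel=1e-12)


def test_pairwise_zero_pooled_sd_rejected():
    with pytest.raises(ValueError):
        sf.pairwise_seasons([1, 1, 2, 2], ["winter"] * 2 + ["spring"] * 2,
                            "winter", "spring")


def test_cosinor_exact_worked_example():
    fit = sf.fit_seasonal_sinusoid([3.0, 2.0, 1.0, 2.0],
                                   ["winter", "spring", "summer", "autumn"])
    assert fit.a == pytest.approx(0.0, abs=1e-10)
    assert fit.b == pytest.approx(1.0, abs=1e-10)
    assert fit.c == pytest.approx(2.0, abs=1e-10)
    assert fit.amplitude == pytest.approx(1.0, abs=1e-10)
    assert fit.phase == pytest.approx(0.0, abs=1e-10)
    assert fit.peak_quarter == SEASON_TO_T["winter"]


def test_cosinor_constant_input():
    fit = sf.fit_seasonal_sinusoid([2.0] * 8, list(sf.SEASONS) * 2)
    assert fit.amplitude == pytest.approx(0.0, abs=1e-10)
    assert fit.F_stat == pytest.approx(0.0, abs=1e-10)


def test_cosinor_reconstruction_identity(rng):
    """A·cos(ωt+ϑ)+c reproduces a·sin(ωt)+b·cos(ωt)+c at every quarter."""
    for _ in range(25):
        y = rng.standard_normal(16)
        seasons = list(np.repeat(sf.SEASONS, 4))
        fit = sf.fit_seasonal_sinusoid(y, seasons)
        t = np.arange(4.0)
        recon = fit.amplitude * np.cos(OMEGA * t + fit.phase) + fit.c
        direct = fit.a * np.sin(OMEGA * t) + fit.b * np.cos(OMEGA * t) + fit.c
        assert np.allclose(recon, direct, atol=1e-10)
        assert fit.amplitude >= 0
        assert -np.pi < fit.phase <= np.pi


def test_cosinor_grand_mean_for_balanced_design(rng):
    y = rng.standard_normal(4)
    fit = sf.fit_seasonal_sinusoid(y, list(sf.SEASONS))
    assert fit.c == pytest.approx(y.mean(), abs=1e-10)


def test_cosinor_band_shape_and_df():
    y = np.tile([3.0, 2.0, 1.0, 2.0], 5) + np.linspace(0, 0.1, 20)
    fit = sf.fit_seasonal_sinusoid(y, list(sf.SEASONS) * 5)
    assert fit.df == (2, 17)
    assert (fit.band["lo"] <= fit.band["fit"]).all()
    assert (fit.band["fit"] <= fit.band["hi"]).all()
    assert fit.band["t"].min() == 0.0 and fit.band["t"].max() < 4.0


def test_cosinor_needs_three_seasons():
    with pytest.raises(ValueError):
        sf.fit_seasonal_sinusoid([1.0, 2.0, 3.0, 4.0],
                                 ["winter", "winter", "summer", "summer"])


def test_cosinor_and_anova_agree_under_null_and_effect(rng):
    """Both tests reject strong injected rhythms and stay quiet under null."""
    seasons = list(np.repeat(sf.SEASONS, 25))
    t = np.array([SEASON_TO_T[s] for s in seasons], float)
    strong = 1.0 * np.cos(OMEGA * t + np.pi / 2) + rng.standard_normal(100)
    assert sf.fit_seasonal_sinusoid(strong, seasons).p_value < 0.01
    assert sf.anova_seasons(strong, seasons).p < 0.01


def _env_frame(years=(2013, 2014), rng=None):
    rng = rng or np.random.default_rng(7)
    rows = []
    for year in years:
        for t in range(4):
            rows.append({
                "season_index": t, "year": year,
                "mean_temperature": 13.5 + 12.0 * np.cos(2 * np.pi * (t - 2) / 4)
                + rng.normal(scale=1.0),
                "mean_daylength": 12.2 + 2.5 * np.cos(2 * np.pi * (t - 2) / 4)
                + rng.normal(scale=0.2),
            })
    return EnvironmentTable(pd.DataFrame(rows))


def test_environmental_regression_exact_recovery(rng):
    env = _env_frame()
    season_years = [(s, y) for y in (2013, 2014) for s in sf.SEASONS] * 3
    temp = np.array([env.lookup(SEASON_TO_T[s], y).mean_temperature for s, y in season_years])
    day = np.array([env.lookup(SEASON_TO_T[s], y).mean_daylength for s, y in season_years])
    values = 0.5 * temp + 0.1 * day + 2.0
    res = sf.environmental_regression(values, season_years, env)
    assert res.coefficients["temperature"] == pytest.approx(0.5, abs=1e-8)
    assert res.coefficients["daylength"] == pytest.approx(0.1, abs=1e-8)
    assert res.coefficients["intercept"] == pytest.approx(2.0, abs=1e-7)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)


def test_environmental_regression_null_rate(rng):
    env = _env_frame()
    season_years = [(s, y) for y in (2013, 2014) for s in sf.SEASONS] * 5
    rej = 0
    reps = 500
    for _ in range(reps):
        res = sf.environmental_regression(rng.standard_normal(len(season_years)),
                                          season_years, env)
        rej += res.p_value < 0.05
    assert abs(rej / reps - 0.05) <= 0.025


def test_environmental_regression_degenerate_design():
    rows = [{"season_index": t, "year": 2013, "mean_temperature": 10.0,
             "mean_daylength": 12.0} for t in range(4)]
    env = EnvironmentTable(pd.DataFrame(rows))
    season_years = [(s, 2013) for s in sf.SEASONS] * 2
    with pytest.raises(ValueError):
        sf.environmental_regression(np.arange(8.0), season_years, env)


def test_environmental_regression_lag_uses_shifted_rows(rng):
    env = _env_frame(years=(2012, 2013, 2014))
    season_years = [(s, y) for y in (2013, 2014) for s in sf.SEASONS] * 2
    # values driven by the environment one quarter earlier
    lagged = []
    for s, y in season_years:
        q = y * 4 + SEASON_TO_T[s] - 1
        row = env.lookup(q % 4, q // 4)
        lagged.append(0.3 * row.mean_temperature + 1.0)
    res = sf.environmental_regression(np.array(lagged), season_years, env, lag_quarters=1)
    assert res.coefficients["temperature"] == pytest.approx(0.3, abs=1e-8)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)


def test_season_group_summary():
    vals = [1.0, 2.0, 3.0, 5.0]
    seasons = ["winter", "winter", "winter", "summer"]
    with pytest.warns(UserWarning, match="single subject"):
        out = sf.season_group_summary(vals, seasons)
    assert out.season.tolist() == ["winter", "summer"]  # winter-first ordering
    w = out[out.season == "winter"].iloc[0]
    assert w["mean"] == pytest.approx(2.0)
    assert w["sem"] == pytest.approx(1.0 / np.sqrt(3.0), rel=1e-12)
    s = out[out.season == "summer"].iloc[0]
    assert s["mean"] == pytest.approx(5.0)
    assert np.isnan(s["sem"])
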