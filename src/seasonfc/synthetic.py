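"""Synthetic four-season BOLD cohorts with known injected seasonal effects.

No generative model for seasonal BOLD modulation exists to copy, so the
simulator makes its assumptions explicit and minimal: each subject's
region signals share a few band-limited (0.01–0.08 Hz) latent signals
through region loadings that are fixed across the cohort, plus white
noise. A single multiplicative seasonal gain

    g(s) = 1 + A_true · cos(2π·s/4 + φ_true),   s ∈ {0..3}

scales the latent component only, so one parameter jointly modulates
low-frequency power (hence fALFF) and inter-regional correlation — the
two families of measures the analysis is meant to recover. Environmental
series (temperature, daylength) follow a summer-peaking cosine over
season-years with small per-year deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .seasonal import SEASONS, SEASON_TO_T
from .signal import RegionTimeSeries, bandpass_white_noise

#: Latent band (Hz) of the simulated low-frequency BOLD component.
LATENT_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth settings of a simulated cohort.

    Defaults reproduce the reference cohort structure: 410 subjects split
    127/99/91/93 over winter/spring/summer/autumn across two acquisition
    years, ~60% female, 90 GM regions in 14 functional networks plus 48 WM
    bundles, 1200 volumes at TR = 0.72 s.
    """

    n_per_season: tuple[int, int, int, int] = (127, 99, 91, 93)
    n_gm_regions: int = 90
    n_wm_regions: int = 48
    n_networks: int = 14
    n_timepoints: int = 1200
    tr_seconds: float = 0.72
    n_latents: int = 3
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    amp_true: float = 0.0
    phase_true: float = 0.0
    sex_effect: float = 0.0
    p_female: float = 0.6
    start_year: int = 2013
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            *self.n_per_season, self.n_gm_regions, self.n_wm_regions,
            self.n_timepoints, self.tr_seconds, self.n_latents,
            self.loading_scale, self.noise_sd, self.amp_true,
            self.phase_true, self.sex_effect, self.p_female,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("SimulationConfig contains non-finite values")
        if len(self.n_per_season) != 4 or any(n < 0 for n in self.n_per_season):
            raise ValueError("n_per_season must be four nonnegative counts")
        if sum(self.n_per_season) == 0:
            raise ValueError("at least one season must have subjects")
        if not (0.0 <= self.amp_true < 1.0):
            raise ValueError("amp_true must lie in [0, 1) so the gain stays positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be at least 16")
        if self.n_gm_regions < 1 or self.n_wm_regions < 0:
            raise ValueError("need at least one GM region and nonnegative WM count")
        if not (1 <= self.n_networks <= max(1, self.n_gm_regions)):
            raise ValueError("n_networks must be between 1 and n_gm_regions")
        if self.n_latents < 1:
            raise ValueError("need at least one latent signal")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        data["n_per_season"] = tuple(data["n_per_season"])
        return cls(**data)


@dataclass
class SubjectRecord:
    """One subject: metadata bound to its region-averaged time series."""

    subject_id: str
    sex: str
    season: str
    year: int
    series: RegionTimeSeries

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")


@dataclass
class Cohort:
    """A list of subjects sharing one region set, with optional ground truth."""

    subjects: list[SubjectRecord]
    network_map: dict[str, str] = field(default_factory=dict)
    ground_truth: SimulationConfig | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    @property
    def region_labels(self) -> list[str]:
        return self.subjects[0].series.region_labels

    @property
    def tissue(self) -> list[str]:
        return self.subjects[0].series.tissue

    def season_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SEASONS}
        for subj in self.subjects:
            counts[subj.season] += 1
        return counts

    def measure_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "season": [s.season for s in self.subjects],
                "year": [s.year for s in self.subjects],
            }
        )


def seasonal_gain(season_index: int, amp: float, phase: float) -> float:
    """Multiplicative seasonal gain 1 + amp·cos(2π·s/4 + phase).

    Strictly positive for amp ∈ [0, 1); larger amp deepens the seasonal
    modulation around the annual mean of 1.
    """
    if not (0.0 <= amp < 1.0):
        raise ValueError("amp must lie in [0, 1) so the gain stays positive")
    if season_index not in (0, 1, 2, 3):
        raise ValueError("season_index must be one of 0, 1, 2, 3")
    return float(1.0 + amp * np.cos(2.0 * np.pi * season_index / 4.0 + phase))


def autumn_peak_phase() -> float:
    """Gain phase placing the seasonal peak in autumn (t = 3)."""
    return float(np.pi / 2.0)


def _region_metadata(config: SimulationConfig):
    gm_labels = [f"GM_{i + 1:03d}" for i in range(config.n_gm_regions)]
    wm_labels = [f"WM_{i + 1:03d}" for i in range(config.n_wm_regions)]
    labels = gm_labels + wm_labels
    tissue = ["GM"] * config.n_gm_regions + ["WM"] * config.n_wm_regions
    network_map = {
        lab: f"network_{(i % config.n_networks) + 1:02d}" for i, lab in enumerate(gm_labels)
    }
    return labels, tissue, network_map


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a four-season cohort of region-averaged BOLD signals.

    Per subject, ``n_latents`` white-noise signals are bandpass filtered to
    0.01–0.08 Hz and standardized; the region matrix is

        X = g(season) · (latents · loadingsᵀ) + noise,

    with loadings drawn once per cohort (N(0, loading_scale²)) so the
    connectivity backbone is shared across subjects, and i.i.d. N(0,
    noise_sd²) observation noise. Identical configs (including seed) yield
    byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    labels, tissue, network_map = _region_metadata(config)
    n_regions = len(labels)
    loadings = config.loading_scale * rng.standard_normal((n_regions, config.n_latents))

    season_of_subject: list[str] = []
    for season, count in zip(SEASONS, config.n_per_season):
        season_of_subject.extend([season] * count)
    n_subjects = len(season_of_subject)

    latents = bandpass_white_noise(
        rng,
        (n_subjects, config.n_latents, config.n_timepoints),
        config.tr_seconds,
        *LATENT_BAND,
    )

    subjects: list[SubjectRecord] = []
    per_season_counter: dict[str, int] = {s: 0 for s in SEASONS}
    for i, season in enumerate(season_of_subject):
        sex = "F" if rng.random() < config.p_female else "M"
        year = config.start_year + per_season_counter[season] % 2
        per_season_counter[season] += 1
        gain = seasonal_gain(SEASON_TO_T[season], config.amp_true, config.phase_true)
        shared = (loadings @ latents[i]).T  # timepoints × regions
        noise = config.noise_sd * rng.standard_normal((config.n_timepoints, n_regions))
        values = gain * shared + noise
        series = RegionTimeSeries(values, config.tr_seconds, list(labels), list(tissue))
        subjects.append(
            SubjectRecord(f"sub-{i + 1:04d}", sex, season, year, series)
        )
    return Cohort(subjects, network_map=network_map, ground_truth=config)


class EnvironmentTable:
    """Per season-year environmental covariates (temperature, daylength)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"season_index", "year", "mean_temperature", "mean_daylength"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"environment table missing column(s) {sorted(missing)}")
        if frame.duplicated(["season_index", "year"]).any():
            raise ValueError("duplicate season-year rows in environment table")
        day = frame["mean_daylength"].to_numpy(dtype=float)
        if np.any(day <= 0) or np.any(day >= 24):
            raise ValueError("daylength must lie strictly between 0 and 24 hours")
        self.frame = frame.reset_index(drop=True)
        self._index = {
            (int(r.season_index), int(r.year)): r for r in self.frame.itertuples()
        }

    def lookup(self, season_index: int, year: int):
        key = (int(season_index), int(year))
        if key not in self._index:
            raise KeyError(f"no environment row for season {season_index}, year {year}")
        return self._index[key]


def generate_environment(
    config: SimulationConfig,
    peak_season_index: int = 2,
    temperature_mean: float = 13.5,
    temperature_amplitude: float = 12.5,
    daylength_mean: float = 12.2,
    daylength_amplitude: float = 2.6,
    temperature_year_sd: float = 1.0,
    daylength_year_sd: float = 0.1,
) -> EnvironmentTable:
    """Sinusoidal season-year environmental series peaking at one season.

    Both covariates follow mean + amplitude·cos(2π(t − peak)/4); small
    seeded per-season-year deviations represent year-to-year weather
    variability and keep the two regressors from being exactly collinear.
    Defaults are plausible for a mid-latitude continental site.
    """
    if peak_season_index not in (0, 1, 2, 3):
        raise ValueError("peak_season_index must be one of 0, 1, 2, 3")
    lo = daylength_mean - daylength_amplitude - 5 * daylength_year_sd
    hi = daylength_mean + daylength_amplitude + 5 * daylength_year_sd
    if lo <= 0 or hi >= 24:
        raise ValueError("daylength parameters can produce values outside (0, 24) hours")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    years = range(config.start_year - 1, config.start_year + 2)
    rows = []
    for year in years:
        for t in range(4):
            season_term = np.cos(2.0 * np.pi * (t - peak_season_index) / 4.0)
            rows.append(
                {
                    "season_index": t,
                    "year": year,
                    "mean_temperature": temperature_mean
                    + temperature_amplitude * season_term
                    + temperature_year_sd * rng.standard_normal(),
                    "mean_daylength": daylength_mean
                    + daylength_amplitude * season_term
                    + daylength_year_sd * rng.standard_normal(),
                }
            )
    return EnvironmentTable(pd.DataFrame(rows))


def inject_sex_effect(values: np.ndarray, sexes, effect: float) -> np.ndarray:
    """Add a constant offset to male subjects' derived measures.

    Simulation-only hook used to exercise nuisance residualization; real
    cohorts never pass through it.
    """
    values = np.asarray(values, dtype=float)
    mask = np.array([s == "M" for s in sexes], dtype=float)
    return values + effect * mask
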