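"""Seeded generators for the survey-style inputs the analyses consume.

Three generators, all bit-reproducible given (seed, config):

* :func:`gen_country_table` — a European-survey-style table of national
  population, pelvic-radiograph frequency and per-exam effective dose.
  Frequencies and doses are log-normal (strictly positive, right-skewed,
  matching the order-of-magnitude spread seen in national surveys);
  populations are rescaled to the configured total exactly, and frequencies
  are rescaled so the population-weighted mean hits the configured target
  exactly.  A reference country (frequency injected verbatim) can be pinned.
* :func:`gen_dose_history` — (year, ESAK) scatter around an exponential
  decline, log-normal noise; emulates a century-long dose-history dataset.
* :func:`gen_exam_records` — per-exposure technique records for a
  radiography room (kVp, mA, ms, mAs, KAP, FID, KfiA) as truncated-normal
  draws around configured means; ESAK is computed as KfiA × bsf, never drawn.

Fields are drawn independently: the generators reproduce marginal spreads,
not the correlation structure of real technique data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import DEFAULT_BSF
from .errors import ValidationError
from .population_scenarios import CountryRecord, weighted_mean_frequency
from .trend_analysis import TrendPoint

__all__ = [
    "SurveyConfig",
    "HistoryConfig",
    "ExamRoomConfig",
    "ROOM1",
    "ROOM2",
    "gen_country_table",
    "gen_dose_history",
    "gen_exam_records",
]


@dataclass(frozen=True)
class SurveyConfig:
    """Settings for a synthetic country table.

    Defaults reproduce the European survey conditions the scenario analysis
    assumes: 35 countries, 573 million inhabitants, a population-weighted
    mean frequency of 54.3 pelvic radiographs per 1000 per year, and a
    Netherlands-like reference country pinned at 39.8 per 1000.
    """

    seed: int
    n_countries: int = 35
    total_population: float = 573e6
    target_mean_freq: float = 54.3
    freq_log_sd: float = 0.6
    e_log_mean: float = math.log(0.75)  # median per-exam E, mSv
    e_log_sd: float = 0.5
    population_log_sd: float = 1.2
    reference_country: tuple[str, float] | None = ("Netherlands-like", 39.8)

    def __post_init__(self):
        if self.n_countries < 1:
            raise ValidationError("must be >= 1", field="n_countries")
        if self.total_population <= 0:
            raise ValidationError("must be > 0", field="total_population")
        if self.target_mean_freq <= 0:
            raise ValidationError("must be > 0", field="target_mean_freq")
        for name in ("freq_log_sd", "e_log_sd", "population_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError("must be >= 0", field=name)


@dataclass(frozen=True)
class HistoryConfig:
    """Settings for a synthetic dose history.

    Defaults: 182 points over 1896–2018, a decline by a factor 400 across
    that span (k = ln(400)/122 per year) from 400 mGy, and log-normal
    scatter with σ = 1.0 — a spread of well over an order of magnitude at
    any given time.
    """

    seed: int
    n_points: int = 182
    year_range: tuple[float, float] = (1896.0, 2018.0)
    true_a0: float = 400.0
    true_k: float = math.log(400.0) / 122.0
    noise_log_sd: float = 1.0

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("must be >= 3", field="n_points")
        if self.true_a0 <= 0:
            raise ValidationError("must be > 0", field="true_a0")
        if self.noise_log_sd < 0:
            raise ValidationError("must be >= 0", field="noise_log_sd")
        if not self.year_range[0] < self.year_range[1]:
            raise ValidationError("year_range must be increasing", field="year_range")


@dataclass(frozen=True)
class ExamRoomConfig:
    """Mean ± sd of the technique parameters of one radiography room.

    Tuples are (mean, sd). KAP in Gy·cm², FID in cm, KfiA in mGy.
    """

    room: str
    kvp: tuple[float, float]
    ma: tuple[float, float]
    t_ms: tuple[float, float]
    mas: tuple[float, float]
    kap: tuple[float, float]
    fid: tuple[float, float]
    kfia: tuple[float, float]
    bsf: float = DEFAULT_BSF

    def __post_init__(self):
        for name in ("kvp", "ma", "t_ms", "mas", "kap", "fid", "kfia"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValidationError("sd must be >= 0", field=name)
        if self.bsf < 1:
            raise ValidationError("must be >= 1", field="bsf")


#: Technique-parameter summaries of the two optimised hospital rooms.
ROOM1 = ExamRoomConfig(
    room="room1", kvp=(81, 1), ma=(806, 15), t_ms=(20, 13), mas=(16, 10),
    kap=(0.48, 0.29), fid=(126, 11), kfia=(0.52, 0.31),
)
ROOM2 = ExamRoomConfig(
    room="room2", kvp=(85, 0), ma=(472, 2), t_ms=(49, 28), mas=(23, 13),
    kap=(0.70, 0.41), fid=(142, 7), kfia=(0.61, 0.36),
)


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, n: int):
    return median * np.exp(rng.normal(0.0, 1.0, size=n) * log_sd)


def gen_country_table(config: SurveyConfig) -> list[CountryRecord]:
    """Generate a calibrated synthetic country table.

    Populations sum to ``total_population`` exactly; frequencies are
    rescaled multiplicatively (sparing the pinned reference country) so the
    population-weighted mean equals ``target_mean_freq`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_countries

    pop = _lognormal(rng, 1.0, config.population_log_sd, n)
    pop *= config.total_population / pop.sum()

    freq = _lognormal(rng, config.target_mean_freq, config.freq_log_sd, n)
    e_dose = _lognormal(rng, math.exp(config.e_log_mean), config.e_log_sd, n)

    names = [f"country{i:02d}" for i in range(1, n + 1)]
    ref_idx: int | None = None
    if config.reference_country is not None:
        ref_name, ref_freq = config.reference_country
        ref_idx = 0
        names[0] = ref_name
        freq[0] = ref_freq

    # calibrate the population-weighted mean frequency exactly
    target_total = config.target_mean_freq * pop.sum() / 1000.0  # total exams
    if ref_idx is None:
        freq *= config.target_mean_freq / (float(pop @ freq) / pop.sum())
    else:
        fixed = pop[ref_idx] * freq[ref_idx] / 1000.0
        others = np.arange(n) != ref_idx
        free = float(pop[others] @ freq[others]) / 1000.0
        if free <= 0 or target_total - fixed <= 0:
            raise ValidationError(
                "cannot calibrate weighted mean frequency: the reference "
                "country alone meets or exceeds the target (add countries or "
                "adjust the target)"
            )
        freq[others] *= (target_total - fixed) / free

    return [
        CountryRecord(
            name=names[i],
            population=float(pop[i]),
            freq_per_1000=float(freq[i]),
            e_per_exam=float(e_dose[i]),
        )
        for i in range(n)
    ]


def gen_dose_history(config: HistoryConfig) -> list[TrendPoint]:
    """Generate (year, ESAK) points scattered around an exponential decline."""
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    years = rng.uniform(y0, y1, size=config.n_points)
    mean = config.true_a0 * np.exp(-config.true_k * (years - y0))
    esak = mean * np.exp(rng.normal(0.0, 1.0, size=config.n_points) * config.noise_log_sd)
    return [TrendPoint(year=float(y), esak=float(d)) for y, d in zip(years, esak)]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int):
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd  # truncate at zero: doses and settings are positive
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_exam_records(
    seed: int, n: int, room: ExamRoomConfig = ROOM1
) -> pd.DataFrame:
    """Generate per-exposure technique records for one room.

    All quantities are independent truncated-normal draws around the room
    means; ESAK is derived as KfiA × bsf, not drawn.
    """
    if n < 1:
        raise ValidationError("must be >= 1", field="n")
    rng = np.random.default_rng(seed)
    cols = {
        "room": np.repeat(room.room, n),
        "kvp": _truncated_normal(rng, *room.kvp, n),
        "ma_tube_current": _truncated_normal(rng, *room.ma, n),
        "t_exposure_ms": _truncated_normal(rng, *room.t_ms, n),
        "tube_load_mAs": _truncated_normal(rng, *room.mas, n),
        "kap_Gycm2": _truncated_normal(rng, *room.kap, n),
        "fid_cm": _truncated_normal(rng, *room.fid, n),
        "kfia_mGy": _truncated_normal(rng, *room.kfia, n),
    }
    df = pd.DataFrame(cols)
    df["esak_mGy"] = df["kfia_mGy"] * room.bsf
    return df
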