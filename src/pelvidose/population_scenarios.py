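"""Collective effective dose of AP pelvic radiography across countries.

A country contributes

    population × (frequency per 1000 / 1000) × effective dose per radiograph

to the collective dose (man-Sv).  Optimisation scenarios replace the
per-exam effective dose with a uniform level (a diagnostic reference level
or an optimised-hospital value), or harmonise the examination frequency to
that of a reference country, and report each scenario as a percentage of
the unmodified baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import ValidationError
from .risk_model import round_half_up

__all__ = [
    "CountryRecord",
    "ScenarioSpec",
    "collective_dose",
    "apply_scenario",
    "weighted_mean_frequency",
    "scenario_report",
]


@dataclass(frozen=True)
class CountryRecord:
    """One national survey row.

    population : persons.
    freq_per_1000 : annual pelvic radiographs per 1000 population.
    e_per_exam : effective dose per radiograph, mSv.
    """

    name: str
    population: float
    freq_per_1000: float
    e_per_exam: float

    def __post_init__(self):
        if self.population <= 0:
            raise ValidationError("must be > 0", field="population")
        if self.freq_per_1000 < 0:
            raise ValidationError("must be >= 0", field="freq_per_1000")
        if self.e_per_exam < 0:
            raise ValidationError("must be >= 0", field="e_per_exam")

    @property
    def annual_exams(self) -> float:
        return self.population * self.freq_per_1000 / 1000.0


@dataclass(frozen=True)
class ScenarioSpec:
    """An optimisation scenario.

    e_override : uniform per-exam effective dose applied to every country,
        mSv (None keeps national values).
    freq_override : uniform frequency per 1000 (None keeps national values).
    freq_reference_country : name of a country whose frequency is applied
        to all (mutually exclusive with ``freq_override``).
    """

    id: int | str
    label: str = ""
    e_override: float | None = None
    freq_override: float | None = None
    freq_reference_country: str | None = None

    def __post_init__(self):
        if self.freq_override is not None and self.freq_reference_country is not None:
            raise ValidationError(
                "freq_override and freq_reference_country are mutually exclusive"
            )
        for name in ("e_override", "freq_override"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError("must be >= 0", field=name)

    @property
    def is_baseline(self) -> bool:
        return (
            self.e_override is None
            and self.freq_override is None
            and self.freq_reference_country is None
        )


def _check_nonempty(countries: list[CountryRecord]) -> None:
    if not countries:
        raise ValidationError("country list is empty")


def collective_dose(countries: list[CountryRecord]) -> float:
    """Collective effective dose in man-Sv (the e_per_exam mSv → Sv factor
    is 1e-3)."""
    _check_nonempty(countries)
    return sum(c.annual_exams * c.e_per_exam * 1e-3 for c in countries)


def total_radiographs(countries: list[CountryRecord]) -> float:
    """Total annual number of radiographs across the table."""
    _check_nonempty(countries)
    return sum(c.annual_exams for c in countries)


def weighted_mean_frequency(countries: list[CountryRecord]) -> float:
    """Population-weighted mean examination frequency, per 1000 persons."""
    _check_nonempty(countries)
    pop = sum(c.population for c in countries)
    return 1000.0 * total_radiographs(countries) / pop


def apply_scenario(
    countries: list[CountryRecord], spec: ScenarioSpec
) -> list[CountryRecord]:
    """Return a copy of the table with the scenario's overrides applied."""
    _check_nonempty(countries)
    freq = spec.freq_override
    if spec.freq_reference_country is not None:
        ref = [c for c in countries if c.name == spec.freq_reference_country]
        if not ref:
            raise ValidationError(
                f"reference country {spec.freq_reference_country!r} not in table"
            )
        freq = ref[0].freq_per_1000
    out = []
    for c in countries:
        changes = {}
        if spec.e_override is not None:
            changes["e_per_exam"] = spec.e_override
        if freq is not None:
            changes["freq_per_1000"] = freq
        out.append(replace(c, **changes) if changes else c)
    return out


def scenario_report(
    countries: list[CountryRecord],
    specs: list[ScenarioSpec],
    decimals: int = 1,
) -> list[dict]:
    """Collective dose per scenario, as kman-Sv plus percentage of baseline.

    The baseline is the first spec without overrides; without one the
    percentage column is omitted with a warning.  kman-Sv values are
    half-up rounded to ``decimals``; the baseline percentage is reported
    as the exact 100.0.
    """
    _check_nonempty(countries)
    baseline = next((s for s in specs if s.is_baseline), None)
    if baseline is None:
        warnings.warn("no baseline scenario; percentages omitted", stacklevel=2)
    doses = {s.id: collective_dose(apply_scenario(countries, s)) for s in specs}
    base = doses[baseline.id] if baseline is not None else None
    rows = []
    for s in specs:
        row = {
            "scenario": s.id,
            "label": s.label or str(s.id),
            "collective_dose_kman_sv": round_half_up(doses[s.id] / 1000.0, decimals),
        }
        if base is not None:
            row["percent_of_baseline"] = 100.0 * doses[s.id] / base
        rows.append(row)
    return rows
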