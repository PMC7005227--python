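"""CSV / config I/O shared by the CLI and the analysis drivers.

One CSV dialect throughout: comma separator, dot decimal, UTF-8, header
required, units encoded in the column names (``…_mGy``, ``…_mSv``,
``…_Gycm2``) so files are self-describing.  An empty cell means "absent",
never zero.

Schemas
-------
doses     : label,esak_mGy,kap_Gycm2,kfia_mGy,e_mSv,h_testes_mGy,h_ovaries_mGy
countries : name,population,freq_per_1000,e_mSv
trend     : year,esak_mGy
exams     : room,kvp,ma_tube_current,t_exposure_ms,tube_load_mAs,kap_Gycm2,
            fid_cm,kfia_mGy,esak_mGy
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .dosimetry import DEFAULT_BSF, DoseVector
from .errors import ValidationError
from .population_scenarios import CountryRecord, ScenarioSpec
from .risk_model import RiskCoefficients, RiskResult, ShieldingModel
from .trend_analysis import TrendPoint

__all__ = [
    "SCHEMAS",
    "load_table",
    "write_report",
    "load_scenario_specs",
    "RunConfig",
    "packaged_fixture",
]

SCHEMAS: dict[str, list[str]] = {
    "doses": [
        "label", "esak_mGy", "kap_Gycm2", "kfia_mGy",
        "e_mSv", "h_testes_mGy", "h_ovaries_mGy",
    ],
    "countries": ["name", "population", "freq_per_1000", "e_mSv"],
    "trend": ["year", "esak_mGy"],
    "exams": [
        "room", "kvp", "ma_tube_current", "t_exposure_ms", "tube_load_mAs",
        "kap_Gycm2", "fid_cm", "kfia_mGy", "esak_mGy",
    ],
}

_DOSE_COLS = {
    "esak_mGy": "esak", "kap_Gycm2": "kap", "kfia_mGy": "kfia",
    "e_mSv": "e_dose", "h_testes_mGy": "h_testes", "h_ovaries_mGy": "h_ovaries",
}

RISK_COLUMNS = [
    "label",
    "male_unshielded", "female_unshielded",
    "male_shielded", "female_shielded",
    "male_reduction", "female_reduction",
]


def packaged_fixture(name: str) -> Path:
    """Path of a data file shipped with the package (e.g. table3_doses.csv)."""
    return Path(resources.files("pelvidose.data").joinpath(name))


def _cell(row: dict, col: str, lineno: int) -> float | None:
    raw = (row.get(col) or "").strip()
    if raw == "":
        return None
    try:
        v = float(raw)
    except ValueError:
        raise ValidationError(
            f"line {lineno}, column {col!r}: non-numeric cell {raw!r}"
        ) from None
    if not math.isfinite(v):
        raise ValidationError(f"line {lineno}, column {col!r}: non-finite value")
    return v


def load_table(path: str | Path, schema: str, strict: bool = True):
    """Read a CSV into validated records.

    Returns a list of records (``doses`` → DoseVector, ``countries`` →
    CountryRecord, ``trend`` → TrendPoint, ``exams`` → list of dicts).
    With ``strict=False`` returns ``(records, errors)`` where malformed rows
    are collected as messages (with line numbers) instead of raised.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    expected = SCHEMAS[schema]
    records: list[Any] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [c for c in header if c not in expected]
        missing = [c for c in expected if c not in header]
        if unknown or missing:
            raise ValidationError(
                f"{path}: header mismatch for schema {schema!r}"
                + (f"; unknown columns {unknown}" if unknown else "")
                + (f"; missing columns {missing}" if missing else "")
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(schema, row, lineno))
            except ValidationError as exc:
                if strict:
                    raise ValidationError(f"{path}: {exc}") from None
                errors.append(str(exc))
    if strict:
        return records
    return records, errors


def _parse_row(schema: str, row: dict, lineno: int):
    if schema == "doses":
        kwargs = {attr: _cell(row, col, lineno) for col, attr in _DOSE_COLS.items()}
        try:
            return DoseVector(label=(row.get("label") or "").strip(), **kwargs)
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    if schema == "countries":
        vals = {c: _cell(row, c, lineno) for c in SCHEMAS[schema][1:]}
        absent = [c for c, v in vals.items() if v is None]
        if absent:
            raise ValidationError(f"line {lineno}: empty required cells {absent}")
        try:
            return CountryRecord(
                name=(row.get("name") or "").strip(),
                population=vals["population"],
                freq_per_1000=vals["freq_per_1000"],
                e_per_exam=vals["e_mSv"],
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    if schema == "trend":
        year, esak = _cell(row, "year", lineno), _cell(row, "esak_mGy", lineno)
        if year is None or esak is None:
            raise ValidationError(f"line {lineno}: year and esak_mGy are required")
        try:
            return TrendPoint(year=year, esak=esak)
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    # exams: keep as plain dict rows (room label + numeric fields)
    rec = {"room": (row.get("room") or "").strip()}
    for col in SCHEMAS["exams"][1:]:
        v = _cell(row, col, lineno)
        if v is not None and v < 0:
            raise ValidationError(f"line {lineno}, column {col!r}: negative value")
        rec[col] = v
    return rec


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def write_report(records: list, path: str | Path, schema: str | None = None) -> None:
    """Write records back to CSV; round-trips with :func:`load_table`.

    ``schema`` is inferred from the record type when omitted.  Risk-result
    pairs (as produced by ``build_risk_table``) are written as a
    seven-column per-million risk table.
    """
    path = Path(path)
    if records and isinstance(records[0], tuple) and isinstance(records[0][0], RiskResult):
        _write_risk_table(records, path)
        return
    if schema is None:
        if not records:
            raise ValidationError("cannot infer schema for an empty record list")
        first = records[0]
        schema = (
            "doses" if isinstance(first, DoseVector)
            else "countries" if isinstance(first, CountryRecord)
            else "trend" if isinstance(first, TrendPoint)
            else "exams"
        )
    cols = SCHEMAS[schema]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for rec in records:
            if isinstance(rec, DoseVector):
                row = [rec.label] + [
                    _fmt(getattr(rec, attr)) for attr in _DOSE_COLS.values()
                ]
            elif isinstance(rec, CountryRecord):
                row = [rec.name, _fmt(rec.population), _fmt(rec.freq_per_1000),
                       _fmt(rec.e_per_exam)]
            elif isinstance(rec, TrendPoint):
                row = [_fmt(rec.year), _fmt(rec.esak)]
            else:  # exams dict
                row = [rec.get("room", "")] + [_fmt(rec.get(c)) for c in cols[1:]]
            w.writerow(row)


def _write_risk_table(
    pairs: list[tuple[RiskResult, RiskResult]],
    path: Path,
    per_million: bool = True,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RISK_COLUMNS)
        scale = 1e6 if per_million else 1.0
        for male, female in pairs:
            w.writerow([
                male.label,
                _fmt(scale * male.risk_unshielded), _fmt(scale * female.risk_unshielded),
                _fmt(scale * male.risk_shielded), _fmt(scale * female.risk_shielded),
                _fmt(scale * male.reduction), _fmt(scale * female.reduction),
            ])


def load_scenario_specs(path: str | Path) -> list[ScenarioSpec]:
    """Read scenario definitions from a YAML config.

    Expected layout: a top-level ``scenarios`` list of mappings with keys
    ``id``, ``label``, ``e_override_mSv``, ``freq_override_per_1000``,
    ``freq_reference_country`` (all but ``id`` optional).
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ValidationError(f"{path}: expected a top-level 'scenarios' list")
    specs = []
    for item in doc["scenarios"]:
        if "id" not in item:
            raise ValidationError(f"{path}: scenario without an 'id'")
        specs.append(ScenarioSpec(
            id=item["id"],
            label=str(item.get("label", "")),
            e_override=item.get("e_override_mSv"),
            freq_override=item.get("freq_override_per_1000"),
            freq_reference_country=item.get("freq_reference_country"),
        ))
    return specs


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings: coefficients, shielding and backscatter factor.

    Resolution order is CLI flag > config file > default.
    """

    coefficients: RiskCoefficients = RiskCoefficients()
    shielding: ShieldingModel = ShieldingModel()
    bsf: float = DEFAULT_BSF

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        coeff_keys = {f.name for f in dc_fields(RiskCoefficients) if f.name != "scheme"}
        shield_keys = {f.name for f in dc_fields(ShieldingModel)}
        coeffs = RiskCoefficients(**{k: v for k, v in doc.items() if k in coeff_keys})
        shield = ShieldingModel(**{k: v for k, v in doc.items() if k in shield_keys})
        return cls(
            coefficients=coeffs,
            shielding=shield,
            bsf=float(doc.get("bsf", DEFAULT_BSF)),
        )
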