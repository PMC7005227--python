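"""Dose quantities of an AP pelvic radiograph and conversions between them.

The quantities follow standard patient dosimetry practice:

* **KfiA** — air kerma free-in-air at the skin-entrance position, patient
  absent (no backscatter), mGy.
* **ESAK** — entrance surface air kerma, i.e. KfiA multiplied by the
  backscatter factor of the patient, mGy.
* **KAP** — kerma–area product, KfiA times the primary-beam area,
  Gy·cm²; invariant with distance from the focus in vacuo.
* **E** — effective dose (tissue-weighted sum of organ equivalent doses),
  mSv.
* **H_testes, H_ovaries** — organ absorbed doses, mGy; numerically equal to
  equivalent dose for X-rays (radiation weighting factor 1 Sv/Gy).

All values are stored in the units above (the units of the CSV headers);
conversion to Sv happens only inside risk formulas.

Effective dose uses a hermaphrodite-phantom convention for the gonads: the
gonad equivalent dose entering E is the mean of the testes and ovaries
doses, so the gonad term of E is (w_gonads / 2) × (H_testes + H_ovaries) —
0.04 × (H_testes + H_ovaries) under the ICRP 103 weighting factor 0.08.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InconsistentDoseError, ValidationError

__all__ = [
    "WeightingScheme",
    "WEIGHTING_SCHEMES",
    "ICRP26",
    "ICRP60",
    "ICRP103",
    "DoseVector",
    "BeamGeometry",
    "DEFAULT_BSF",
    "esak_from_kfia",
    "kfia_from_esak",
    "kfia_from_kap",
    "kap_from_kfia",
    "rescale_inverse_square",
    "gonad_contribution_to_e",
    "nongonad_effective_dose",
    "dose_ratio_report",
]

#: Backscatter factor for the beam quality of a modern AP pelvic radiograph.
DEFAULT_BSF = 1.49


@dataclass(frozen=True)
class WeightingScheme:
    """A tissue-weighting convention: the gonad weighting factor w_T."""

    name: str
    w_gonads: float

    def __post_init__(self):
        if not 0.0 < self.w_gonads <= 0.3:
            raise ValidationError("w_gonads must lie in (0, 0.3]", field="w_gonads")


ICRP26 = WeightingScheme("ICRP26", 0.25)
ICRP60 = WeightingScheme("ICRP60", 0.20)
ICRP103 = WeightingScheme("ICRP103", 0.08)

#: Registry of the three ICRP gonad weighting factors (1977, 1990, 2007).
WEIGHTING_SCHEMES: dict[str, WeightingScheme] = {
    s.name: s for s in (ICRP26, ICRP60, ICRP103)
}

# Gonad-to-effective-dose ratio bands (dimensionless, organ mGy per E mSv).
# The nominal physical bands are 8-14 (testes) and 1-2.5 (ovaries); the
# bounds below are widened to absorb rounding of printed table values.
TESTES_E_RATIO_BAND = (7.5, 14.5)
OVARIES_E_RATIO_BAND = (0.9, 2.6)

_DOSE_FIELDS = ("esak", "kap", "kfia", "e_dose", "h_testes", "h_ovaries")


@dataclass
class DoseVector:
    """Mean dose quantities of one examination epoch or source.

    Any dose field may be ``None`` (absent); absent is never coded as zero.

    Parameters
    ----------
    label
        Epoch or data source, e.g. ``"1958 Janker, Lincoln"``.
    esak, kfia, h_testes, h_ovaries
        mGy.
    kap
        Gy·cm².
    e_dose
        Effective dose, mSv.
    """

    label: str = ""
    esak: float | None = None
    kap: float | None = None
    kfia: float | None = None
    e_dose: float | None = None
    h_testes: float | None = None
    h_ovaries: float | None = None

    def __post_init__(self):
        for name in _DOSE_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"dose value must be finite and >= 0, got {v!r}", field=name
                )
            setattr(self, name, v)

    def present(self) -> dict[str, float]:
        """The populated dose fields, as a name -> value mapping."""
        return {
            n: getattr(self, n) for n in _DOSE_FIELDS if getattr(self, n) is not None
        }

    def require(self, *names: str) -> None:
        """Raise listing any of ``names`` that are absent."""
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValidationError(
                f"dose vector {self.label!r} is missing required fields: "
                + ", ".join(missing)
            )

    def gonad_ratios(self) -> tuple[float, float]:
        """(H_testes / E, H_ovaries / E); requires all three fields."""
        self.require("e_dose", "h_testes", "h_ovaries")
        if self.e_dose == 0:
            raise ValidationError("effective dose is zero", field="e_dose")
        return self.h_testes / self.e_dose, self.h_ovaries / self.e_dose

    def check_consistency(self, bsf: float | None = None) -> None:
        """Verify internal relations between populated fields.

        * ESAK = KfiA × bsf within one unit of the last shared digit, when
          all three are known;
        * the gonad/effective-dose ratios lie in the physical bands, when
          effective and organ doses are known.
        """
        if bsf is not None and self.esak is not None and self.kfia is not None:
            expected = self.kfia * bsf
            # tolerance: one unit in the last digit of the smaller value
            tol = 10.0 ** math.floor(math.log10(max(expected, 1e-12))) * 0.01
            if abs(self.esak - expected) > max(tol, 0.01 * expected):
                raise InconsistentDoseError(
                    f"{self.label!r}: esak={self.esak} inconsistent with "
                    f"kfia*bsf={expected:.4g}"
                )
        if all(getattr(self, n) is not None for n in ("e_dose", "h_testes", "h_ovaries")):
            rt, ro = self.gonad_ratios()
            lo, hi = TESTES_E_RATIO_BAND
            if not lo <= rt <= hi:
                raise InconsistentDoseError(
                    f"{self.label!r}: testes/E ratio {rt:.3g} outside [{lo}, {hi}]"
                )
            lo, hi = OVARIES_E_RATIO_BAND
            if not lo <= ro <= hi:
                raise InconsistentDoseError(
                    f"{self.label!r}: ovaries/E ratio {ro:.3g} outside [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class BeamGeometry:
    """Geometry of the primary beam.

    fid : focus-to-image-receptor distance, cm.
    skin_to_receptor : distance from the skin entrance plane to the
        receptor, cm (25 cm is a typical AP pelvis assumption).
    field_area : beam area at a stated reference plane, cm².
    bsf : backscatter factor, >= 1.
    """

    fid: float
    skin_to_receptor: float = 25.0
    field_area: float | None = None
    bsf: float = DEFAULT_BSF

    def __post_init__(self):
        if self.skin_to_receptor < 0:
            raise ValidationError("must be >= 0", field="skin_to_receptor")
        if self.fid <= self.skin_to_receptor:
            raise ValidationError(
                "fid must exceed skin_to_receptor", field="fid"
            )
        if self.field_area is not None and self.field_area <= 0:
            raise ValidationError("must be > 0", field="field_area")
        if self.bsf < 1:
            raise ValidationError("backscatter factor must be >= 1", field="bsf")

    @property
    def focus_to_skin(self) -> float:
        """Distance from focus to the skin entrance plane, cm."""
        return self.fid - self.skin_to_receptor


def esak_from_kfia(kfia: float, bsf: float = DEFAULT_BSF) -> float:
    """Entrance surface air kerma from free-in-air kerma: ESAK = KfiA × bsf."""
    if kfia < 0:
        raise ValidationError("must be >= 0", field="kfia")
    if bsf < 1:
        raise ValidationError("backscatter factor must be >= 1", field="bsf")
    return kfia * bsf


def kfia_from_esak(esak: float, bsf: float = DEFAULT_BSF) -> float:
    """Exact inverse of :func:`esak_from_kfia`."""
    if esak < 0:
        raise ValidationError("must be >= 0", field="esak")
    if bsf < 1:
        raise ValidationError("backscatter factor must be >= 1", field="bsf")
    return esak / bsf


def kfia_from_kap(kap: float, field_area: float) -> float:
    """KfiA (mGy) from the kerma-area product (Gy·cm²) and beam area (cm²).

    KAP = KfiA × area, so KfiA = KAP / area; the factor 1000 converts the
    Gy of KAP into the mGy in which point kerma is quoted.
    """
    if kap < 0:
        raise ValidationError("must be >= 0", field="kap")
    if field_area <= 0:
        raise ValidationError("must be > 0", field="field_area")
    return kap / field_area * 1000.0


def kap_from_kfia(kfia: float, field_area: float) -> float:
    """Exact inverse of :func:`kfia_from_kap` (returns Gy·cm²)."""
    if kfia < 0:
        raise ValidationError("must be >= 0", field="kfia")
    if field_area <= 0:
        raise ValidationError("must be > 0", field="field_area")
    return kfia * field_area / 1000.0


def rescale_inverse_square(kfia: float, d_from: float, d_to: float) -> float:
    """Move a free-in-air kerma between reference planes of a point source.

    Returns ``kfia × (d_from / d_to)²`` where the distances are measured
    from the focus.
    """
    if d_from <= 0:
        raise ValidationError("must be > 0", field="d_from")
    if d_to <= 0:
        raise ValidationError("must be > 0", field="d_to")
    return kfia * (d_from / d_to) ** 2


def gonad_contribution_to_e(
    h_testes: float, h_ovaries: float, scheme: WeightingScheme = ICRP103
) -> float:
    """Gonad term of the effective dose, mSv.

    Hermaphrodite-phantom convention: gonad equivalent dose is the mean of
    the testes and ovaries doses, so the term is
    (w_gonads / 2) × (H_testes + H_ovaries) — 0.04 × (sum) under ICRP 103.
    """
    if h_testes < 0:
        raise ValidationError("must be >= 0", field="h_testes")
    if h_ovaries < 0:
        raise ValidationError("must be >= 0", field="h_ovaries")
    return (scheme.w_gonads / 2.0) * (h_testes + h_ovaries)


def nongonad_effective_dose(
    e_dose: float,
    h_testes: float,
    h_ovaries: float,
    scheme: WeightingScheme = ICRP103,
) -> float:
    """Effective dose minus its gonad term, mSv.

    Adding :func:`gonad_contribution_to_e` back recovers ``e_dose`` exactly.
    """
    gonad = gonad_contribution_to_e(h_testes, h_ovaries, scheme)
    rest = e_dose - gonad
    if rest < 0:
        raise InconsistentDoseError(
            f"inconsistent dose vector: gonad contribution {gonad:.4g} mSv "
            f"exceeds total effective dose {e_dose:.4g} mSv"
        )
    return rest


def dose_ratio_report(
    numerator: DoseVector, denominator: DoseVector
) -> dict[str, float]:
    """Field-wise percentage ratio of two dose vectors, 100 × num / den.

    Only fields populated in both vectors appear in the output. A zero
    denominator field is flagged (NaN plus a warning), never dropped.
    """
    num, den = numerator.present(), denominator.present()
    common = [n for n in _DOSE_FIELDS if n in num and n in den]
    if not common:
        raise ValidationError("dose vectors share no populated fields")
    out: dict[str, float] = {}
    for name in common:
        if den[name] == 0:
            warnings.warn(
                f"zero denominator in field {name!r}; ratio undefined",
                stacklevel=2,
            )
            out[name] = math.nan
        else:
            out[name] = 100.0 * num[name] / den[name]
    return out
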