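"""Beer–Lambert forward optics and the ratio-of-ratios oximetry inversion.

Transmission oximetry rests on three relations:

* Beer–Lambert absorbance ``A = ln(Ii/It) = a·C·L`` for a single absorber,
  additive over the species of a mixture.
* Dynamic transmission through pulsating blood,
  ``I(λ,t) = I0(λ)·exp(−(s·β_oxy(λ) + (1−s)·β_deoxy(λ))·l(t))``,
  where ``s`` is the oxygen saturation of that blood compartment and
  ``l(t)`` the pulsating optical path.
* The ratio of ratios
  ``R = ln(I_red(t1)/I_red(t2)) / ln(I_ir(t1)/I_ir(t2))``,
  which for the model above equals the ratio of effective extinction
  coefficients ``μ_red(s)/μ_ir(s)`` independently of the path excursion, and
  is therefore invertible to ``s``.

Saturation convention: ``s`` multiplies the *oxyhemoglobin* coefficient, so
``s = 1`` is fully oxygenated blood.  The inversion used is

    s = (R·ε_Hb(IR) − ε_Hb(R)) / [(ε_HbO2(R) − ε_Hb(R)) − R·(ε_HbO2(IR) − ε_Hb(IR))]

which round-trips exactly with the forward model on noiseless two-time-point
data.  Units: coefficients in reciprocal (concentration·length); any
consistent unit system works because only products of coefficient,
concentration and path enter the results.  Natural logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateSignalError,
    InvalidInputError,
    NonInvertibleError,
)

RED = "red"
IR = "ir"
#: Wavelengths (nm) conventionally used for the two channels.
WAVELENGTH_NM = {RED: 660, IR: 940}


@dataclass(frozen=True)
class OpticalCoefficients:
    """Absorption coefficients of Hb and HbO2 at the red and infrared wavelengths.

    The two ordering invariants (Hb absorbs more red light than HbO2; HbO2
    absorbs more infrared than Hb) give the ratio-of-ratios curve R(s) a
    strictly negative slope, which is what makes the inversion well posed.
    """

    eps_hb_red: float
    eps_hbo2_red: float
    eps_hb_ir: float
    eps_hbo2_ir: float

    def __post_init__(self) -> None:
        vals = (self.eps_hb_red, self.eps_hbo2_red, self.eps_hb_ir, self.eps_hbo2_ir)
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise InvalidInputError("all four absorption coefficients must be finite and > 0")
        if not self.eps_hb_red > self.eps_hbo2_red:
            raise InvalidInputError("require eps_hb_red > eps_hbo2_red (Hb absorbs more red)")
        if not self.eps_hbo2_ir > self.eps_hb_ir:
            raise InvalidInputError("require eps_hbo2_ir > eps_hb_ir (HbO2 absorbs more infrared)")

    def effective(self, saturation: float, wavelength: str):
        """Effective extinction μ(λ, s) = s·ε_HbO2(λ) + (1−s)·ε_Hb(λ).

        ``saturation`` may be a scalar or an array.
        """
        if wavelength == RED:
            oxy, deoxy = self.eps_hbo2_red, self.eps_hb_red
        elif wavelength == IR:
            oxy, deoxy = self.eps_hbo2_ir, self.eps_hb_ir
        else:
            raise InvalidInputError(f"wavelength must be 'red' or 'ir', got {wavelength!r}")
        s = np.asarray(saturation, dtype=float)
        mu = s * oxy + (1.0 - s) * deoxy
        return float(mu) if mu.ndim == 0 else mu

    def to_dict(self) -> dict:
        return {
            "eps_hb_red": self.eps_hb_red,
            "eps_hbo2_red": self.eps_hbo2_red,
            "eps_hb_ir": self.eps_hb_ir,
            "eps_hbo2_ir": self.eps_hbo2_ir,
        }

    @classmethod
    def from_config(cls, blocks: Iterable[Mapping]) -> "OpticalCoefficients":
        """Build from config blocks with keys ``wavelength``, ``eps_hb``, ``eps_hbo2``.

        ``wavelength`` may be 660/940 (nm) or the strings "red"/"ir".
        """
        by_channel: dict[str, Mapping] = {}
        for block in blocks:
            wl = block["wavelength"]
            if wl in (660, "660", RED):
                by_channel[RED] = block
            elif wl in (940, "940", IR):
                by_channel[IR] = block
            else:
                raise InvalidInputError(f"unrecognized wavelength {wl!r} (expect 660/940 or red/ir)")
        missing = {RED, IR} - set(by_channel)
        if missing:
            raise InvalidInputError(f"coefficient config missing channel(s): {sorted(missing)}")
        return cls(
            eps_hb_red=float(by_channel[RED]["eps_hb"]),
            eps_hbo2_red=float(by_channel[RED]["eps_hbo2"]),
            eps_hb_ir=float(by_channel[IR]["eps_hb"]),
            eps_hbo2_ir=float(by_channel[IR]["eps_hbo2"]),
        )


#: Commonly tabulated molar extinction coefficients of Hb/HbO2 at 660 and
#: 940 nm, in mM^-1 cm^-1.  Overridable through any config that carries an
#: OpticalCoefficients block.
DEFAULT_COEFFICIENTS = OpticalCoefficients(
    eps_hb_red=3.2266,
    eps_hbo2_red=0.3196,
    eps_hb_ir=0.6934,
    eps_hbo2_ir=1.2140,
)


@dataclass(frozen=True)
class AbsorbingSpecies:
    """One absorber of a mixture: absorption coefficient and concentration."""

    coefficient: float
    concentration: float

    def __post_init__(self) -> None:
        if self.coefficient < 0 or self.concentration < 0:
            raise InvalidInputError("coefficient and concentration must be >= 0")


@dataclass(frozen=True)
class Saturation:
    """An oxygen saturation as a fraction in [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise InvalidInputError(f"saturation must lie in [0, 1], got {self.value}")

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def _sat_value(s) -> float:
    return s.value if isinstance(s, Saturation) else float(s)


def absorbance_single(coefficient: float, concentration: float, path: float) -> float:
    """Absorbance a·C·L of a single solution; equals ln(Ii/It)."""
    if coefficient < 0 or concentration < 0 or path < 0:
        raise InvalidInputError("absorbance arguments must be >= 0")
    return coefficient * concentration * path


def absorbance_mixture(species: Sequence[AbsorbingSpecies], path: float) -> float:
    """Superposed absorbance Σ a_k·C_k·L of a mixture; empty mixture absorbs nothing."""
    if path < 0:
        raise InvalidInputError("path must be >= 0")
    return sum(sp.coefficient * sp.concentration * path for sp in species)


def transmitted_intensity(
    incident: float,
    saturation,
    coefs: OpticalCoefficients,
    wavelength: str,
    path: float,
) -> float:
    """Transmitted intensity of blood at saturation ``s`` over optical path ``path``.

    ``incident · exp(−(s·ε_HbO2(λ) + (1−s)·ε_Hb(λ))·path)``; equals the
    incident intensity at zero path and decreases strictly with path.
    """
    if incident <= 0:
        raise InvalidInputError("incident intensity must be > 0")
    if path < 0:
        raise InvalidInputError("path must be >= 0")
    s = _sat_value(saturation)
    mu = coefs.effective(s, wavelength)
    return incident * math.exp(-mu * path)


def ratio_of_ratios(
    i_red_t1: float, i_red_t2: float, i_ir_t1: float, i_ir_t2: float
) -> float:
    """Ratio of ratios R = ln(I_red(t1)/I_red(t2)) / ln(I_ir(t1)/I_ir(t2)).

    The small-modulation AC/DC form (ΔI/I)_red / (ΔI/I)_ir (see
    :func:`ratio_of_ratios_acdc`) agrees with this log form to second order in
    the modulation depth, because ln(1+x) ≈ x for small x.
    """
    for v in (i_red_t1, i_red_t2, i_ir_t1, i_ir_t2):
        if not (v > 0 and math.isfinite(v)):
            raise InvalidInputError("intensities must be finite and > 0")
    if i_ir_t1 == i_ir_t2:
        raise DegenerateSignalError("no infrared intensity change: R is undefined")
    return math.log(i_red_t1 / i_red_t2) / math.log(i_ir_t1 / i_ir_t2)


def ratio_of_ratios_acdc(ac_red: float, dc_red: float, ac_ir: float, dc_ir: float) -> float:
    """Small-signal form R ≈ (AC/DC)_red / (AC/DC)_ir."""
    if dc_red <= 0 or dc_ir <= 0:
        raise InvalidInputError("DC values must be > 0")
    if ac_ir == 0:
        raise DegenerateSignalError("no infrared AC component: R is undefined")
    return (ac_red / dc_red) / (ac_ir / dc_ir)


class SaturationEstimate(NamedTuple):
    """Inverted saturation: clipped value, raw (unclipped) value, and range flag."""

    value: float
    raw: float
    in_range: bool


def _invert_r(r, coefs: OpticalCoefficients):
    """Vectorized raw inversion s(R); returns NaN where the denominator vanishes."""
    r = np.asarray(r, dtype=float)
    num = r * coefs.eps_hb_ir - coefs.eps_hb_red
    den = (coefs.eps_hbo2_red - coefs.eps_hb_red) - r * (coefs.eps_hbo2_ir - coefs.eps_hb_ir)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
    return s if s.ndim else float(s)


def saturation_from_r(
    r: float, coefs: OpticalCoefficients, *, slack: float = 0.05
) -> SaturationEstimate:
    """Invert the ratio-of-ratios to a saturation.

    Returns the value clipped to [0, 1] together with the raw inversion and an
    ``in_range`` flag which is False when the raw value falls outside [0, 1]
    by more than ``slack``.  Raises :class:`NonInvertibleError` when the
    inversion denominator vanishes at this R.
    """
    if not math.isfinite(r):
        raise InvalidInputError("r must be finite")
    raw = _invert_r(r, coefs)
    if not math.isfinite(raw):
        raise NonInvertibleError(f"saturation inversion is singular at R = {r}")
    in_range = (-slack <= raw <= 1.0 + slack)
    return SaturationEstimate(value=min(max(raw, 0.0), 1.0), raw=raw, in_range=in_range)


def r_for_saturation(saturation, coefs: OpticalCoefficients) -> float:
    """Forward map R(s) = μ_red(s)/μ_ir(s) implied by the dynamic transmission model."""
    s = _sat_value(saturation)
    return coefs.effective(s, RED) / coefs.effective(s, IR)
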