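"""Spectrophotometric pigment quantification and pigment ratios.

Chlorophyll and carotenoids are extracted in 80% acetone and read at
445/645/663 nm; anthocyanins in acidified methanol read at 530/657 nm.
The exact extinction coefficients behind published trait values are rarely
printed, so the coefficient set is configuration with documented defaults:

* Arnon-style chlorophyll equations on the 645/663 nm pair
  (Chl a = 12.70*A663 - 2.69*A645, Chl b = 22.90*A645 - 4.68*A663, both
  mg/L); total chlorophyll is the row sum of the a and b equations
  (= 20.21*A645 + 8.02*A663), which keeps the a/b split and the total
  mutually consistent.
* A Lichtenthaler-style carotenoid equation adapted to the 445 nm band:
  Car = (1000*A445 - k1*Chla - k2*Chlb)/k3 with defaults k1 = 3.27,
  k2 = 104, k3 = 229 (mg/L).
* Anthocyanin as a chlorophyll-corrected absorbance difference
  dA = A530 - 0.25*A657, reported by default in relative dA-based units
  per gram fresh weight; a molar-extinction mode is available.

Contents are converted from extract concentration (mg/L) to tissue content
(mg per g fresh weight) via content = conc * volume * dilution / mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: cyanidin-3-glucoside convention for the optional molar anthocyanin mode
CYANIDIN_EXTINCTION = 29600.0  # L/(mol cm)
CYANIDIN_MW = 449.2  # g/mol


@dataclass(frozen=True)
class PigmentCoefficients:
    """Linear coefficient sets over the measured wavelengths (mg/L units).

    ``chl_a`` and ``chl_b`` are (coefficient on A645, coefficient on A663);
    the total-chlorophyll equation is their row sum.  ``car`` is
    (k1, k2, k3) in Car = (1000*A445 - k1*Chla - k2*Chlb)/k3.
    """

    chl_a: tuple[float, float] = (-2.69, 12.70)
    chl_b: tuple[float, float] = (22.90, -4.68)
    car: tuple[float, float, float] = (3.27, 104.0, 229.0)
    ant_subtraction: float = 0.25
    ant_scale: float = 1.0

    @property
    def chl_total(self) -> tuple[float, float]:
        return (self.chl_a[0] + self.chl_b[0], self.chl_a[1] + self.chl_b[1])

    def describe(self) -> dict:
        """Record of the coefficient set, for report provenance."""
        return {
            "chl_a(A645,A663)": list(self.chl_a),
            "chl_b(A645,A663)": list(self.chl_b),
            "chl_total(A645,A663)": list(self.chl_total),
            "car(k1,k2,k3)": list(self.car),
            "ant_subtraction": self.ant_subtraction,
            "ant_scale": self.ant_scale,
        }


@dataclass
class AbsorbanceSet:
    """One replicate's absorbance readings plus extraction bookkeeping.

    ``mass`` in g fresh weight, ``volume`` in litres of extract,
    ``dilution`` the fold-dilution applied before reading.  The chlorophyll
    and anthocyanin extractions may differ; anthocyanin fields carry their
    own mass/volume/dilution when supplied.
    """

    A445: float = 0.0
    A645: float = 0.0
    A663: float = 0.0
    A530: float = 0.0
    A657: float = 0.0
    mass: float = 0.2
    volume: float = 0.005
    dilution: float = 1.0
    ant_mass: float | None = None
    ant_volume: float | None = None
    ant_dilution: float | None = None

    def __post_init__(self) -> None:
        for name in ("A445", "A645", "A663", "A530", "A657"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative absorbance {name}")
        if self.mass <= 0 or self.volume <= 0 or self.dilution <= 0:
            raise ValueError("mass, volume and dilution must be positive")

    def ant_extraction(self) -> tuple[float, float, float]:
        return (
            self.ant_mass if self.ant_mass is not None else self.mass,
            self.ant_volume if self.ant_volume is not None else self.volume,
            self.ant_dilution if self.ant_dilution is not None else self.dilution,
        )


@dataclass(frozen=True)
class PigmentProfile:
    """Pigment contents per g fresh weight plus the three ratios.

    Undefined ratios (zero denominator) are NaN markers, not errors.
    """

    Chl: float
    Car: float
    Ant: float
    Ant_Chl: float = field(default=np.nan)
    Car_Chl: float = field(default=np.nan)
    Ant_Car: float = field(default=np.nan)
    ant_floored: bool = False


def _per_gram(conc_mg_per_l: float, mass: float, volume: float, dilution: float) -> float:
    return conc_mg_per_l * volume * dilution / mass


def chlorophyll_content(
    abs_set: AbsorbanceSet, coeffs: PigmentCoefficients | None = None
) -> float:
    """Total chlorophyll in mg per g fresh weight.

    Concentration (mg/L) from the configured 645/663 nm equation, then
    scaled by volume * dilution / mass.
    """
    coeffs = coeffs or PigmentCoefficients()
    c645, c663 = coeffs.chl_total
    conc = c645 * abs_set.A645 + c663 * abs_set.A663
    return _per_gram(conc, abs_set.mass, abs_set.volume, abs_set.dilution)


def chlorophyll_ab(
    abs_set: AbsorbanceSet, coeffs: PigmentCoefficients | None = None
) -> tuple[float, float]:
    """(Chl a, Chl b) extract concentrations in mg/L."""
    coeffs = coeffs or PigmentCoefficients()
    chla = coeffs.chl_a[0] * abs_set.A645 + coeffs.chl_a[1] * abs_set.A663
    chlb = coeffs.chl_b[0] * abs_set.A645 + coeffs.chl_b[1] * abs_set.A663
    return chla, chlb


def carotenoid_content(
    abs_set: AbsorbanceSet, coeffs: PigmentCoefficients | None = None
) -> float:
    """Carotenoids in mg per g fresh weight (445 nm equation)."""
    coeffs = coeffs or PigmentCoefficients()
    k1, k2, k3 = coeffs.car
    if k3 == 0:
        raise ValueError("carotenoid denominator coefficient k3 must be nonzero")
    chla, chlb = chlorophyll_ab(abs_set, coeffs)
    conc = (1000.0 * abs_set.A445 - k1 * chla - k2 * chlb) / k3
    return _per_gram(conc, abs_set.mass, abs_set.volume, abs_set.dilution)


def anthocyanin_content(
    abs_set: AbsorbanceSet,
    coeffs: PigmentCoefficients | None = None,
    molar: bool = False,
    path_length_cm: float = 1.0,
) -> tuple[float, bool]:
    """Anthocyanin content per g fresh weight.

    Default output is in relative dA-based units (dA * L * dilution / g);
    with ``molar=True`` the chlorophyll-corrected absorbance is converted to
    mg/g via the cyanidin-3-glucoside extinction convention.

    Returns
    -------
    (content, floored)
        ``floored`` flags a negative corrected absorbance clipped to 0.
    """
    coeffs = coeffs or PigmentCoefficients()
    delta = abs_set.A530 - coeffs.ant_subtraction * abs_set.A657
    floored = delta < 0
    delta = max(delta, 0.0)
    mass, volume, dilution = abs_set.ant_extraction()
    if molar:
        conc_mg_per_l = delta / (CYANIDIN_EXTINCTION * path_length_cm) * CYANIDIN_MW * 1000.0
        return _per_gram(conc_mg_per_l, mass, volume, dilution), floored
    return coeffs.ant_scale * delta * volume * dilution / mass, floored


def pigment_ratios(chl: float, car: float, ant: float) -> tuple[float, float, float]:
    """(Ant/Chl, Car/Chl, Ant/Car); NaN where the denominator is not > 0."""
    ant_chl = ant / chl if chl > 0 else np.nan
    car_chl = car / chl if chl > 0 else np.nan
    ant_car = ant / car if car > 0 else np.nan
    return ant_chl, car_chl, ant_car


def pigment_profile(
    abs_set: AbsorbanceSet, coeffs: PigmentCoefficients | None = None
) -> PigmentProfile:
    """Full pigment profile (contents plus ratios) for one absorbance set."""
    coeffs = coeffs or PigmentCoefficients()
    chl = chlorophyll_content(abs_set, coeffs)
    car = carotenoid_content(abs_set, coeffs)
    ant, floored = anthocyanin_content(abs_set, coeffs)
    ant_chl, car_chl, ant_car = pigment_ratios(chl, car, ant)
    return PigmentProfile(
        Chl=chl,
        Car=car,
        Ant=ant,
        Ant_Chl=ant_chl,
        Car_Chl=car_chl,
        Ant_Car=ant_car,
        ant_floored=floored,
    )
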