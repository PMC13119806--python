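"""Seeded generators for every raw input the pipeline consumes.

The generators emulate a 4-treatment x 4-period x 3-replicate pot-drought
experiment: a long-format trait table drawn around configured cell means,
plus the raw measurement bundles behind the derived traits — CIELAB
readings, pigment absorbance sets, petiole vessel anatomy, fresh-weight
drydown series and pressure-volume observation sequences.

Design contracts:

* every draw flows from one master seed through named substreams
  (:mod:`leafstress._rng`), so stages regenerate independently and a fixed
  seed is bit-reproducible;
* at zero noise each generator composed with its analysis counterpart is
  an identity (color aggregation, pigment inversion, ge, PV, Kmax);
* replicate noise is Gaussian with sd = SE * sqrt(n), reproducing the
  configured per-cell standard errors in expectation (n = 3 replicates).

Within-cell Gaussianity is an assumption of the emulation, not a property
of the underlying study, whose raw distributions are unpublished.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from leafstress._rng import substream
from leafstress.colorimetry import TRAIT_COLUMNS
from leafstress.config import RATIO_TRAITS, ExperimentConfig
from leafstress.hydraulics import (
    GE_CONVERSION,
    MassLossSeries,
    PVCurve,
    VesselAnatomy,
)
from leafstress.pigments import AbsorbanceSet, PigmentCoefficients

# ---------------------------------------------------------------------------
# trait table


def generate_trait_table(config: ExperimentConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one replicate-level observation per (trait, treatment, period).

    Values are ``mean + Normal(0, SE * sqrt(se_n))``.  The three
    pigment ratios (Ant/Chl, Car/Chl, Ant/Car) are computed per replicate
    from the drawn pigment values, preserving their sampling correlation,
    whenever Chl/Car/Ant are configured.
    """
    seed = config.seed if seed is None else seed
    rng = substream(seed, "trait_table")
    n = config.replicates
    rows = []
    drawn: dict[tuple[str, str, int, str], float] = {}
    for trait in config.traits:
        # SEs describe cell means over se_n replicates, so the per-replicate
        # sd is SE * sqrt(se_n) regardless of how many replicates are drawn
        sd_scale = math.sqrt(config.se_n)
        for treatment in config.treatments:
            for period in config.periods:
                mean, se = config.cell(trait, treatment, period)
                values = mean + rng.normal(0.0, se * sd_scale, size=n)
                for rep, value in enumerate(values, start=1):
                    drawn[(treatment, period, rep, trait)] = float(value)
                    rows.append(
                        (
                            treatment,
                            period,
                            rep,
                            trait,
                            float(value),
                            config.units.get(trait, ""),
                        )
                    )
    have_pigments = all(t in config.traits for t in ("Chl", "Car", "Ant"))
    if have_pigments:
        for treatment in config.treatments:
            for period in config.periods:
                for rep in range(1, n + 1):
                    chl = drawn[(treatment, period, rep, "Chl")]
                    car = drawn[(treatment, period, rep, "Car")]
                    ant = drawn[(treatment, period, rep, "Ant")]
                    ratios = {
                        "Ant_Chl": ant / chl if chl > 0 else np.nan,
                        "Car_Chl": car / chl if chl > 0 else np.nan,
                        "Ant_Car": ant / car if car > 0 else np.nan,
                    }
                    for name in RATIO_TRAITS:
                        rows.append(
                            (
                                treatment,
                                period,
                                rep,
                                name,
                                float(ratios[name]),
                                config.units.get(name, ""),
                            )
                        )
    return pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))


# ---------------------------------------------------------------------------
# color readings


def generate_color_readings(
    mean_lab: tuple[float, float, float],
    n_leaves: int = 10,
    reads_per_leaf: int = 10,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-leaf CIELAB reading sets around a replicate-level mean.

    Emulates the colorimeter protocol: ``n_leaves`` leaves, each read
    ``reads_per_leaf`` times, iid Gaussian reading noise.  L* is clipped
    into [0, 100].
    """
    if n_leaves < 1 or reads_per_leaf < 1:
        raise ValueError("need at least one leaf and one reading per leaf")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = substream(seed, "color_readings")
    L, a, b = mean_lab
    rows = []
    for leaf in range(1, n_leaves + 1):
        for read in range(1, reads_per_leaf + 1):
            rows.append(
                (
                    leaf,
                    read,
                    float(np.clip(L + rng.normal(0, noise_sd), 0.0, 100.0)),
                    float(a + rng.normal(0, noise_sd)),
                    float(b + rng.normal(0, noise_sd)),
                )
            )
    return pd.DataFrame(
        rows, columns=["leaf_id", "reading_index", "L_star", "a_star", "b_star"]
    )


# ---------------------------------------------------------------------------
# absorbance sets (pigment inverse model)


def generate_absorbance_sets(
    chl: float,
    car: float,
    ant: float,
    mass: float = 0.2,
    volume: float = 0.005,
    dilution: float = 1.0,
    ant_mass: float = 1.0,
    ant_volume: float = 0.01,
    ant_dilution: float = 5.0,
    coeffs: PigmentCoefficients | None = None,
    chl_ab_ratio: float = 3.0,
    a657_baseline: float = 0.0,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> AbsorbanceSet:
    """Invert the pigment equations: target contents -> absorbance readings.

    Targets are tissue contents (mg/g FW; anthocyanin in the configured
    relative units).  Total chlorophyll is split a:b = ``chl_ab_ratio``
    (sun-leaf convention ~3:1) and the 2x2 chlorophyll coefficient system
    is solved for A645/A663; A445 follows from the carotenoid equation and
    A530 from the anthocyanin difference on top of an optional A657
    chlorophyll-interference baseline.  ``noise_rel`` applies multiplicative
    Gaussian noise to every absorbance.  Feeding the result to the pigments
    module reproduces the targets exactly at zero noise (round-trip
    contract).
    """
    if mass <= 0 or volume <= 0 or dilution <= 0:
        raise ValueError("mass, volume and dilution must be positive")
    if min(chl, car, ant) < 0:
        raise ValueError("target contents must be non-negative")
    coeffs = coeffs or PigmentCoefficients()
    # extract concentrations, mg/L
    chl_conc = chl * mass / (volume * dilution)
    car_conc = car * mass / (volume * dilution)
    frac_a = chl_ab_ratio / (1.0 + chl_ab_ratio)
    chla, chlb = frac_a * chl_conc, (1.0 - frac_a) * chl_conc
    coeff_matrix = np.array([list(coeffs.chl_a), list(coeffs.chl_b)], dtype=float)
    if abs(np.linalg.det(coeff_matrix)) < 1e-9:
        raise ValueError("chlorophyll coefficient matrix is not invertible")
    a645, a663 = np.linalg.solve(coeff_matrix, np.array([chla, chlb]))
    k1, k2, k3 = coeffs.car
    a445 = (k3 * car_conc + k1 * chla + k2 * chlb) / 1000.0
    delta = ant * ant_mass / (ant_volume * ant_dilution * coeffs.ant_scale)
    a657 = a657_baseline
    a530 = delta + coeffs.ant_subtraction * a657

    values = np.array([a445, a645, a663, a530, a657], dtype=float)
    if (values < -1e-9).any():
        raise ValueError(
            "target pigment combination implies negative absorbance; "
            "adjust targets or coefficient set"
        )
    values = np.clip(values, 0.0, None)
    if noise_rel > 0:
        rng = substream(seed, "absorbance")
        values = values * (1.0 + rng.normal(0.0, noise_rel, size=values.size))
        values = np.clip(values, 0.0, None)
    return AbsorbanceSet(
        A445=float(values[0]),
        A645=float(values[1]),
        A663=float(values[2]),
        A530=float(values[3]),
        A657=float(values[4]),
        mass=mass,
        volume=volume,
        dilution=dilution,
        ant_mass=ant_mass,
        ant_volume=ant_volume,
        ant_dilution=ant_dilution,
    )


# ---------------------------------------------------------------------------
# vessel anatomy


def generate_vessel_anatomy(
    n_vessels: int = 60,
    radius_mean: float = 5.2,
    radius_sd: float = 0.8,
    counted_fraction: float = 0.8,
    leaf_area: float = 0.004,
    petiole_length: float = 0.02,
    water_temperature: float = 25.0,
    seed: int = 0,
) -> VesselAnatomy:
    """Petiole vessel geometry with Gaussian equivalent radii (um).

    A ``counted_fraction`` subset is sampled without replacement to mimic
    partial vessel measurement; fractions below the conventional 2/3
    sampling rule warn.  Vessel areas are pi r^2, consistent with the
    radii by construction.
    """
    if n_vessels < 1:
        raise ValueError("need at least one vessel")
    if not 0 < counted_fraction <= 1:
        raise ValueError("counted_fraction must lie in (0, 1]")
    if counted_fraction < 2.0 / 3.0:
        warnings.warn(
            "counted_fraction below the 2/3 sampling rule; Kmax may be biased",
            stacklevel=2,
        )
    rng = substream(seed, "vessel_anatomy")
    radii = rng.normal(radius_mean, radius_sd, size=n_vessels)
    radii = np.clip(radii, 0.2 * radius_mean, None)  # no degenerate vessels
    areas = math.pi * radii**2
    n_counted = max(1, int(round(counted_fraction * n_vessels)))
    counted = rng.choice(n_vessels, size=n_counted, replace=False)
    return VesselAnatomy(
        vessel_areas=areas[np.sort(counted)],
        n_total=n_vessels,
        leaf_area=leaf_area,
        petiole_length=petiole_length,
        water_temperature=water_temperature,
    )


# ---------------------------------------------------------------------------
# mass-loss (drydown) series


def generate_mass_loss_series(
    ge_true: float = 231.0,
    leaf_area: float = 0.01,
    delta_e: float = 20.0,
    stomatal_multiplier: float = 5.0,
    stomatal_duration: float = 6000.0,
    total_duration: float = 28800.0,
    interval: float = 3000.0,
    saturated_weight: float = 2.0,
    dry_weight: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MassLossSeries:
    """Two-phase piecewise-linear drydown of a detached saturated leaf.

    The epidermal (tail) slope is the exact inverse of the ge formula,
    -ge * A * de / 2.31e6 (g/s); the initial stomatal phase is steeper by
    ``stomatal_multiplier``.  Weighing every ``interval`` seconds (the
    bench protocol uses 50 min) for ``total_duration`` (8 h), with optional
    Gaussian weighing noise.
    """
    if total_duration <= 0 or interval <= 0 or stomatal_duration < 0:
        raise ValueError("durations and interval must be positive")
    if stomatal_multiplier < 1:
        raise ValueError("stomatal-phase slope must be at least the epidermal slope")
    if ge_true < 0:
        raise ValueError("ge_true must be non-negative")
    tail_slope = -ge_true * leaf_area * delta_e / GE_CONVERSION
    stomatal_slope = stomatal_multiplier * tail_slope
    times = np.arange(0.0, total_duration + 0.5 * interval, interval)
    weights = np.where(
        times <= stomatal_duration,
        saturated_weight + stomatal_slope * times,
        saturated_weight
        + stomatal_slope * stomatal_duration
        + tail_slope * (times - stomatal_duration),
    )
    if noise_sd > 0:
        rng = substream(seed, "mass_loss")
        weights = weights + rng.normal(0.0, noise_sd, size=weights.size)
    return MassLossSeries(
        times=times,
        fresh_weights=weights,
        leaf_area=leaf_area,
        delta_e=delta_e,
        saturated_weight=saturated_weight,
        dry_weight=dry_weight,
    )


# ---------------------------------------------------------------------------
# pressure-volume curves


@dataclass(frozen=True)
class PVGenParams:
    """Ground-truth parameters of a simulated pressure-volume curve.

    Water potential follows Psi(R) = Psi_pi(R) + Psi_p(R) with the osmotic
    component Psi_pi = psi_sat * (1 - af) / (R - af) (van't Hoff dilution
    of the symplastic water) and a turgor component linear in R between
    full turgor at R = 1 and zero at R = rwc_tlp.
    """

    psi_sat: float = -1.2  # MPa, < 0
    apoplastic_fraction: float = 0.15
    rwc_tlp: float = 0.90
    n_points: int = 24
    noise_sd: float = 0.0  # MPa on balance pressure
    r_start: float = 0.98
    r_end: float = 0.58

    def __post_init__(self) -> None:
        if self.psi_sat >= 0:
            raise ValueError("psi_sat must be negative")
        if not 0 <= self.apoplastic_fraction < self.rwc_tlp < 1:
            raise ValueError("require 0 <= apoplastic_fraction < rwc_tlp < 1")
        if self.n_points < 6:
            raise ValueError("need at least 6 PV points")
        if not 0 < self.r_start <= 1:
            raise ValueError("r_start must lie in (0, 1]")

    def water_potential(self, rwc: np.ndarray) -> np.ndarray:
        rwc = np.asarray(rwc, dtype=float)
        af = self.apoplastic_fraction
        psi_pi = self.psi_sat * (1.0 - af) / (rwc - af)
        turgor = np.where(
            rwc >= self.rwc_tlp,
            -self.psi_sat * (rwc - self.rwc_tlp) / (1.0 - self.rwc_tlp),
            0.0,
        )
        return psi_pi + turgor

    @property
    def psi_tlp(self) -> float:
        """Closed-form water potential at the turgor loss point."""
        af = self.apoplastic_fraction
        return self.psi_sat * (1.0 - af) / (self.rwc_tlp - af)


def generate_pv_curve(
    params: PVGenParams,
    saturated_mass: float = 2.0,
    dry_mass: float = 1.0,
    seed: int = 0,
) -> PVCurve:
    """Simulate pressure-chamber observations along an air-drying sequence.

    RWC steps from ``r_start`` down to ``r_end`` (truncated above the
    apoplastic fraction — the osmotic model diverges there and a real leaf
    would be wilted beyond measurement); balance pressure is -Psi plus
    optional Gaussian noise, floored just above zero to respect the
    pressure-chamber sign convention.
    """
    if saturated_mass <= dry_mass:
        raise ValueError("saturated mass must exceed dry mass")
    r_end = max(params.r_end, params.apoplastic_fraction + 0.05)
    rwc = np.linspace(params.r_start, r_end, params.n_points)
    psi = params.water_potential(rwc)
    pressure = -psi
    if params.noise_sd > 0:
        rng = substream(seed, "pv_curve")
        pressure = pressure + rng.normal(0.0, params.noise_sd, size=pressure.size)
    pressure = np.clip(pressure, 1e-3, None)
    weights = dry_mass + rwc * (saturated_mass - dry_mass)
    return PVCurve(
        observations=np.column_stack([pressure, weights]),
        saturated_weight=saturated_mass,
        dry_weight=dry_mass,
    )
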