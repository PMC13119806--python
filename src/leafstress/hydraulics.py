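"""Leaf hydraulic trait estimators.

Three estimators used in drought ecophysiology:

* **Anatomical Kmax** — maximum leaf hydraulic conductivity from petiole
  xylem vessel geometry via the Hagen-Poiseuille law.  Each vessel of
  equivalent circular radius r contributes a volumetric conductivity
  Ki = pi r^4 / (8 eta l) (m^3 s^-1 Pa^-1) for a conduit of length l filled
  with water of viscosity eta.  Summing counted vessels, scaling by the
  total-to-counted vessel ratio N/n, dividing by leaf area A and converting
  volume flow to molar flow gives Kmax in mmol m^-2 s^-1 MPa^-1.  The
  conduit length is an explicit, configurable parameter (default 0.02 m)
  because a bare pi r^4/(8 eta) is not dimensionally a conductivity;
  relative comparisons between treatments are unaffected by its value.

* **Epidermal conductance ge** — the residual water-vapor conductance after
  stomatal closure, from the linear tail of a bench-top fresh-weight
  drydown: ge = 2.31e6 * |dw/dt| * (1/A) * (1/de), where dw/dt is the
  regression slope of the post-stomatal-closure phase (g/s), A the leaf
  area (m^2) and de the leaf-to-air absolute humidity difference.  The
  2.31e6 factor is treated as a given unit-conversion constant.  Phase
  detection fits a two-segment piecewise-linear model over time and keeps
  the later (shallower) segment.

* **Pressure-volume (PV) parameters** — the classic air-drying PV curve.
  In the transform x = 1 - RWC, y = -1/P (P = balance pressure, so water
  potential is -P), the post-turgor-loss region is linear; the osmotic
  potential at full saturation is 1/intercept, the apoplastic water
  fraction comes from the x-intercept, and the turgor loss point is the
  wettest observation still on the osmotic line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: molar volume of liquid water, m^3 / mol
WATER_MOLAR_VOLUME = 1.8e-5

#: unit conversion factor of the epidermal-conductance formula (given)
GE_CONVERSION = 2.31e6


def water_viscosity(temperature_c: float = 25.0) -> float:
    """Dynamic viscosity of water (Pa s) from the Vogel correlation.

    eta = exp(-3.7188 + 578.919 / (T - 137.546)) mPa s with T in kelvin;
    accurate to ~1% between 0 and 60 degrees C (1.002 mPa s at 20 C,
    0.892 mPa s at 25 C).
    """
    t_k = temperature_c + 273.15
    return 1e-3 * math.exp(-3.7188 + 578.919 / (t_k - 137.546))


# ---------------------------------------------------------------------------
# anatomical Kmax


@dataclass
class VesselAnatomy:
    """Petiole vessel geometry for the anatomical Kmax estimate.

    ``vessel_areas`` are cross-section areas (um^2) of the n counted
    vessels; ``n_total`` is the total vessel count N in the petiole;
    ``leaf_area`` in m^2; ``petiole_length`` in m.
    """

    vessel_areas: np.ndarray
    n_total: int
    leaf_area: float
    petiole_length: float = 0.02
    water_temperature: float = 25.0

    def __post_init__(self) -> None:
        self.vessel_areas = np.asarray(self.vessel_areas, dtype=float)
        if self.vessel_areas.size == 0:
            raise ValueError("empty vessel list")
        if (self.vessel_areas <= 0).any():
            raise ValueError("vessel areas must be positive")
        if self.n_counted > self.n_total:
            raise ValueError("counted vessels exceed total vessel count")
        if self.leaf_area <= 0 or self.petiole_length <= 0:
            raise ValueError("leaf area and petiole length must be positive")

    @property
    def n_counted(self) -> int:
        return int(self.vessel_areas.size)


def equivalent_radius(area_um2: float | np.ndarray) -> float | np.ndarray:
    """Radius (um) of the circle with the same area as an irregular vessel."""
    area = np.asarray(area_um2, dtype=float)
    if (area <= 0).any():
        raise ValueError("vessel area must be positive")
    r = np.sqrt(area / math.pi)
    return float(r) if np.isscalar(area_um2) else r


def single_vessel_conductivity(
    radius_m: float, viscosity: float, petiole_length: float = 0.02
) -> float:
    """Hagen-Poiseuille volumetric conductivity of one vessel.

    Ki = pi r^4 / (8 eta l) in m^3 s^-1 Pa^-1 for radius r (m), water
    viscosity eta (Pa s) and conduit length l (m).  Scales as r^4.
    """
    if radius_m < 0:
        raise ValueError("radius must be non-negative")
    if viscosity <= 0 or petiole_length <= 0:
        raise ValueError("viscosity and petiole length must be positive")
    return math.pi * radius_m**4 / (8.0 * viscosity * petiole_length)


def leaf_kmax(anatomy: VesselAnatomy) -> float:
    """Maximum leaf hydraulic conductivity, mmol m^-2 s^-1 MPa^-1.

    Kmax = (N / (n A)) * sum_i Ki over the n counted vessels, converted
    from volumetric (m^3 s^-1 Pa^-1 per m^2 leaf) to molar units via the
    molar volume of water and Pa -> MPa, mol -> mmol factors.  Warns when
    fewer than two-thirds of the vessels were measured (the conventional
    sampling rule for this method).
    """
    n, big_n = anatomy.n_counted, anatomy.n_total
    if n < math.ceil(2 * big_n / 3):
        warnings.warn(
            f"only {n}/{big_n} vessels measured (< 2/3 of total); "
            "Kmax estimate may be unrepresentative",
            stacklevel=2,
        )
    eta = water_viscosity(anatomy.water_temperature)
    radii_m = equivalent_radius(anatomy.vessel_areas) * 1e-6
    ki_sum = sum(
        single_vessel_conductivity(r, eta, anatomy.petiole_length) for r in radii_m
    )
    k_si = (big_n / n) * ki_sum / anatomy.leaf_area  # m s^-1 Pa^-1
    return k_si / WATER_MOLAR_VOLUME * 1e6 * 1e3  # mmol m^-2 s^-1 MPa^-1


# ---------------------------------------------------------------------------
# epidermal conductance


@dataclass
class MassLossSeries:
    """Timed fresh weights of a detached, saturated leaf drying in the dark.

    ``times`` in s (strictly increasing), ``fresh_weights`` in g,
    ``leaf_area`` in m^2, ``delta_e`` the leaf-to-air absolute humidity
    difference in the units of the ge formula.
    """

    times: np.ndarray
    fresh_weights: np.ndarray
    leaf_area: float
    delta_e: float
    saturated_weight: float | None = None
    dry_weight: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fresh_weights = np.asarray(self.fresh_weights, dtype=float)
        if self.times.shape != self.fresh_weights.shape:
            raise ValueError("times and fresh_weights must have equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.leaf_area <= 0:
            raise ValueError("leaf area must be positive")
        if self.dry_weight is not None and (self.fresh_weights < self.dry_weight).any():
            raise ValueError("fresh weights below dry weight")


@dataclass(frozen=True)
class EpidermalPhase:
    """Detected post-stomatal-closure segment of a drydown series."""

    start: int
    stop: int  # exclusive
    slope: float  # g/s, <= 0 on physical data
    intercept: float
    sse_total: float


def _ols_sse(t: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, SSE)."""
    slope, intercept = np.polyfit(t, w, 1)
    resid = w - (slope * t + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def detect_epidermal_phase(series: MassLossSeries, min_segment: int = 3) -> EpidermalPhase:
    """Locate the linear tail after stomatal closure.

    Fits every two-segment split (each segment >= ``min_segment`` points)
    with independent least-squares lines and keeps the split with minimal
    total squared error; ties resolve to the earliest breakpoint (longest
    tail).  Returns the later segment's slope and index range.
    """
    t, w = series.times, series.fresh_weights
    n = t.size
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} observations, got {n}")
    if np.all(np.diff(w) >= 0) and np.ptp(w) > 0:
        raise ValueError("fresh weights do not decrease; not a drydown series")

    best: EpidermalPhase | None = None
    for k in range(min_segment, n - min_segment + 1):
        _, _, sse1 = _ols_sse(t[:k], w[:k])
        slope2, icpt2, sse2 = _ols_sse(t[k:], w[k:])
        total = sse1 + sse2
        if best is None or total < best.sse_total - 1e-18:
            best = EpidermalPhase(start=k, stop=n, slope=slope2, intercept=icpt2, sse_total=total)
    assert best is not None
    return best


def epidermal_conductance(
    series: MassLossSeries, phase: EpidermalPhase | None = None
) -> float:
    """Epidermal conductance ge from the drydown tail slope.

    ge = 2.31e6 * |slope| / (A * de); homogeneous of degree -1 in both the
    leaf area and the humidity difference.
    """
    if series.delta_e <= 0:
        raise ValueError("delta_e must be positive")
    if phase is None:
        phase = detect_epidermal_phase(series)
    return GE_CONVERSION * abs(phase.slope) / (series.leaf_area * series.delta_e)


def relative_water_content(fresh: float, saturated: float, dry: float) -> float:
    """RWC = (fresh - dry) / (saturated - dry), clipped to [0, 1].

    Values outside the unit interval by at most 1% (measurement jitter)
    are clipped with a warning; larger excursions raise.
    """
    if saturated <= dry:
        raise ValueError("saturated weight must exceed dry weight")
    rwc = (fresh - dry) / (saturated - dry)
    if rwc < -0.01 or rwc > 1.01:
        raise ValueError(f"relative water content {rwc:.3f} outside plausible range")
    if rwc < 0.0 or rwc > 1.0:
        warnings.warn("relative water content clipped to [0, 1]", stacklevel=2)
        rwc = min(max(rwc, 0.0), 1.0)
    return rwc


# ---------------------------------------------------------------------------
# pressure-volume curves


@dataclass
class PVCurve:
    """Pressure-chamber observations along an air-drying sequence.

    ``observations`` is a sequence of (balance_pressure MPa > 0,
    fresh_weight g), ordered from wet to dry; water potential is the
    negative of the balance pressure.
    """

    observations: np.ndarray  # shape (n, 2): balance pressure, fresh weight
    saturated_weight: float
    dry_weight: float

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if self.observations.ndim != 2 or self.observations.shape[1] != 2:
            raise ValueError("observations must be an (n, 2) array")
        p, w = self.observations[:, 0], self.observations[:, 1]
        if (p <= 0).any():
            raise ValueError("balance pressures must be positive")
        if (np.diff(w) > 1e-12).any():
            raise ValueError("fresh weights must be non-increasing along the sequence")
        if self.saturated_weight <= self.dry_weight:
            raise ValueError("saturated weight must exceed dry weight")

    def rwc(self) -> np.ndarray:
        return (self.observations[:, 1] - self.dry_weight) / (
            self.saturated_weight - self.dry_weight
        )


@dataclass(frozen=True)
class PVParams:
    """Fitted pressure-volume parameters.

    All successful fits satisfy psi_tlp < psi_sat < 0 and
    apoplastic_fraction < rwc_tlp.
    """

    psi_sat: float  # MPa, osmotic potential at full saturation
    psi_tlp: float  # MPa, water potential at the turgor loss point
    rwc_tlp: float  # fraction
    apoplastic_fraction: float
    slope: float  # osmotic line in (x = 1-RWC, y = -1/P) space
    intercept: float
    n_points_on_line: int
    r_squared: float
    line_points: np.ndarray = field(repr=False, default=None)


def fit_pv_parameters(
    curve: PVCurve,
    r2_threshold: float = 0.99,
    residual_factor: float = 2.5,
    min_points: int = 3,
    interpolate_tlp: bool = False,
) -> PVParams:
    """Fit the osmotic line of a PV curve and extract its parameters.

    Observations are transformed to (x = 1 - RWC, y = -1/P).  The osmotic
    line is seeded with the driest third of the observations (air-drying
    protocols deliberately run well past turgor loss, so the driest third
    is safely osmotic) and grown toward wetter points while each
    candidate's residual stays within ``residual_factor`` times the
    current RMSE; the accepted set is the post-turgor-loss (purely
    osmotic) region.  The final region must reach R^2 >=
    ``r2_threshold`` — R^2 is a validation criterion rather than a
    growth criterion because over a short dry-end span the statistic is
    dominated by noise even on perfectly osmotic points.

    psi_sat = 1/intercept; the apoplastic fraction is 1 - x0 where the line
    crosses y = 0; rwc_tlp is the RWC of the wettest accepted point (or,
    with ``interpolate_tlp``, unchanged here because the discrete
    convention is the primary definition — the flag instead midpoints the
    wettest accepted and the first rejected observation); psi_tlp is the
    osmotic line evaluated at rwc_tlp.
    """
    rwc = curve.rwc()
    if rwc.size < 2 * min_points:
        raise ValueError(f"need at least {2 * min_points} PV observations")
    x = 1.0 - rwc
    y = -1.0 / curve.observations[:, 0]
    order = np.argsort(x)[::-1]  # driest first
    xs, ys = x[order], y[order]

    # Residuals are judged on the balance-pressure scale: chamber noise is
    # homoscedastic in P, while the y = -1/P transform inflates it at wet
    # (low-pressure) points and would stall the region growth there.
    pressures = -1.0 / ys

    def pressure_residuals(slope: float, intercept: float, idx: np.ndarray) -> np.ndarray:
        y_pred = slope * xs[idx] + intercept
        with np.errstate(divide="ignore"):
            p_pred = -1.0 / y_pred
        return pressures[idx] - p_pred

    accepted = max(min_points, xs.size // 3)
    while accepted < xs.size:
        slope, intercept, _ = _ols_sse(xs[:accepted], ys[:accepted])
        resid_acc = pressure_residuals(slope, intercept, np.arange(accepted))
        rmse = math.sqrt(float(np.mean(resid_acc**2)))
        resid = abs(pressure_residuals(slope, intercept, np.array([accepted]))[0])
        # absolute floor keeps exact (noise-free) points from being rejected
        # on float-epsilon RMSE
        if resid > max(residual_factor * rmse, 1e-9):
            break
        accepted += 1

    slope, intercept, sse = _ols_sse(xs[:accepted], ys[:accepted])
    sst = float(np.sum((ys[:accepted] - ys[:accepted].mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if r2 < r2_threshold:
        raise ValueError(
            f"no acceptable linear region: R^2 = {r2:.4f} over the "
            f"{accepted} driest observations (threshold {r2_threshold})"
        )
    if intercept >= 0:
        raise ValueError(
            "positive intercept in the PV transform (implies osmotic potential "
            f">= 0); accepted {accepted} points, slope={slope:.4g}, "
            f"intercept={intercept:.4g} — curve may lack a post-turgor-loss region"
        )
    if slope <= 0:
        raise ValueError(
            "non-positive osmotic-line slope; no valid linear region found "
            f"(accepted {accepted} points)"
        )

    psi_sat = 1.0 / intercept
    x0 = -intercept / slope
    af = 1.0 - x0
    x_tlp = xs[accepted - 1]  # wettest accepted point
    if interpolate_tlp and accepted < xs.size:
        x_tlp = 0.5 * (xs[accepted - 1] + xs[accepted])
    rwc_tlp = 1.0 - x_tlp
    y_tlp = slope * x_tlp + intercept
    psi_tlp = 1.0 / y_tlp
    if not (psi_tlp < psi_sat < 0):
        raise ValueError(
            f"inconsistent PV fit: psi_tlp={psi_tlp:.3f}, psi_sat={psi_sat:.3f}"
        )
    return PVParams(
        psi_sat=psi_sat,
        psi_tlp=psi_tlp,
        rwc_tlp=float(rwc_tlp),
        apoplastic_fraction=float(af),
        slope=slope,
        intercept=intercept,
        n_points_on_line=int(accepted),
        r_squared=float(r2),
        line_points=np.column_stack([xs[:accepted], ys[:accepted]]),
    )
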