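"""Experiment configuration and the default calibration.

The emulated study is a factorial pot-drought experiment on two-year-old
seedlings of an autumn-coloring deciduous tree: four soil-water treatments
(CK = 100% of field capacity, T1 = 75-80%, T2 = 50-55%, T3 = 35-40%) crossed
with four sampling periods (S1..S4, 20-day intervals through the leaf-color
transition), three replicates per cell.

Cell means and standard errors come from two sources:

* the eight leaf-anatomy traits (Uep, Lep, Pt, St, Xt, Mvt, LT, PSR) carry
  published per-cell means +/- SE (n = 3) and are reproduced verbatim;
* all remaining traits (CIELAB color, pigments, enzyme activities, gas
  exchange, hydraulics) were published only as bar charts, so their cell
  means here are plausible calibrations: anchored to the handful of values
  and percent changes quoted in the running text (e.g. a* = 29.6 for T3 at
  S3 vs 3.7 for CK; the S4 hydraulic percent declines) and otherwise chosen
  once to follow the described treatment/period profiles. They are flagged
  via :data:`CALIBRATED_TRAITS` and must not be mistaken for printed data.

SEs are per-cell standard errors of the mean over n = 3 replicates; the
generator draws replicates with sd = SE * sqrt(n) so that sample SEs match
the configured ones in expectation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

SCHEMA_VERSION = 1

TREATMENTS = ("CK", "T1", "T2", "T3")
PERIODS = ("S1", "S2", "S3", "S4")

#: soil water content band per treatment, as percent of field capacity
SOIL_WATER_BANDS = {
    "CK": (100.0, 100.0),
    "T1": (75.0, 80.0),
    "T2": (50.0, 55.0),
    "T3": (35.0, 40.0),
}

#: ratio traits derived per replicate from drawn pigment values
RATIO_TRAITS = ("Ant_Chl", "Car_Chl", "Ant_Car")

#: response traits (CIELAB color); everything else is a candidate predictor
COLOR_TRAITS = ("L_star", "a_star", "b_star")

TRAIT_UNITS = {
    "L_star": "dimensionless",
    "a_star": "dimensionless",
    "b_star": "dimensionless",
    "Uep": "um",
    "Lep": "um",
    "Pt": "um",
    "St": "um",
    "Xt": "um",
    "Mvt": "um",
    "LT": "um",
    "PSR": "dimensionless",
    "Chl": "mg/g FW",
    "Car": "mg/g FW",
    "Ant": "dA/g FW",
    "Ant_Chl": "dimensionless",
    "Car_Chl": "dimensionless",
    "Ant_Car": "dimensionless",
    "POD": "U/g",
    "SOD": "U/g",
    "Pn": "umol/m2/s",
    "Tr": "mmol/m2/s",
    "Kmax": "mmol/m2/s/MPa",
    "ge": "mmol/m2/s",
    "RWC_tlp": "fraction",
    "Psi_tlp": "MPa",
    "Psi_sat": "MPa",
}

# -- published anatomy table: (treatment, period) -> (mean, SE), n = 3 --------
# Order of rows: S1, S2, S3, S4 within each treatment.

_ANATOMY_TABLE = {
    "Uep": {
        "CK": [(14.5, 0.3), (14.2, 0.1), (13.5, 0.1), (13.1, 0.2)],
        "T1": [(14.2, 0.1), (13.8, 0.3), (12.8, 0.4), (12.2, 0.2)],
        "T2": [(14.1, 0.4), (13.1, 0.3), (11.3, 0.2), (10.6, 0.2)],
        "T3": [(14.2, 0.4), (12.6, 0.3), (10.2, 0.3), (9.3, 0.1)],
    },
    "Lep": {
        "CK": [(10.6, 0.7), (10.1, 0.6), (10.2, 0.8), (8.9, 0.5)],
        "T1": [(10.2, 0.8), (9.6, 0.6), (9.0, 0.5), (8.8, 0.4)],
        "T2": [(10.6, 0.6), (8.8, 0.5), (8.1, 0.7), (7.3, 0.6)],
        "T3": [(10.4, 0.4), (8.3, 0.5), (7.4, 0.6), (7.1, 0.3)],
    },
    "Pt": {
        "CK": [(82.1, 3.7), (72.1, 1.1), (66.8, 1.8), (61.5, 0.9)],
        "T1": [(82.3, 1.3), (70.5, 2.4), (64.2, 3.4), (58.2, 2.6)],
        "T2": [(82.5, 2.7), (63.2, 3.3), (56.6, 3.1), (50.3, 2.3)],
        "T3": [(82.2, 2.6), (60.1, 3.4), (51.2, 3.2), (46.3, 1.6)],
    },
    "St": {
        "CK": [(62.7, 3.6), (57.1, 0.8), (54.8, 2.4), (49.2, 0.2)],
        "T1": [(63.3, 2.3), (55.2, 1.4), (53.2, 1.2), (48.6, 0.9)],
        "T2": [(62.6, 2.8), (48.6, 0.9), (46.6, 0.8), (43.2, 0.6)],
        "T3": [(62.8, 2.2), (46.2, 0.8), (44.1, 0.7), (38.6, 0.6)],
    },
    "Xt": {
        "CK": [(77.1, 2.5), (67.1, 1.3), (52.4, 1.4), (50.5, 0.3)],
        "T1": [(77.2, 2.3), (65.2, 1.8), (50.2, 0.8), (48.9, 0.5)],
        "T2": [(76.4, 2.2), (58.3, 1.1), (46.7, 0.6), (44.4, 0.4)],
        "T3": [(76.1, 2.7), (56.2, 1.3), (43.2, 0.3), (40.6, 0.3)],
    },
    "Mvt": {
        "CK": [(925.3, 1.6), (862.5, 0.7), (723.6, 7.6), (716.3, 8.4)],
        "T1": [(916.3, 5.6), (855.2, 4.5), (714.6, 3.3), (714.2, 3.6)],
        "T2": [(922.2, 5.1), (836.8, 4.3), (702.9, 2.8), (703.6, 2.4)],
        "T3": [(918.3, 5.1), (821.4, 4.2), (691.5, 2.9), (687.6, 1.8)],
    },
    "LT": {
        "CK": [(170.5, 5.1), (155.3, 2.0), (147.5, 2.6), (131.3, 2.1)],
        "T1": [(168.1, 2.8), (154.1, 5.7), (143.8, 4.4), (128.5, 4.6)],
        "T2": [(171.6, 3.1), (150.6, 2.7), (140.3, 7.3), (126.2, 9.7)],
        "T3": [(170.9, 3.3), (145.5, 1.8), (134.3, 2.16), (120.2, 6.87)],
    },
    "PSR": {
        "CK": [(1.31, 0.02), (1.26, 0.00), (1.22, 0.02), (1.25, 0.01)],
        "T1": [(1.30, 0.03), (1.28, 0.01), (1.21, 0.04), (1.20, 0.03)],
        "T2": [(1.32, 0.02), (1.30, 0.04), (1.21, 0.05), (1.16, 0.04)],
        "T3": [(1.31, 0.01), (1.30, 0.05), (1.16, 0.06), (1.20, 0.03)],
    },
}

# -- figure-only traits: plausible calibrations (see module docstring) --------
# Each entry: (means-by-row, SE) with rows S1..S4 and columns CK,T1,T2,T3.

_FIGURE_CALIBRATION = {
    "L_star": (
        [
            [42.0, 41.8, 42.1, 41.9],
            [38.5, 38.2, 38.8, 38.0],
            [35.0, 38.0, 41.0, 36.0],
            [48.0, 52.0, 55.0, 50.0],
        ],
        0.8,
    ),
    "a_star": (
        [
            [-12.0, -11.8, -12.1, -11.9],
            [-10.0, -9.0, -7.5, 8.0],
            [3.7, 15.0, 22.0, 29.6],
            [43.4, 20.0, 18.0, 28.0],
        ],
        0.8,
    ),
    "b_star": (
        [
            [22.0, 21.8, 22.2, 21.9],
            [18.5, 18.2, 18.8, 18.0],
            [15.0, 24.0, 26.0, 17.0],
            [30.0, 40.0, 42.0, 34.0],
        ],
        0.8,
    ),
    "Chl": (
        [
            [1.80, 1.78, 1.79, 1.77],
            [1.60, 1.45, 1.30, 1.15],
            [1.30, 1.05, 0.85, 0.65],
            [0.70, 0.55, 0.45, 0.40],
        ],
        0.04,
    ),
    "Ant": (
        [
            [0.08, 0.08, 0.08, 0.08],
            [0.10, 0.14, 0.18, 0.22],
            [0.14, 0.22, 0.28, 0.27],
            [0.30, 0.12, 0.14, 0.15],
        ],
        0.01,
    ),
    "Car": (
        [
            [0.40, 0.40, 0.40, 0.39],
            [0.39, 0.38, 0.38, 0.37],
            [0.38, 0.37, 0.36, 0.35],
            [0.35, 0.52, 0.55, 0.45],
        ],
        0.02,
    ),
    # POD/SOD anchors: at S2 T3 exceeds CK by 38.0% (POD) and 75.7% (SOD);
    # POD peaks under T2 at S3 (+57.7%) and S4 (+31.3%); SOD peaks under T1
    # at S3 (+12.9%) and S4 (+6.3%).
    "POD": (
        [
            [350.0, 352.0, 348.0, 351.0],
            [420.0, 520.0, 540.0, 420.0 * 1.380],
            [380.0, 500.0, 380.0 * 1.577, 450.0],
            [320.0, 380.0, 320.0 * 1.313, 350.0],
        ],
        12.0,
    ),
    "SOD": (
        [
            [300.0, 302.0, 298.0, 301.0],
            [340.0, 420.0, 500.0, 340.0 * 1.757],
            [430.0, 430.0 * 1.129, 460.0, 440.0],
            [380.0, 380.0 * 1.063, 390.0, 370.0],
        ],
        10.0,
    ),
    # Pn declines with severity; T3 is 21.4% (S2) and 20.1% (S3) below CK.
    "Pn": (
        [
            [10.5, 10.4, 10.5, 10.4],
            [9.8, 9.2, 8.5, 9.8 * (1 - 0.214)],
            [8.6, 8.0, 7.4, 8.6 * (1 - 0.201)],
            [6.5, 6.0, 5.6, 5.2],
        ],
        0.2,
    ),
    # Tr: T3 is 36.9% / 24.8% / 20.7% below CK at S2/S3/S4.
    "Tr": (
        [
            [3.60, 3.58, 3.61, 3.59],
            [3.25, 2.90, 2.50, 3.25 * (1 - 0.369)],
            [2.70, 2.50, 2.25, 2.70 * (1 - 0.248)],
            [2.10, 2.00, 1.85, 2.10 * (1 - 0.207)],
        ],
        0.08,
    ),
    # Hydraulics: S4 declines vs CK are the quoted 5.1/24.3/45.2% (Kmax),
    # 20.2/20.5/39.7% (RWC_tlp), 9.5/4.8/14.3% (Psi_tlp), 5.5/10.0/16.5%
    # (Psi_sat); overall Kmax span kept inside 9.7-22.5.
    "Kmax": (
        [
            [22.5, 22.2, 21.9, 21.6],
            [21.0, 20.0, 18.5, 16.5],
            [19.5, 18.0, 16.0, 13.0],
            [17.7, 17.7 * (1 - 0.051), 17.7 * (1 - 0.243), 17.7 * (1 - 0.452)],
        ],
        0.4,
    ),
    "ge": (
        [
            [9.0, 8.9, 8.8, 8.7],
            [8.0, 7.6, 7.2, 6.8],
            [6.5, 6.2, 5.8, 5.5],
            [5.0, 4.8, 4.5, 4.2],
        ],
        0.2,
    ),
    "RWC_tlp": (
        [
            [0.96, 0.95, 0.95, 0.94],
            [0.94, 0.90, 0.88, 0.85],
            [0.91, 0.80, 0.78, 0.70],
            [0.88, 0.88 * (1 - 0.202), 0.88 * (1 - 0.205), 0.88 * (1 - 0.397)],
        ],
        0.01,
    ),
    "Psi_tlp": (
        [
            [-1.60, -1.61, -1.62, -1.63],
            [-1.70, -1.78, -1.85, -1.95],
            [-1.90, -2.05, -2.10, -2.20],
            [-2.10, -2.10 * 1.095, -2.10 * 1.048, -2.10 * 1.143],
        ],
        0.04,
    ),
    "Psi_sat": (
        [
            [-1.30, -1.31, -1.32, -1.33],
            [-1.40, -1.48, -1.55, -1.62],
            [-1.60, -1.70, -1.78, -1.88],
            [-1.90, -1.90 * 1.055, -1.90 * 1.100, -1.90 * 1.165],
        ],
        0.04,
    ),
}

#: traits whose cell means are calibrations, not printed numbers
CALIBRATED_TRAITS = tuple(sorted(_FIGURE_CALIBRATION))


@dataclass
class ExperimentConfig:
    """Factorial design plus per-cell trait means and noise model.

    ``cell_stats[trait][(treatment, period)] = (mean, se)``.  Replicates are
    drawn as ``mean + Normal(0, se * sqrt(replicates))``.
    """

    treatments: tuple[str, ...] = TREATMENTS
    periods: tuple[str, ...] = PERIODS
    replicates: int = 3
    #: replicate count behind the configured SEs (published tables use n = 3)
    se_n: int = 3
    cell_stats: dict[str, dict[tuple[str, str], tuple[float, float]]] = field(
        default_factory=dict
    )
    units: dict[str, str] = field(default_factory=lambda: dict(TRAIT_UNITS))
    soil_water_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SOIL_WATER_BANDS)
    )
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        for trait, cells in self.cell_stats.items():
            for key, (mean, se) in cells.items():
                if se < 0:
                    raise ValueError(f"negative SE for {trait} at {key}")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.cell_stats)

    def cell(self, trait: str, treatment: str, period: str) -> tuple[float, float]:
        """(mean, SE) for one design cell; explicit error when missing."""
        try:
            cells = self.cell_stats[trait]
        except KeyError:
            raise KeyError(f"no cell means configured for trait {trait!r}") from None
        try:
            return cells[(treatment, period)]
        except KeyError:
            raise KeyError(
                f"missing cell mean for trait {trait!r} at "
                f"treatment={treatment!r}, period={period!r}"
            ) from None

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "treatments": list(self.treatments),
            "periods": list(self.periods),
            "replicates": self.replicates,
            "se_n": self.se_n,
            "soil_water_bands": {k: list(v) for k, v in self.soil_water_bands.items()},
            "units": dict(self.units),
            "cell_stats": {
                trait: {
                    f"{t}:{p}": [mean, se] for (t, p), (mean, se) in cells.items()
                }
                for trait, cells in self.cell_stats.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        cell_stats = {}
        for trait, cells in data.get("cell_stats", {}).items():
            parsed = {}
            for key, (mean, se) in cells.items():
                t, p = key.split(":")
                parsed[(t, p)] = (float(mean), float(se))
            cell_stats[trait] = parsed
        return cls(
            treatments=tuple(data.get("treatments", TREATMENTS)),
            periods=tuple(data.get("periods", PERIODS)),
            replicates=int(data.get("replicates", 3)),
            se_n=int(data.get("se_n", 3)),
            cell_stats=cell_stats,
            units=dict(data.get("units", TRAIT_UNITS)),
            soil_water_bands={
                k: tuple(v) for k, v in data.get("soil_water_bands", SOIL_WATER_BANDS).items()
            },
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """SHA-256 over the canonical JSON form (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_config(seed: int = 0) -> ExperimentConfig:
    """The study-calibrated default configuration.

    Anatomy traits carry published per-cell means/SEs; figure-only traits
    carry the documented calibrations (:data:`CALIBRATED_TRAITS`).
    """
    cell_stats: dict[str, dict[tuple[str, str], tuple[float, float]]] = {}
    for trait, by_treatment in _ANATOMY_TABLE.items():
        cells = {}
        for treatment, rows in by_treatment.items():
            for period, (mean, se) in zip(PERIODS, rows):
                cells[(treatment, period)] = (float(mean), float(se))
        cell_stats[trait] = cells
    for trait, (rows, se) in _FIGURE_CALIBRATION.items():
        cells = {}
        for period, row in zip(PERIODS, rows):
            for treatment, mean in zip(TREATMENTS, row):
                cells[(treatment, period)] = (float(mean), float(se))
        cell_stats[trait] = cells
    return ExperimentConfig(cell_stats=cell_stats, seed=seed)
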