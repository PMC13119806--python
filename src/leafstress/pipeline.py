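"""Pipeline orchestration: simulate -> traits -> stats -> importance -> report.

Each stage reads and writes plain CSV/JSON artifacts under one run
directory and records itself in ``manifest.json`` (config digest, master
seed, per-file SHA-256 digests, package version).  Stages are
deterministic given the config and master seed, so re-running a stage
rewrites byte-identical artifacts.

The simulate stage writes the long-format trait table (the canonical
analysis input) plus raw measurement exemplars per design cell for the
five derivable trait families; the traits stage re-derives replicate- or
cell-level values from those raw bundles, demonstrating the measurement
-> trait half of the pipeline; stats and importance consume the trait
table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from leafstress import __version__
from leafstress._rng import substream
from leafstress.colorimetry import aggregate_color, write_trait_table, read_trait_table
from leafstress.config import COLOR_TRAITS, RATIO_TRAITS, ExperimentConfig, default_config
from leafstress.hydraulics import (
    MassLossSeries,
    PVCurve,
    VesselAnatomy,
    epidermal_conductance,
    fit_pv_parameters,
    leaf_kmax,
)
from leafstress.importance import backward_select, importance_significance, model_significance
from leafstress.pigments import AbsorbanceSet, pigment_profile
from leafstress.stats import letter_matrix, pearson_matrix
from leafstress.synthetic import (
    PVGenParams,
    generate_absorbance_sets,
    generate_color_readings,
    generate_mass_loss_series,
    generate_pv_curve,
    generate_trait_table,
    generate_vessel_anatomy,
)

logger = logging.getLogger("leafstress.pipeline")

STAGES = ("simulate", "traits", "stats", "importance", "report")

#: humidity difference used for the drydown exemplars (formula units)
_EXEMPLAR_DELTA_E = 400.0
_EXEMPLAR_LEAF_AREA = 0.01


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_manifest(outdir: Path) -> dict:
    path = outdir / "manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {"version": __version__, "stages": {}}


def _record_stage(outdir: Path, name: str, config: ExperimentConfig, files: list[Path]) -> None:
    manifest = _load_manifest(outdir)
    manifest["version"] = __version__
    manifest["config_digest"] = config.digest()
    manifest["seed"] = config.seed
    manifest["stages"][name] = {
        "files": {f.name: _sha256(f) for f in sorted(files)},
        "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# simulate


def stage_simulate(config: ExperimentConfig, outdir: Path) -> list[Path]:
    """Generate the trait table and per-cell raw measurement exemplars."""
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    table = generate_trait_table(config)
    table_path = outdir / "trait_table.csv"
    write_trait_table(table, table_path)
    written.append(table_path)

    wide = table.pivot_table(
        index=["treatment", "period"], columns="trait", values="value"
    )  # cell means of the drawn replicates
    seed_stream = substream(config.seed, "raw_exemplars")

    color_rows, abs_rows, vessel_rows, mass_rows, pv_rows = [], [], [], [], []
    for (treatment, period), cell in wide.iterrows():
        cell_seed = int(seed_stream.integers(2**31))
        readings = generate_color_readings(
            (cell["L_star"], cell["a_star"], cell["b_star"]),
            n_leaves=10,
            reads_per_leaf=10,
            noise_sd=1.5,
            seed=cell_seed,
        )
        readings.insert(0, "period", period)
        readings.insert(0, "treatment", treatment)
        color_rows.append(readings)

        abs_set = generate_absorbance_sets(
            chl=max(cell["Chl"], 0.0),
            car=max(cell["Car"], 0.0),
            ant=max(cell["Ant"], 0.0),
            noise_rel=0.01,
            seed=cell_seed + 1,
        )
        abs_rows.append(
            {
                "treatment": treatment,
                "period": period,
                "A445": abs_set.A445,
                "A645": abs_set.A645,
                "A663": abs_set.A663,
                "A530": abs_set.A530,
                "A657": abs_set.A657,
                "mass": abs_set.mass,
                "volume": abs_set.volume,
                "dilution": abs_set.dilution,
                "ant_mass": abs_set.ant_mass,
                "ant_volume": abs_set.ant_volume,
                "ant_dilution": abs_set.ant_dilution,
            }
        )

        # vessel geometry scaled so the anatomical Kmax tracks the cell mean
        base = generate_vessel_anatomy(seed=cell_seed + 2)
        scale = (cell["Kmax"] / leaf_kmax(base)) ** 0.25
        for area in base.vessel_areas * scale**2:
            vessel_rows.append(
                {
                    "treatment": treatment,
                    "period": period,
                    "vessel_area_um2": area,
                    "n_total": base.n_total,
                    "leaf_area_m2": base.leaf_area,
                    "petiole_length_m": base.petiole_length,
                    "water_temperature_c": base.water_temperature,
                }
            )

        series = generate_mass_loss_series(
            ge_true=cell["ge"],
            leaf_area=_EXEMPLAR_LEAF_AREA,
            delta_e=_EXEMPLAR_DELTA_E,
            noise_sd=0.002,
            seed=cell_seed + 3,
        )
        for t, w in zip(series.times, series.fresh_weights):
            mass_rows.append(
                {
                    "treatment": treatment,
                    "period": period,
                    "time_s": t,
                    "fresh_weight_g": w,
                    "leaf_area_m2": series.leaf_area,
                    "delta_e": series.delta_e,
                }
            )

        rwc_tlp = min(cell["RWC_tlp"], 0.95)
        pv_params = PVGenParams(
            psi_sat=cell["Psi_sat"],
            rwc_tlp=rwc_tlp,
            apoplastic_fraction=0.15,
            noise_sd=0.02,
            r_end=max(0.15 + 0.08, rwc_tlp - 0.30),
        )
        curve = generate_pv_curve(pv_params, seed=cell_seed + 4)
        for pressure, weight in curve.observations:
            pv_rows.append(
                {
                    "treatment": treatment,
                    "period": period,
                    "balance_pressure_mpa": pressure,
                    "fresh_weight_g": weight,
                    "saturated_weight_g": curve.saturated_weight,
                    "dry_weight_g": curve.dry_weight,
                }
            )

    for name, rows in (
        ("color_readings.csv", pd.concat(color_rows, ignore_index=True)),
        ("absorbance_sets.csv", pd.DataFrame(abs_rows)),
        ("vessel_anatomy.csv", pd.DataFrame(vessel_rows)),
        ("mass_loss.csv", pd.DataFrame(mass_rows)),
        ("pv_curves.csv", pd.DataFrame(pv_rows)),
    ):
        path = outdir / name
        rows.to_csv(path, index=False)
        written.append(path)
    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    written.append(config_path)
    _record_stage(outdir, "simulate", config, written)
    logger.info("simulate: wrote %d files to %s", len(written), outdir)
    return written


# ---------------------------------------------------------------------------
# traits


def stage_traits(config: ExperimentConfig, outdir: Path) -> list[Path]:
    """Re-derive cell-level traits from the simulated raw exemplars."""
    colors = pd.read_csv(outdir / "color_readings.csv")
    absorb = pd.read_csv(outdir / "absorbance_sets.csv")
    vessels = pd.read_csv(outdir / "vessel_anatomy.csv")
    mass = pd.read_csv(outdir / "mass_loss.csv")
    pv = pd.read_csv(outdir / "pv_curves.csv")

    rows = []
    for (treatment, period), group in colors.groupby(["treatment", "period"], sort=False):
        agg = aggregate_color(group)
        for trait, value in (
            ("L_star", agg.L_star),
            ("a_star", agg.a_star),
            ("b_star", agg.b_star),
        ):
            rows.append((treatment, period, trait, value))

    for _, rec in absorb.iterrows():
        abs_set = AbsorbanceSet(
            A445=rec["A445"],
            A645=rec["A645"],
            A663=rec["A663"],
            A530=rec["A530"],
            A657=rec["A657"],
            mass=rec["mass"],
            volume=rec["volume"],
            dilution=rec["dilution"],
            ant_mass=rec["ant_mass"],
            ant_volume=rec["ant_volume"],
            ant_dilution=rec["ant_dilution"],
        )
        profile = pigment_profile(abs_set)
        for trait in ("Chl", "Car", "Ant", "Ant_Chl", "Car_Chl", "Ant_Car"):
            rows.append((rec["treatment"], rec["period"], trait, getattr(profile, trait)))

    for (treatment, period), group in vessels.groupby(["treatment", "period"], sort=False):
        anatomy = VesselAnatomy(
            vessel_areas=group["vessel_area_um2"].to_numpy(),
            n_total=int(group["n_total"].iloc[0]),
            leaf_area=float(group["leaf_area_m2"].iloc[0]),
            petiole_length=float(group["petiole_length_m"].iloc[0]),
            water_temperature=float(group["water_temperature_c"].iloc[0]),
        )
        rows.append((treatment, period, "Kmax", leaf_kmax(anatomy)))

    for (treatment, period), group in mass.groupby(["treatment", "period"], sort=False):
        series = MassLossSeries(
            times=group["time_s"].to_numpy(),
            fresh_weights=group["fresh_weight_g"].to_numpy(),
            leaf_area=float(group["leaf_area_m2"].iloc[0]),
            delta_e=float(group["delta_e"].iloc[0]),
        )
        rows.append((treatment, period, "ge", epidermal_conductance(series)))

    for (treatment, period), group in pv.groupby(["treatment", "period"], sort=False):
        curve = PVCurve(
            observations=group[["balance_pressure_mpa", "fresh_weight_g"]].to_numpy(),
            saturated_weight=float(group["saturated_weight_g"].iloc[0]),
            dry_weight=float(group["dry_weight_g"].iloc[0]),
        )
        try:
            params = fit_pv_parameters(curve)
        except ValueError as exc:  # occasional noisy curve without a clean region
            logger.warning("PV fit failed for %s/%s: %s", treatment, period, exc)
            continue
        rows.append((treatment, period, "Psi_sat", params.psi_sat))
        rows.append((treatment, period, "Psi_tlp", params.psi_tlp))
        rows.append((treatment, period, "RWC_tlp", params.rwc_tlp))

    derived = pd.DataFrame(rows, columns=["treatment", "period", "trait", "derived_value"])
    configured = []
    for _, rec in derived.iterrows():
        trait = rec["trait"]
        if trait in RATIO_TRAITS or trait == "Psi_tlp":
            configured.append(np.nan)  # derived through other quantities
            continue
        try:
            mean, _ = config.cell(trait, rec["treatment"], rec["period"])
            configured.append(mean)
        except KeyError:
            configured.append(np.nan)
    derived["configured_mean"] = configured
    path = outdir / "derived_traits.csv"
    derived.to_csv(path, index=False)
    _record_stage(outdir, "traits", config, [path])
    logger.info("traits: derived %d cell-level values", len(derived))
    return [path]


# ---------------------------------------------------------------------------
# stats


def stage_stats(config: ExperimentConfig, outdir: Path, alpha: float = 0.05) -> list[Path]:
    """Letter grids for every trait plus the Pearson correlation matrices."""
    table = read_trait_table(outdir / "trait_table.csv")
    grids = [letter_matrix(table, trait, alpha=alpha) for trait in sorted(table["trait"].unique())]
    letters = pd.concat(grids, ignore_index=True)
    letters_path = outdir / "letters.csv"
    letters.to_csv(letters_path, index=False)
    r, p = pearson_matrix(table)
    r_path, p_path = outdir / "pearson_r.csv", outdir / "pearson_p.csv"
    r.to_csv(r_path)
    p.to_csv(p_path)
    written = [letters_path, r_path, p_path]
    _record_stage(outdir, "stats", config, written)
    logger.info("stats: %d letter rows, %d traits correlated", len(letters), len(r))
    return written


# ---------------------------------------------------------------------------
# importance


def stage_importance(
    config: ExperimentConfig,
    outdir: Path,
    n_trees: int = 500,
    n_perm_importance: int = 100,
    n_perm_model: int = 99,
    target_vars: int = 14,
) -> list[Path]:
    """Backward selection + permutation-tested importance per color response."""
    table = read_trait_table(outdir / "trait_table.csv")
    wide = table.pivot_table(
        index=["treatment", "period", "replicate"], columns="trait", values="value"
    ).dropna()
    predictors = [c for c in wide.columns if c not in COLOR_TRAITS]
    written: list[Path] = []
    summary = {}
    for response in COLOR_TRAITS:
        y = wide[response]
        X = wide[predictors]
        seed = config.seed + {"L_star": 1, "a_star": 2, "b_star": 3}[response]
        reduced, dropped = backward_select(
            X, y, target_count=target_vars, n_trees=n_trees, seed=seed
        )
        result = importance_significance(
            reduced, y, n_perm=n_perm_importance, n_trees=n_trees, seed=seed
        )
        r2, model_p = model_significance(
            reduced, y, n_perm=n_perm_model, n_trees=n_trees, seed=seed
        )
        frame = result.to_frame()
        path = outdir / f"importance_{response}.csv"
        frame.to_csv(path)
        written.append(path)
        summary[response] = {
            "r_squared_oob": r2,
            "model_p": model_p,
            "n_trees": n_trees,
            "n_perm_importance": n_perm_importance,
            "n_perm_model": n_perm_model,
            "dropped": dropped,
            "retained": list(reduced.columns),
            "significant": frame.index[frame["p"] < 0.05].tolist(),
        }
    summary_path = outdir / "importance_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(summary_path)
    _record_stage(outdir, "importance", config, written)
    logger.info("importance: analysed %d responses", len(COLOR_TRAITS))
    return written


# ---------------------------------------------------------------------------
# report


def stage_report(config: ExperimentConfig, outdir: Path) -> list[Path]:
    """Assemble a human-readable run summary from completed stage outputs."""
    manifest = _load_manifest(outdir)
    lines = [
        "leafstress run report",
        "=====================",
        f"package version: {manifest.get('version', '?')}",
        f"master seed: {manifest.get('seed', '?')}",
        f"config digest: {manifest.get('config_digest', '?')[:16]}...",
        "",
    ]
    completed = manifest.get("stages", {})
    if not completed:
        lines.append("no stages completed: nothing to report")
    if "stats" in completed:
        letters = pd.read_csv(outdir / "letters.csv")
        lines.append("Letter grid (uppercase: periods within treatment; "
                     "lowercase: treatments within period)")
        for trait in ("Mvt", "a_star", "Kmax"):
            sub = letters[letters["trait"] == trait]
            if sub.empty:
                continue
            lines.append(f"\n  {trait}:")
            for _, rec in sub.iterrows():
                lines.append(
                    f"    {rec['treatment']:>3} {rec['period']}: "
                    f"{rec['mean']:9.2f} +/- {rec['se']:.2f} "
                    f"{rec['upper']}{rec['lower']}"
                )
        lines.append("")
        lines.append("note: two independent one-way ANOVA families; no "
                     "cross-trait multiplicity correction is applied")
    else:
        lines.append("stats stage missing: letter grid unavailable")
    if "importance" in completed:
        summary = json.loads((outdir / "importance_summary.json").read_text())
        lines.append("")
        lines.append("Random-forest importance (%IncMSE, permutation-tested)")
        lines.append("caveat: n = 48 observations is small for 14 predictors; "
                     "rankings are seed-sensitive")
        for response, info in summary.items():
            lines.append(
                f"\n  {response}: OOB R^2 = {info['r_squared_oob']:.2f}, "
                f"model p = {info['model_p']:.3f}; retained "
                f"{len(info['retained'])} predictors"
            )
            frame = pd.read_csv(outdir / f"importance_{response}.csv", index_col=0)
            for name, rec in frame.head(5).iterrows():
                star = "*" if rec["p"] < 0.05 else " "
                lines.append(f"    {name:>10}: {rec['inc_mse']:7.2f} {star}")
    else:
        lines.append("importance stage missing: rankings unavailable")
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    _record_stage(outdir, "report", config, [path])
    return [path]


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    config: ExperimentConfig | None = None,
    outdir: str | Path = "runs/default",
    stages: tuple[str, ...] = STAGES,
    **importance_kwargs,
) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    config = config or default_config()
    outdir = Path(outdir)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        if stage == "simulate":
            stage_simulate(config, outdir)
        elif stage == "traits":
            stage_traits(config, outdir)
        elif stage == "stats":
            stage_stats(config, outdir)
        elif stage == "importance":
            stage_importance(config, outdir, **importance_kwargs)
        elif stage == "report":
            stage_report(config, outdir)
    return _load_manifest(outdir)
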