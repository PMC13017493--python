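"""End-to-end synthetic-trial pipeline driven by one YAML configuration.

Stages: simulate a multi-stratum MAD trial with known genotype, spatial
and curve truth -> spatial adjustment of plot yields -> time-course trait
extraction (peak LAI, CC50/CC100, NDVI decline onset) -> image indices and
voxel biomass spot checks -> A-Ci fits -> quadratic LAI-yield optimum per
stratum.  Every stage's tables are written to the run directory and a
truth-vs-estimate recovery table goes into the JSON run report.

All randomness derives from one root seed through named per-stage
substreams, so a repeated run with the same configuration is byte
identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from canopytrial import imaging, io, mad, optimum, synthetic, timecourse

log = logging.getLogger("canopytrial.pipeline")

_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "strata": None,
    "trial": {
        "n_blocks", "block_shape", "n_test_genotypes", "grand_mean_yield",
        "yield_noise_sd", "row_effect_sd", "col_effect_sd",
        "lai_vertex", "lai_curvature", "lai_mean", "lai_sd",
    },
    "adjustment": {"per_block_reference"},
    "timecourse": {"sampling_days", "noise_sd", "lowess_frac"},
    "imaging": {"n_images", "image_shape", "noise_sd"},
    "biomass": {"n_clouds", "voxel_size", "height_m", "points_per_m3"},
    "aci": {"n_curves", "vcmax25", "jmax25", "rd25", "noise_sd", "tleaf_c"},
}

_DEFAULTS = {
    "trial": {
        "n_blocks": 5, "block_shape": [5, 5], "n_test_genotypes": 40,
        # defaults follow the trial's reported scales: yields near
        # 5,500-6,300 kg ha-1 and peak LAI around 9-10
        "grand_mean_yield": 5900.0, "yield_noise_sd": 150.0,
        "row_effect_sd": 120.0, "col_effect_sd": 120.0,
        "lai_vertex": 9.5, "lai_curvature": 60.0, "lai_mean": 9.2, "lai_sd": 1.2,
    },
    "adjustment": {"per_block_reference": False},
    "timecourse": {"sampling_days": list(range(25, 96, 5)), "noise_sd": 0.15,
                   "lowess_frac": 0.5},
    "imaging": {"n_images": 4, "image_shape": [60, 60], "noise_sd": 0.0},
    "biomass": {"n_clouds": 3, "voxel_size": 0.05, "height_m": 0.6,
                "points_per_m3": 2.0e4},
    "aci": {"n_curves": 3, "vcmax25": 110.0, "jmax25": 180.0, "rd25": 1.5,
            "noise_sd": 0.0, "tleaf_c": 28.0},
}


class ConfigError(ValueError):
    """Configuration failed schema validation."""


def validate_config(cfg: dict) -> dict:
    """Check required keys, reject unknown ones, and fill defaults."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigError("missing required key: 'seed'")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("'seed' must be an integer")
    if "strata" not in cfg or not cfg["strata"]:
        raise ConfigError("missing required key: 'strata' (list of location/spacing)")
    for s in cfg["strata"]:
        bad = set(s) - {"location", "spacing", "n_blocks"}
        if bad:
            raise ConfigError(f"unknown stratum keys: {sorted(bad)}")
        if "location" not in s or "spacing" not in s:
            raise ConfigError("each stratum needs 'location' and 'spacing'")
    out = {"seed": cfg["seed"], "strata": [dict(s) for s in cfg["strata"]]}
    for section, allowed in _SCHEMA.items():
        if allowed is None:
            continue
        given = cfg.get(section, {})
        bad = set(given) - allowed
        if bad:
            raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
        merged = dict(_DEFAULTS[section])
        merged.update(given)
        out[section] = merged
    return out


def stage_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (root_seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _centered(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    e = rng.normal(0.0, sd, n) if n > 1 and sd > 0 else np.zeros(n)
    return e - e.mean()


def _simulate_stratum(stratum: dict, trial_cfg: dict, seed: int):
    """One stratum's layout, yield table and genotype truth."""
    layout = synthetic.generate_layout(
        n_blocks=int(stratum.get("n_blocks", trial_cfg["n_blocks"])),
        block_shape=tuple(trial_cfg["block_shape"]),
        seed=seed,
        n_test_genotypes=trial_cfg["n_test_genotypes"],
        location_label=stratum["location"],
        spacing_label=str(stratum["spacing"]),
    )
    rng = np.random.default_rng(seed + 1)
    genotypes = sorted({p.genotype_id for p in layout.plots})
    # each genotype's true peak LAI drives its yield through the quadratic
    # yield-LAI response whose vertex is the ground-truth optimum
    true_lai = {g: float(rng.normal(trial_cfg["lai_mean"], trial_cfg["lai_sd"]))
                for g in genotypes}
    vertex, curv = trial_cfg["lai_vertex"], trial_cfg["lai_curvature"]
    effects = {g: -curv * (true_lai[g] - vertex) ** 2 for g in genotypes}
    bg_rows, bg_cols = layout.block_grid
    truth = synthetic.TrialTruth(
        genotype_effects=effects,
        row_effects=_centered(rng, bg_rows, trial_cfg["row_effect_sd"]),
        col_effects=_centered(rng, bg_cols, trial_cfg["col_effect_sd"]),
        grand_mean=trial_cfg["grand_mean_yield"],
        noise_sd=trial_cfg["yield_noise_sd"],
        effect_scale="block",
    )
    table = synthetic.simulate_trial(layout, truth, seed=seed + 2)
    return layout, table, true_lai, truth


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = cfg["seed"]
    report: dict = {"config": cfg, "stages": {}, "recovery": {}}

    try:
        # --- simulate + adjust -------------------------------------------
        yield_tables, summaries_all, decisions_json = [], [], {}
        truth_lai_frames = []
        for i, stratum in enumerate(cfg["strata"]):
            key = f"{stratum['location']}_{stratum['spacing']}"
            s_seed = stage_seed(root, f"simulate/{key}")
            layout, table, true_lai, _truth = _simulate_stratum(
                stratum, cfg["trial"], s_seed
            )
            yield_tables.append(table)
            log.info("stratum %s: %d plots simulated", key, len(table))

            # time courses: LAI peaks scale with each genotype's true value
            tc = cfg["timecourse"]
            params = synthetic.CurveParams(
                family="rise_plateau_decline", asymptote=cfg["trial"]["lai_mean"],
                midpoint_day=45.0, rate=0.22, decline_onset_day=80.0,
                decline_rate=0.05 * cfg["trial"]["lai_mean"],
                noise_sd=tc["noise_sd"], trait="LAI",
            )
            series, _curve_truth = synthetic.simulate_timecourse(
                layout, params, tc["sampling_days"],
                seed=stage_seed(root, f"timecourse/{key}"),
                asymptote_by_genotype=true_lai,
            )
            summ = timecourse.summarize_table(
                series, model="auto", lowess_frac=tc["lowess_frac"]
            )
            summ["stratum"] = key
            summaries_all.append(summ)
            truth_lai_frames.append(pd.DataFrame({
                "genotype_id": list(true_lai), "true_peak_lai": list(true_lai.values()),
                "stratum": key,
            }))

        yields = pd.concat(yield_tables, ignore_index=True)
        io.write_plot_table(yields, out / "yield_raw.csv")
        adjusted, decisions = mad.adjust_by_stratum(
            yields, per_block_reference=cfg["adjustment"]["per_block_reference"]
        )
        io.write_plot_table(adjusted, out / "yield_adjusted.csv")
        for key, dec in decisions.items():
            decisions_json["_".join(map(str, key))] = {
                "chosen": dec.chosen,
                "re_method1": dec.re_method1,
                "re_method3": dec.re_method3,
                "iwp_original": dec.iwp_original,
            }
        report["stages"]["adjust"] = decisions_json

        summaries = pd.concat(summaries_all, ignore_index=True)
        summaries.to_csv(out / "trait_summaries.csv", index=False)
        pd.concat(truth_lai_frames, ignore_index=True).to_csv(
            out / "truth_peak_lai.csv", index=False
        )
        report["stages"]["traits"] = {
            "n_series": int(len(summaries)),
            "models_used": summaries["model_used"].value_counts().to_dict(),
        }

        # --- image indices ------------------------------------------------
        im = cfg["imaging"]
        rng = np.random.default_rng(stage_seed(root, "imaging"))
        cov_rows = []
        for k in range(int(im["n_images"])):
            frac = float(rng.uniform(0.2, 0.9))
            img, mask = synthetic.simulate_plot_image(
                frac, tuple(im["image_shape"]),
                seed=stage_seed(root, f"imaging/{k}"), noise_sd=im["noise_sd"],
            )
            idx = imaging.plot_indices(img)
            cov_rows.append({
                "image": k, "requested_pct": 100 * frac,
                "truth_pct": 100 * mask.mean(),
                "estimated_pct": idx["canopy_coverage"], "ndvi_mean": idx["ndvi"],
            })
        cov = pd.DataFrame(cov_rows)
        cov.to_csv(out / "coverage_ndvi.csv", index=False)
        report["stages"]["indices"] = {
            "max_abs_coverage_error_pct":
                float((cov["estimated_pct"] - cov["truth_pct"]).abs().max()),
        }

        # --- voxel biomass -------------------------------------------------
        bm = cfg["biomass"]
        bm_rows = []
        for k in range(int(bm["n_clouds"])):
            cloud = synthetic.simulate_point_cloud(
                footprint_m=(2.0, 1.0), height_m=bm["height_m"],
                points_per_m3=bm["points_per_m3"],
                seed=stage_seed(root, f"biomass/{k}"),
            )
            bm_rows.append({
                "cloud": k,
                "digital_biomass_m3_per_m2":
                    imaging.digital_biomass(cloud, bm["voxel_size"]),
                "analytic_m3_per_m2": bm["height_m"],
            })
        pd.DataFrame(bm_rows).to_csv(out / "digital_biomass.csv", index=False)
        report["stages"]["biomass"] = bm_rows

        # --- A-Ci ----------------------------------------------------------
        from canopytrial import aci as aci_mod

        ac = cfg["aci"]
        aci_rows = []
        for k in range(int(ac["n_curves"])):
            curve = synthetic.simulate_aci_curve(
                ac["vcmax25"], ac["jmax25"], ac["rd25"],
                noise_sd=ac["noise_sd"], tleaf_c=ac["tleaf_c"],
                seed=stage_seed(root, f"aci/{k}"), curve_id=f"curve{k}",
            )
            fit = aci_mod.fit_aci(curve, seed=stage_seed(root, f"acifit/{k}"))
            aci_rows.append({
                "curve_id": curve.curve_id, "vcmax25": fit.vcmax25,
                "jmax25": fit.jmax25, "rd25": fit.rd25,
                "rss": fit.rss, "converged": fit.converged,
            })
        pd.DataFrame(aci_rows).to_csv(out / "aci_fits.csv", index=False)
        report["stages"]["aci"] = {
            "true": {"vcmax25": ac["vcmax25"], "jmax25": ac["jmax25"],
                     "rd25": ac["rd25"]},
            "fits": aci_rows,
        }

        # --- LAI-yield optimum --------------------------------------------
        test = adjusted[adjusted["role"] == "test"].copy()
        peaks = summaries[summaries["trait"] == "LAI"][["plot_id", "peak_value"]]
        merged = test.merge(peaks, on="plot_id", how="inner")
        merged["stratum"] = merged["location"] + "_" + merged["spacing"].astype(str)
        opt = optimum.optimum_by_stratum(
            merged.rename(columns={"peak_value": "peak_lai", "value": "yield"}),
            lai_col="peak_lai", yield_col="yield", stratum_col="stratum",
        )
        report["stages"]["optimum"] = opt
        report["recovery"] = {
            "true_optimal_lai": cfg["trial"]["lai_vertex"],
            "estimated_optimal_lai": {
                r["stratum"]: r["optimal_lai"] for r in opt
            },
            "true_biomass_m3_per_m2": bm["height_m"],
            "aci_relative_error_pct": {
                r["curve_id"]: 100.0 * (r["vcmax25"] / ac["vcmax25"] - 1.0)
                for r in aci_rows
            },
        }
    except ConfigError:
        raise
    except Exception as exc:  # partial report with the failed stage marked
        report["failed_stage"] = repr(exc)
        _write_report(report, out)
        raise

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
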