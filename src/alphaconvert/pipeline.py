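"""End-to-end orchestration: cohort -> behavior -> spectral -> maps -> predict.

Every stage draws its seed deterministically from the master seed, writes
its outputs under the run directory, and records content hashes in
``manifest.json`` so a rerun with the same configuration reproduces
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, io, maps, predict, spectral, synthgen
from .config import RunConfig
from .exceptions import ConfigError

log = logging.getLogger("alphaconvert")

TASK_SHORT = {"encoding": "enc", "memory": "ret"}
VOLUME_COLS = ("hippocampus_L", "hippocampus_R", "amygdala_L", "amygdala_R")


def _stage_seeds(master: int, n: int = 8):
    return [int(s % (2**31)) for s in np.random.SeedSequence(master).generate_state(n)]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_feature_table(cohort, stat_maps: dict, radius_voxels: float = 3.0) -> pd.DataFrame:
    """Candidate-predictor table for the aMCI subjects.

    ERD features come from sphere-clustering each significant group-contrast
    map; MRI volumes and ICV come straight from the subject records; the
    label marks converters.
    """
    subj = cohort.subjects.set_index("subject_id")
    table = subj.loc[subj["group"].isin(["aMCI-s", "aMCI-c"])].copy()
    for (band, task), stat in stat_maps.items():
        feats, _ = maps.sphere_cluster(stat, cohort.maps[(band, task)], radius_voxels)
        feats = feats.rename(
            columns={c: f"{band}_{TASK_SHORT[task]}_{c}" for c in feats.columns}
        )
        table = table.join(feats, how="left")
    table["converter"] = (table["group"] == "aMCI-c").astype(int)
    return table


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stage = "synthgen"
    try:
        # --- cohort -------------------------------------------------------
        cohort = synthgen.generate_cohort(config.cohort, seed=seeds[0])
        io.save_cohort(cohort, out / "cohort")

        # --- behavior -----------------------------------------------------
        stage = "behavior"
        scores = behavior.score_cohort(cohort.trials)
        scores = scores.merge(cohort.subjects[["subject_id", "group", "age", "icv"]], on="subject_id")
        scores.to_csv(out / "scores.csv", index=False)
        glm_assoc = behavior.group_glm(
            scores[["d_scf", "d_sif"]].to_numpy(),
            scores["group"].to_numpy(),
            within=("SCF", "SIF"),
            nuisance=scores[["age"]].to_numpy(),
        )
        subj = cohort.subjects
        glm_vols = {}
        for region in ("hippocampus", "amygdala"):
            glm_vols[region] = behavior.group_glm(
                subj[[f"{region}_L", f"{region}_R"]].to_numpy(),
                subj["group"].to_numpy(),
                within=("L", "R"),
                nuisance=subj[["age", "icv"]].to_numpy(),
            )
        (out / "behavior_stats.json").write_text(
            json.dumps(_jsonable({"memory_ancova": glm_assoc, "volume_ancovas": glm_vols}), indent=1)
        )

        # --- spectral demo ------------------------------------------------
        stage = "spectral"
        demo_rows = []
        rng = np.random.default_rng(seeds[1])
        picked = (
            cohort.subjects.groupby("group", sort=False)
            .head(1)
            .head(config.spectral_demo_subjects)
        )
        freqs = np.arange(6.0, 12.25, 0.25)
        for _, row in picked.iterrows():
            erd_target = config.cohort.erd_effect[("alpha", "encoding")]["l_pcc"][row["group"]][0]
            att = 1.0 - np.sqrt(1.0 + erd_target / 100.0)
            ep = synthgen.make_epochs(
                task="encoding",
                n_trials=20,
                channels=synthgen.CHANNELS_59[: config.spectral_demo_channels],
                sampling_rate=config.cohort.sampling_rate,
                noise_sd=0.4,
                rng=rng,
            )
            ep = synthgen.plant_oscillation(ep, 8.5, att, (0.0, 1000.0), amplitude=3.0, rng=rng)
            ep = spectral.common_average_reference(ep)
            tfr = spectral.morlet_tfr(ep, freqs)
            grid = spectral.erd(tfr, spectral.BaselineWindow(*spectral.BASELINE_WINDOWS_MS["encoding"]))
            measured = spectral.band_window_mean(grid, 8.5, (500.0, 1000.0))
            demo_rows.append(
                {"subject_id": row["subject_id"], "group": row["group"],
                 "planted_erd_pct": erd_target, "measured_erd_pct": measured}
            )
        pd.DataFrame(demo_rows).to_csv(out / "spectral_demo.csv", index=False)

        # --- maps ---------------------------------------------------------
        stage = "maps"
        stat_maps = {}
        cluster_summary = {}
        for i, key in enumerate(cohort.maps):
            stat = maps.cluster_permutation(
                cohort.maps[key],
                group_a="aMCI-s",
                group_b="aMCI-c",
                threshold_p=config.cluster_threshold_p,
                n_perm=config.cluster_n_perm,
                seed=seeds[2] + i,
            )
            stat_maps[key] = stat
            cluster_summary["{}_{}".format(*key)] = [
                {"mass": c.mass, "p_cluster": c.p_cluster, "sign": c.sign, "n_voxels": len(c.voxels)}
                for c in stat.clusters[:5]
            ]
        alpha_enc = cohort.maps[("alpha", "encoding")]
        pls = maps.task_pls(
            alpha_enc.values.reshape(len(cohort.subjects), -1),
            cohort.subjects["group"].to_numpy(),
            n_perm=config.pls_n_perm,
            n_boot=config.pls_n_boot,
            seed=seeds[3],
        )
        (out / "maps_stats.json").write_text(
            json.dumps(
                _jsonable(
                    {
                        "clusters": cluster_summary,
                        "task_pls_alpha_encoding": {
                            "singular_values": pls.singular_values[:3],
                            "perm_p": pls.perm_p[:3],
                        },
                    }
                ),
                indent=1,
            )
        )
        features = build_feature_table(cohort, stat_maps)
        features.to_csv(out / "features.csv")

        # --- predict ------------------------------------------------------
        stage = "predict"
        report = _predict_stage(features, config, seeds[4])
        (out / "predict_report.json").write_text(json.dumps(_jsonable(report), indent=1))
        rows = []
        for name, r in report["models"].items():
            cv = r["cv"]
            rows.append(
                {
                    "classifier": name,
                    "predictors": "+".join(r["predictors"]),
                    "auc": round(cv["mean_auc"], 3),
                    "auc_ci_low": round(cv["auc_ci"][0], 3),
                    "auc_ci_high": round(cv["auc_ci"][1], 3),
                    "acc_pct": round(100 * cv["mean_accuracy"], 1),
                    "se_pct": round(100 * cv["mean_sensitivity"], 1),
                    "sp_pct": round(100 * cv["mean_specificity"], 1),
                    "perm_p": round(r["perm_p"], 4),
                }
            )
        pd.DataFrame(rows).to_csv(out / "model_comparison.csv", index=False)

        # --- manifest -----------------------------------------------------
        stage = "manifest"
        files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": _jsonable(config),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "hashes": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except ConfigError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _predict_stage(features: pd.DataFrame, config: RunConfig, seed: int) -> dict:
    """Stepwise single-modality models, surviving combinations, CV + permutation."""
    erd_cols = {
        key: [c for c in features.columns if c.startswith(f"{key}_")]
        for key in ("alpha_enc", "alpha_ret", "beta_enc", "beta_ret")
    }
    models: dict[str, dict] = {}

    mri = predict.stepwise_lr(
        features, list(VOLUME_COLS), nuisance=["icv"],
        entry_p=config.entry_p, removal_p=config.removal_p,
    )
    if mri.selected:
        models["mri"] = {"predictors": mri.selected, "nuisance": ["icv"], "lr_chi2": mri.lr_chi2, "p": mri.p}
    eeg_selected = {}
    for key, cols in erd_cols.items():
        if not cols:
            continue
        m = predict.stepwise_lr(
            features, cols, nuisance=[], entry_p=config.entry_p, removal_p=config.removal_p
        )
        if m.selected:
            models[key] = {"predictors": m.selected, "nuisance": [], "lr_chi2": m.lr_chi2, "p": m.p}
            eeg_selected[key] = m.selected

    out = {"models": {}}
    for i, (name, spec_) in enumerate(models.items()):
        cv = predict.cv_leave10out(
            features, spec_["predictors"], spec_["nuisance"], n_rounds=config.cv_rounds, seed=seed + i
        )
        perm = predict.permutation_test(
            features, spec_["predictors"], spec_["nuisance"],
            n_perm=config.predict_n_perm, n_rounds=config.cv_rounds, seed=seed + i,
        )
        spec_["cv"] = {
            "mean_auc": cv.mean_auc, "auc_ci": cv.auc_ci, "mean_accuracy": cv.mean_accuracy,
            "mean_sensitivity": cv.mean_sensitivity, "mean_specificity": cv.mean_specificity,
        }
        spec_["_cv_obj"] = cv
        spec_["perm_p"] = perm.p
        spec_["perm_q95"] = perm.q95
        out["models"][name] = spec_

    # combine each surviving MRI volume with each EEG predictor that beat its null
    combos = []
    if "mri" in out["models"]:
        for key, sel in eeg_selected.items():
            if out["models"][key]["perm_p"] < 0.05:
                combos.append((key, sel))
    for j, (key, sel) in enumerate(combos):
        name = f"mri+{key}"
        predictors = out["models"]["mri"]["predictors"] + sel
        cv = predict.cv_leave10out(features, predictors, ["icv"], n_rounds=config.cv_rounds, seed=seed + 100 + j)
        perm = predict.permutation_test(
            features, predictors, ["icv"], n_perm=config.predict_n_perm,
            n_rounds=config.cv_rounds, seed=seed + 100 + j,
        )
        entry = {
            "predictors": predictors,
            "nuisance": ["icv"],
            "cv": {
                "mean_auc": cv.mean_auc, "auc_ci": cv.auc_ci, "mean_accuracy": cv.mean_accuracy,
                "mean_sensitivity": cv.mean_sensitivity, "mean_specificity": cv.mean_specificity,
            },
            "perm_p": perm.p,
            "perm_q95": perm.q95,
            "_cv_obj": cv,
        }
        if len(predictors) > 1:
            rw = predict.relative_weights(features, predictors, n_boot=config.rw_n_boot, seed=seed + 200 + j)
            entry["relative_weights_pct"] = rw.percent
            entry["relative_weights_ci"] = rw.ci_percent
        out["models"][name] = entry

    if len(out["models"]) >= 2:
        cv_objs = {n: m["_cv_obj"] for n, m in out["models"].items()}
        comp = predict.compare_models(cv_objs, metrics=("auc", "accuracy"))
        out["comparison"] = {
            metric: {
                "friedman": res["friedman"],
                "pairwise": {f"{a} vs {b}": v for (a, b), v in res["pairwise"].items()},
            }
            for metric, res in comp.items()
        }
    for m in out["models"].values():
        m.pop("_cv_obj", None)
    return out


def render_report(run_dir) -> str:
    """Deterministic plain-text summary of a completed run."""
    run = Path(run_dir)
    lines = ["alphaconvert run report", "=" * 40, ""]

    subj_path = run / "cohort" / "subjects.csv"
    if not subj_path.exists():
        raise FileNotFoundError(f"incomplete run: missing stage output {subj_path}")
    subjects = pd.read_csv(subj_path)
    lines.append("Cohort summary (mean ± SD)")
    lines.append("-" * 40)
    fields = [c for c in subjects.columns if subjects[c].dtype.kind == "f"]
    groups = list(dict.fromkeys(subjects["group"]))
    header = "field".ljust(22) + "".join(g.rjust(20) for g in groups)
    lines.append(header)
    for f in fields:
        row = f.ljust(22)
        for g in groups:
            v = subjects.loc[subjects["group"] == g, f]
            row += f"{v.mean():.1f} ± {v.std():.1f}".rjust(20)
        lines.append(row)
    counts = "n".ljust(22) + "".join(
        str((subjects["group"] == g).sum()).rjust(20) for g in groups
    )
    lines.append(counts)
    lines.append("")

    pred_path = run / "predict_report.json"
    lines.append("Prediction models (cross-validated)")
    lines.append("-" * 40)
    if pred_path.exists():
        report = json.loads(pred_path.read_text())
        lines.append(
            "classifier".ljust(18) + "AUC (CI)".ljust(22) + "ACC%".rjust(7)
            + "SE%".rjust(7) + "SP%".rjust(7) + "perm p".rjust(9)
        )
        for name, m in report["models"].items():
            cv = m["cv"]
            ci = f"{cv['mean_auc']:.2f} ({cv['auc_ci'][0]:.2f}-{cv['auc_ci'][1]:.2f})"
            lines.append(
                name.ljust(18) + ci.ljust(22)
                + f"{100 * cv['mean_accuracy']:.1f}".rjust(7)
                + f"{100 * cv['mean_sensitivity']:.1f}".rjust(7)
                + f"{100 * cv['mean_specificity']:.1f}".rjust(7)
                + f"{m['perm_p']:.4f}".rjust(9)
            )
            if "relative_weights_pct" in m:
                for pred_name, pct in m["relative_weights_pct"].items():
                    lo, hi = m["relative_weights_ci"][pred_name]
                    lines.append(f"    weight {pred_name}: {pct:.1f}% (BCa {lo:.1f}-{hi:.1f})")
    else:
        lines.append("not run")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
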