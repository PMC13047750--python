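"""End-to-end orchestration: simulate -> fit -> score -> associate -> growth.

Each stage is a plain function over DataFrames/CSV paths so the numbered
analysis drivers, the command-line interface and the test-suite all run the
same code.  A run manifest records config hash, seeds, package version and
stage outputs, so a rerun with the same manifest reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc_stats import metric_wide, param_performance_associations, test_retest
from .growth_models import ALL_METRICS, AGE_CENTER, ladder_table, run_trajectory_ladder
from .hier_fit import FitConfig, estimates_to_df, fit_wave
from .igt_task import sessions_from_csv, sessions_to_csv
from .pop_orl import ModelConfig
from .summary_scores import score_sessions
from .synthetic_cohort import CohortConfig, default_effect_maps, simulate_study

STAGES = ("simulate", "fit", "score", "associate", "growth")


def assemble_long_table(
    estimates: pd.DataFrame,
    scores: pd.DataFrame,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Long metric table for growth modelling: one row per
    subject x wave x metric, with age and covariates attached."""
    metrics = estimates.merge(scores, on=["subject_id", "wave"], how="outer")
    merged = metrics.merge(demographics, on=["subject_id", "wave"], how="inner")
    merged["age_c"] = merged["age"] - AGE_CENTER
    rows = []
    for metric in ALL_METRICS:
        if metric not in merged:
            continue
        sub = merged[["subject_id", "wave", "age_c", "maternal_hx", "sex",
                      "iq", "onsite"]].copy()
        if "internalizing" in merged:
            sub["internalizing"] = merged["internalizing"]
        sub["metric_name"] = metric
        sub["value"] = merged[metric].to_numpy()
        rows.append(sub.dropna(subset=["value"]))
    return pd.concat(rows, ignore_index=True)


def fit_all_waves(sessions, fit_config: FitConfig = FitConfig(),
                  model_config: ModelConfig = ModelConfig()) -> pd.DataFrame:
    """Hierarchical model fit run separately at each assessment wave."""
    by_wave: dict[int, list] = {}
    for s in sessions:
        by_wave.setdefault(s.wave, []).append(s)
    frames = []
    for wave in sorted(by_wave):
        estimates, _ = fit_wave(by_wave[wave], fit_config, model_config)
        frames.append(estimates_to_df(estimates))
    return pd.concat(frames, ignore_index=True)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
    fit_config: FitConfig = FitConfig(),
    model_config: ModelConfig = ModelConfig(),
    resume: str | None = None,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the full pipeline into ``outdir`` and return the manifest.

    ``resume`` names the first stage to run; earlier stages must have left
    their outputs in ``outdir`` (a missing input raises with the file name).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_config = cohort_config or CohortConfig()
    if resume:
        if resume not in STAGES:
            raise ValueError(f"unknown stage {resume!r}")
        stages = STAGES[STAGES.index(resume):]

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash({
            "cohort": asdict(cohort_config) | {
                "effect_maps": {
                    k: asdict(v)
                    for k, v in (cohort_config.effect_maps
                                 or default_effect_maps()).items()
                }
            },
            "fit": asdict(fit_config),
            "model": asdict(model_config),
        }),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _need(path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage input {path} is missing; run the producing stage first"
            )
        return path

    sessions_csv = outdir / "sessions.csv"
    demo_csv = outdir / "demographics.csv"
    truth_csv = outdir / "ground_truth.csv"
    estimates_csv = outdir / "estimates.csv"
    scores_csv = outdir / "scores.csv"

    if "simulate" in stages:
        sessions, demographics, truth = simulate_study(
            cohort_config, None, model_config, seed
        )
        sessions_to_csv(sessions, sessions_csv)
        demographics.to_csv(demo_csv, index=False)
        truth.to_csv(truth_csv, index=False)
        manifest["stages"]["simulate"] = {
            "sessions": str(sessions_csv), "n_sessions": len(sessions),
        }
    if "fit" in stages:
        sessions = sessions_from_csv(_need(sessions_csv))
        estimates = fit_all_waves(sessions, fit_config, model_config)
        estimates.to_csv(estimates_csv, index=False)
        manifest["stages"]["fit"] = {"estimates": str(estimates_csv),
                                     "backend": fit_config.backend}
    if "score" in stages:
        sessions = sessions_from_csv(_need(sessions_csv))
        scores = score_sessions(sessions)
        scores.to_csv(scores_csv, index=False)
        manifest["stages"]["score"] = {"scores": str(scores_csv)}
    if "associate" in stages:
        estimates = pd.read_csv(_need(estimates_csv))
        scores = pd.read_csv(_need(scores_csv))
        assoc = param_performance_associations(estimates, scores)
        assoc.to_csv(outdir / "associations.csv", index=False)
        demographics = pd.read_csv(_need(demo_csv))
        long_df = assemble_long_table(estimates, scores, demographics)
        reliability = []
        for metric in ALL_METRICS:
            rel = test_retest(metric_wide(long_df, metric))
            rel.insert(0, "metric", metric)
            reliability.append(rel)
        pd.concat(reliability, ignore_index=True).to_csv(
            outdir / "test_retest.csv", index=False
        )
        manifest["stages"]["associate"] = {
            "associations": str(outdir / "associations.csv"),
            "test_retest": str(outdir / "test_retest.csv"),
        }
    if "growth" in stages:
        estimates = pd.read_csv(_need(estimates_csv))
        scores = pd.read_csv(_need(scores_csv))
        demographics = pd.read_csv(_need(demo_csv))
        long_df = assemble_long_table(estimates, scores, demographics)
        if long_df["wave"].nunique() < 2:
            raise ValueError(
                "growth stage needs >= 2 waves of data; "
                f"found {long_df['wave'].nunique()}"
            )
        ladders = run_trajectory_ladder(long_df)
        table = ladder_table(ladders)
        table.to_csv(outdir / "growth_models.csv", index=False)
        report = {
            m: {
                "winner": lad.winner,
                "age_coef": float(lad.model4.fixed.loc["age", "coef"]),
                "age_p": lad.age_p,
                "age_fdr": lad.age_fdr,
                "hx_coef": float(lad.model4.fixed.loc["maternal_hx", "coef"]),
                "icc": lad.icc,
                "pseudo_r2_total": lad.model4.pseudo_r2_total,
            }
            for m, lad in ladders.items()
        }
        with open(outdir / "growth_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest["stages"]["growth"] = {
            "table": str(outdir / "growth_models.csv"),
            "report": str(outdir / "growth_report.json"),
        }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
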