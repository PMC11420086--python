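"""Config-driven end-to-end runner and report assembly.

Stages run in dependency order: read/simulate → trajectories → burden/usage →
association fits → mediation → report. Every run directory receives the
output tables plus a ``manifest.json`` recording package/library versions, the
seed, row counts and content hashes, so reruns are verifiable. A stage
failure aborts with the stage name; outputs written so far are kept.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .analyses import (
    burden_hierarchy_fit,
    burden_on_sud_fit,
    burden_pgs_fit,
    mediation_fit,
    progression_cox_fit,
    progression_logistic_fit,
    progression_sex_fit,
    sud_exclusion_fit,
    sud_logistic_fit,
)
from .association import SeparationError, standardized_pgs_frame, pgs_strata
from .burden import cohort_burden, cohort_usage, group_burden_curve
from .hierarchy import TRAJECTORY_COLUMNS, progression_cohort, summarize_trajectories
from .registry import MajorClass, RegistryBundle, read_bundle, write_bundle
from .simulate import preset_paper_defaults, simulate_cohort

logger = logging.getLogger(__name__)

ANALYSIS_STAGES = ("progression", "burden", "usage", "curves", "mediation")


class AnalysisConfig(BaseModel):
    """Full description of a pipeline run."""

    input_dir: Optional[str] = None         # registry tables on disk …
    preset: Optional[str] = None            # … or a named generator preset
    n_persons: int = 10_000
    seed: int = 0
    analyses: list[Literal["progression", "burden", "usage", "curves", "mediation"]] = Field(
        default_factory=lambda: ["progression", "burden", "usage", "curves", "mediation"]
    )
    pgs_traits: list[str] = Field(default_factory=lambda: ["sz", "ea", "mdd"])
    time_origin: Literal["first_major", "onset"] = "first_major"
    min_observed_years: int = 3             # burden-regression inclusion floor
    bootstrap_reps: int = 1000
    output_dir: str = "psycourse-run"

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if (self.input_dir is None) == (self.preset is None):
            raise ValueError("exactly one of input_dir or preset must be set")
        if "mediation" in self.analyses and "burden" not in self.analyses:
            raise ValueError("mediation requires the burden stage to be enabled")
        if "curves" in self.analyses and "burden" not in self.analyses:
            raise ValueError("curves require the burden stage to be enabled")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_or_simulate(config: AnalysisConfig) -> RegistryBundle:
    if config.input_dir is not None:
        return read_bundle(config.input_dir)
    preset = preset_paper_defaults(config.preset, n_persons=config.n_persons, seed=config.seed)
    bundle, _ = simulate_cohort(preset)
    return bundle


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "psycourse_version": __version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "outputs": {},
        "stages": [],
    }
    fits_rows: list[dict] = []
    stage = "input"
    try:
        bundle = load_or_simulate(config)
        manifest["n_persons"] = bundle.n_persons

        stage = "trajectories"
        traj = summarize_trajectories(bundle, time_origin=config.time_origin)
        _write(out, "trajectories.csv", traj[TRAJECTORY_COLUMNS], manifest)
        labelled, counts = progression_cohort(traj)
        manifest["progression_counts"] = counts
        tj = traj.set_index("person_id")
        sz_ids = tj.index[tj["main_lifetime"] == MajorClass.SZ.value]

        burden_table = None
        if "burden" in config.analyses:
            stage = "burden"
            burden_table = cohort_burden(bundle, traj)
            excluded_short = int((burden_table["observed_years"] < config.min_observed_years).sum())
            logger.info("burden: %d persons below min_observed_years=%d excluded from regressions",
                        excluded_short, config.min_observed_years)
            manifest["burden_excluded_short_followup"] = excluded_short
            _write(out, "burden.csv", burden_table, manifest)

        if "usage" in config.analyses:
            stage = "usage"
            usage_table = cohort_usage(bundle, traj)
            _write(out, "usage.csv", usage_table, manifest)

        if "progression" in config.analyses:
            stage = "progression-fits"
            for name, fn in (
                ("progression_logistic_szpgs", progression_logistic_fit),
                ("progression_cox_szpgs", lambda b: progression_cox_fit(b, time_origin=config.time_origin)),
                ("progression_sex", progression_sex_fit),
            ):
                _try_fit(fits_rows, name, fn, bundle)

        if "burden" in config.analyses:
            stage = "burden-fits"
            _try_fit(fits_rows, "burden_hierarchy_sz_vs_lower", burden_hierarchy_fit, bundle)
            for trait in config.pgs_traits:
                _try_fit(
                    fits_rows, f"burden_{trait}pgs_in_sz",
                    lambda b, t=trait: burden_pgs_fit(b, trait=t), bundle,
                )
            _try_fit(fits_rows, "sud_eapgs_or", sud_logistic_fit, bundle)
            _try_fit(fits_rows, "burden_on_sud", burden_on_sud_fit, bundle)

        if "curves" in config.analyses:
            stage = "curves"
            groups = tj["main_lifetime"].rename("group")
            curve = group_burden_curve(burden_table, groups)
            pgs = standardized_pgs_frame(bundle.persons)
            strata = pd.Series(
                pgs_strata(pgs["sz"]), index=pgs.index, name="group"
            ).reindex(sz_ids)
            strata_curve = group_burden_curve(burden_table, strata)
            strata_curve["group"] = "szpgs_" + strata_curve["group"].astype(str)
            _write(out, "curves.csv", pd.concat([curve, strata_curve], ignore_index=True), manifest)

        if "mediation" in config.analyses:
            stage = "mediation"
            med = mediation_fit(bundle, bootstrap_reps=config.bootstrap_reps, seed=config.seed)
            excl = sud_exclusion_fit(bundle)
            report = {
                "a": med.a, "b": med.b, "direct": med.direct,
                "indirect": med.indirect, "total": med.total,
                "ci": {k: list(v) for k, v in med.bootstrap_ci.items()},
                "n": med.n, "reps": med.reps, "seed": med.seed,
                "sud_exclusion": excl.as_row("sud_exclusion"),
            }
            path = out / "mediation.json"
            path.write_text(json.dumps(report, indent=2) + "\n")
            manifest["outputs"]["mediation.json"] = {"sha256": _sha256(path)}

        stage = "report"
        fits = pd.DataFrame(
            fits_rows,
            columns=["analysis_id", "term", "model", "estimate", "effect", "ci_low", "ci_high", "p", "n"],
        )
        _write(out, "fits.csv", fits, manifest)
        manifest["stages"] = ["input", "trajectories"] + [a for a in config.analyses] + ["report"]
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _write(out: Path, name: str, df: pd.DataFrame, manifest: dict) -> None:
    path = out / name
    df.to_csv(path, index=False)
    manifest["outputs"][name] = {"rows": int(len(df)), "sha256": _sha256(path)}


def _try_fit(rows: list[dict], analysis_id: str, fn, bundle: RegistryBundle) -> None:
    try:
        res = fn(bundle)
        rows.append(res.as_row(analysis_id))
    except (ValueError, SeparationError) as exc:
        logger.warning("fit %s skipped: %s", analysis_id, exc)


def simulate_to_dir(preset_name: str, n_persons: int, seed: int, directory: str | Path) -> dict:
    """Simulate a preset cohort and write registry tables plus truth.json."""
    preset = preset_paper_defaults(preset_name, n_persons=n_persons, seed=seed)
    bundle, truth = simulate_cohort(preset)
    paths = write_bundle(bundle, directory)
    tpath = Path(directory) / "truth.json"
    tpath.write_text(
        json.dumps(
            {
                "preset": preset.model_dump(mode="json"),
                "clip_rates": truth.clip_rates,
                "n_persons": bundle.n_persons,
            },
            indent=2, default=str,
        )
        + "\n"
    )
    truth.frame.to_csv(Path(directory) / "truth.csv", index=False)
    return {k: str(v) for k, v in paths.items()}
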