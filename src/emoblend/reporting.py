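"""Pipeline orchestration and table rendering.

``run_pipeline`` drives the full analysis from a :class:`PipelineConfig`
(either an input CSV or simulation parameters), writes the report tables in
stable layouts, and records a machine-readable manifest (config, seed,
version) from which every rendered number is recomputable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .data_model import PROPORTIONS
from .study import BlendedEmotionStudy, StudyResults
from .synthetic_raters import RaterModelParams, params_from_config


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run.

    Exactly one of ``input_path`` and ``simulation`` must be set.
    ``simulation`` holds rater-model keys (gain, sigma, tau, kernel, ...)
    plus ``n_participants`` and ``n_actors``.
    """

    input_path: str | None = None
    simulation: Mapping | None = None
    mode: str = "forced2"
    ci_method: str = "wald"
    strict_policy: str = "superset"
    chance_reference: str = "fixed2"
    out_dir: str = "emoblend_out"
    seed: int | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_path and simulation must be set"
            )


#: Stable file names for the report bundle.
TABLE_FILES = {
    "cell_means": "cell_mean_ratings.csv",
    "anovas": "anova_summaries.csv",
    "accuracy": "accuracy.csv",
    "accuracy_wide": "accuracy_table.csv",
    "target_contrasts": "target_contrasts.csv",
    "order_tests": "order_tests.csv",
    "chance_levels": "chance_levels.csv",
    "scale_usage": "scale_usage.csv",
    "manifest": "manifest.json",
}


def _round_df(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(decimals)
    return out


def render_accuracy_table(accuracy: pd.DataFrame, fmt: str = "frame"):
    """Wide accuracy layout: one row per combination x proportion.

    Columns: very-strict / strict / generous means with 95% CIs; the
    very-strict columns are NA for the equal-proportion rows.  Rows ordered
    combination-alphabetical x proportion (30:70, 50:50, 70:30).

    ``fmt``: ``'frame'`` (DataFrame, full precision), ``'csv'`` or
    ``'markdown'`` (strings, 2-decimal display rounding).
    """
    if accuracy.empty:
        raise ValueError("no accuracy results to render")
    rows = []
    combos = sorted(accuracy["combination"].unique())
    for combo in combos:
        for prop in PROPORTIONS:
            row: dict[str, object] = {"combination": combo, "proportion": prop}
            for index in ("very_strict", "strict", "generous"):
                sub = accuracy[
                    (accuracy["index"] == index)
                    & (accuracy["combination"] == combo)
                    & (accuracy["proportion"] == prop)
                ]
                if sub.empty:
                    row[index] = math.nan
                    row[f"{index}_ci_low"] = math.nan
                    row[f"{index}_ci_high"] = math.nan
                else:
                    r = sub.iloc[0]
                    row[index] = r["mean"]
                    row[f"{index}_ci_low"] = r["ci_low"]
                    row[f"{index}_ci_high"] = r["ci_high"]
            rows.append(row)
    wide = pd.DataFrame(rows)
    if fmt == "frame":
        return wide
    disp = _round_df(wide)
    if fmt == "csv":
        return disp.to_csv(index=False)
    if fmt == "markdown":
        return disp.to_markdown(index=False)
    raise ValueError(f"unknown format {fmt!r}")


def _write_tables(results: StudyResults, out: Path, cfg: PipelineConfig) -> list[Path]:
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / TABLE_FILES[name]
        df.to_csv(path, index=False)
        written.append(path)

    emit("cell_means", results.cell_means)
    emit("anovas", results.anovas)
    emit(
        "accuracy",
        pd.concat([results.overall_accuracy, results.accuracy], ignore_index=True),
    )
    emit("accuracy_wide", render_accuracy_table(results.accuracy))
    emit("target_contrasts", results.target_contrasts)
    emit("order_tests", results.order_tests)
    emit("chance_levels", results.chance_levels)
    if results.scale_usage is not None:
        usage = results.scale_usage
        emit(
            "scale_usage",
            pd.DataFrame(
                {
                    "k": list(usage["counts"]),
                    "count": list(usage["counts"].values()),
                    "percent": list(usage["percentages"].values()),
                }
            ).assign(mean_k=usage["mean"], sd_k=usage["sd"]),
        )
    return written


def run_pipeline(cfg: PipelineConfig) -> StudyResults:
    """Run the full analysis and write the report bundle to ``cfg.out_dir``.

    Stages: load-or-simulate -> validate -> fit -> render.  On failure the
    partially written tables are removed and a :class:`PipelineError` naming
    the stage is raised.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log = print if cfg.verbosity else (lambda *a, **k: None)

    try:
        stage = "load"
        if cfg.input_path is not None:
            study = BlendedEmotionStudy.from_csv(cfg.input_path, mode=cfg.mode)
        else:
            sim = dict(cfg.simulation or {})
            n_participants = int(sim.pop("n_participants", 40))
            n_actors = int(sim.pop("n_actors", 6))
            params = params_from_config(sim)
            study = BlendedEmotionStudy.from_simulation(
                params=params,
                n_participants=n_participants,
                n_actors=n_actors,
                mode=cfg.mode,
                seed=cfg.seed,
            )
        log(
            f"[load] {len(study.dataset)} responses, "
            f"{len(study.dataset.stimuli)} stimuli, mode={cfg.mode}"
        )

        stage = "fit"
        results = study.fit(
            ci_method=cfg.ci_method,
            strict_policy=cfg.strict_policy,
            chance_reference=cfg.chance_reference,
        )
        log(
            f"[fit] {len(results.accuracy)} accuracy cells, "
            f"{len(results.anovas)} ANOVAs, "
            f"{len(results.target_contrasts)} target contrasts, "
            f"{len(results.order_tests)} order tests"
        )

        stage = "render"
        written = _write_tables(results, out, cfg)
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "tables": {
                p.name: int(len(pd.read_csv(p))) for p in written
            },
        }
        manifest_path = out / TABLE_FILES["manifest"]
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        written.append(manifest_path)
        log(f"[render] wrote {len(written)} files to {out}")
        return results
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
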