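"""Command-line entry points, input validation, logging, result bundles.

Subcommands: ``simulate``, ``behavior``, ``glm``, ``network``,
``components``, ``run-all``, ``validate``. Every run writes a structured
log (text + JSON lines) that records the seed and every analysis
threshold in force (group criterion, search alpha, regression threshold,
censoring threshold, value percentile, high-pass cutoff, TR), and
serializes the full configuration into the results bundle so any output
can be regenerated exactly from config + seed. Exit codes: 0 ok, 1 user
error (bad inputs/flags), 2 internal error.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import components as components_mod
from . import roiglm, synth, usem
from .config import EXPLOSION_MAX, EXPLOSION_MIN, N_BALLOONS, N_ROIS, RunConfig, load_config

logger = logging.getLogger("dmnstab")


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------


class _JsonLineHandler(logging.Handler):
    def __init__(self, path: Path):
        super().__init__()
        self.path = path

    def emit(self, record: logging.LogRecord) -> None:
        entry = {
            "time": record.created,
            "level": record.levelname,
            "message": record.getMessage(),
        }
        extra = getattr(record, "payload", None)
        if extra:
            entry.update(extra)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, (_JsonLineHandler, logging.FileHandler))]
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.addHandler(_JsonLineHandler(out_dir / "run.jsonl"))


def log_stage(stage: str, seconds: float, **payload) -> None:
    logger.info(
        "stage=%s wall_time=%.2fs", stage, seconds, extra={"payload": {"stage": stage, "wall_time": seconds, **payload}}
    )


def log_thresholds(cfg: RunConfig) -> None:
    logger.info(
        "thresholds: group_criterion=%s search_alpha=%s regression_p=%s "
        "censor_mm=%s value_percentile=%s highpass_s=%s tr_s=%s seed=%s",
        cfg.group_criterion,
        cfg.search_alpha,
        cfg.regression_p_threshold,
        cfg.motion_censor_mm,
        cfg.value_percentile,
        cfg.highpass_cutoff_s,
        cfg.tr_seconds,
        cfg.seed,
        extra={
            "payload": {
                "group_criterion": cfg.group_criterion,
                "search_alpha": cfg.search_alpha,
                "regression_p_threshold": cfg.regression_p_threshold,
                "motion_censor_mm": cfg.motion_censor_mm,
                "value_percentile": cfg.value_percentile,
                "highpass_cutoff_s": cfg.highpass_cutoff_s,
                "tr_seconds": cfg.tr_seconds,
                "seed": cfg.seed,
            }
        },
    )


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    files_checked: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "files_checked": self.files_checked,
            "violations": self.violations,
        }


def _check_trials(path: Path, report: ValidationReport) -> None:
    df = pd.read_csv(path)
    required = ["subject", "balloon", "pumps", "outcome", "explosion_point"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.violations.append(f"{path.name}: missing columns {missing}")
        return
    for i, row in df.iterrows():
        line = f"{path.name}:{i + 2}"
        if row["pumps"] < 1:
            report.violations.append(f"{line}: pumps must be >= 1")
        if not 0 <= row["balloon"] < N_BALLOONS:
            report.violations.append(f"{line}: balloon outside 0-{N_BALLOONS - 1}")
        if row["outcome"] not in ("cash_out", "explosion"):
            report.violations.append(f"{line}: unknown outcome {row['outcome']!r}")
        if not EXPLOSION_MIN <= row["explosion_point"] <= EXPLOSION_MAX:
            report.violations.append(f"{line}: explosion_point outside 4-10")
        elif row["pumps"] > row["explosion_point"]:
            report.violations.append(f"{line}: pumps exceed explosion_point")


def _check_events(path: Path, report: ValidationReport) -> None:
    df = pd.read_csv(path, sep="\t")
    required = ["onset", "duration", "type", "pump_number"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.violations.append(f"{path.name}: missing columns {missing}")
        return
    if (df["onset"] < 0).any():
        report.violations.append(f"{path.name}: negative onsets")
    if not df["type"].isin(["pump", "cash_out", "explosion"]).all():
        report.violations.append(f"{path.name}: unknown event types")
    if (df["pump_number"] < 1).any():
        report.violations.append(f"{path.name}: pump_number must be >= 1")


def _check_series(path: Path, report: ValidationReport) -> None:
    df = pd.read_csv(path)
    if df.shape[1] != N_ROIS:
        report.violations.append(
            f"{path.name}: expected {N_ROIS} ROI columns, found {df.shape[1]}"
        )
    values = df.to_numpy(dtype=float)
    if np.isinf(values).any():
        report.violations.append(f"{path.name}: non-finite values")
    if len(df) < 20:
        report.violations.append(f"{path.name}: fewer than 20 volumes")


def validate_inputs(paths: list[str | Path]) -> ValidationReport:
    """Schema-check study input files; returns a machine-readable report."""
    report = ValidationReport()
    for raw in paths:
        path = Path(raw)
        if not path.exists():
            report.violations.append(f"{path}: file not found")
            continue
        report.files_checked.append(str(path))
        try:
            name = path.name
            if name.endswith(".tsv") or "events" in name:
                _check_events(path, report)
            elif "trial" in name:
                _check_trials(path, report)
            else:
                _check_series(path, report)
        except Exception as exc:  # noqa: BLE001 - any parse failure is a violation
            report.violations.append(f"{path.name}: unreadable ({exc})")
    return report


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------


def write_results(result: components_mod.PipelineResult, out_dir: str | Path) -> None:
    """Write loadings, scores, regression summaries, tables, and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    fmt = "%.10g"
    loadings = pd.concat(
        [
            pd.DataFrame(
                {
                    "factor_type": "deactivation",
                    "roi": result.deactivation_component.rescaled_loadings.index,
                    "rescaled_loading": result.deactivation_component.rescaled_loadings.to_numpy(),
                }
            ),
            pd.DataFrame(
                {
                    "factor_type": "stability",
                    "roi": result.stability_component.rescaled_loadings.index,
                    "rescaled_loading": result.stability_component.rescaled_loadings.to_numpy(),
                }
            ),
        ],
        ignore_index=True,
    )
    loadings.to_csv(out / "loadings.csv", index=False, float_format=fmt)
    scores = pd.DataFrame(
        {
            "stability_score": result.stability_component.scores,
            "deactivation_score": result.deactivation_component.scores,
        }
    )
    scores.to_csv(out / "scores.csv", index_label="subject_id", float_format=fmt)
    result.stability.to_csv(out / "ar_estimates.csv", index_label="subject_id", float_format=fmt)
    result.deactivation.to_csv(out / "deactivation_betas.csv", index_label="subject_id", float_format=fmt)
    result.learning_indices.to_csv(out / "learning_indices.csv", index_label="subject_id", float_format=fmt)
    result.group_model.edge_list(result.fits).to_csv(
        out / "group_edges.csv", index=False, float_format=fmt
    )
    from .usem import subject_path_table

    subject_path_table(result.fits, result.group_model.structure).to_csv(
        out / "subject_paths.csv", index=False, float_format=fmt
    )
    summary = {
        "seed": result.config.seed,
        "n_subjects": int(len(result.learning_indices)),
        "excluded": result.excluded,
        "factor_correlation": result.regressions["valence"].factor_correlation,
        "regressions": {
            outcome: {
                "n": reg.n,
                "r2": reg.r2,
                "interaction_p": reg.interaction_p,
                "p_threshold": reg.p_threshold,
                "coefficients": {
                    name: {
                        "B": float(row["B"]),
                        "SE": float(row["SE"]),
                        "t": float(row["t"]),
                        "p": float(row["p"]),
                        "significant": bool(row["significant"]),
                    }
                    for name, row in reg.coefficients.iterrows()
                },
            }
            for outcome, reg in result.regressions.items()
        },
    }
    (out / "regressions.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    report_lines = [
        "stability-vs-deactivation pipeline report",
        f"seed: {result.config.seed}",
        f"subjects analyzed: {len(result.learning_indices)}",
        f"excluded: {sorted(result.excluded) or 'none'}",
        f"group paths: {len(result.group_model.structure.paths())}",
        "",
    ]
    for outcome, reg in result.regressions.items():
        b = reg.coefficients
        report_lines.append(
            f"{outcome}: stability B={b.loc['stability', 'B']:.4f} "
            f"(p={b.loc['stability', 'p']:.4g}), deactivation "
            f"B={b.loc['deactivation', 'B']:.4f} (p={b.loc['deactivation', 'p']:.4g})"
        )
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _load_cfg(config_path, seed, n_subjects, out):
    overrides = {}
    if seed is not None:
        overrides["seed"] = seed
    if n_subjects is not None:
        overrides["n_subjects"] = n_subjects
    if out is not None:
        overrides["out_dir"] = str(out)
    return load_config(config_path, **overrides)


@click.group()
def cli() -> None:
    """Stability vs. deactivation of the default mode network on the BART."""


def _common_options(fn):
    fn = click.option("--config", "config_path", type=click.Path(exists=True), default=None)(fn)
    fn = click.option("--seed", type=int, default=None)(fn)
    fn = click.option("--n-subjects", type=int, default=None)(fn)
    fn = click.option("--out", type=click.Path(), default=None)(fn)
    return fn


@cli.command()
@_common_options
def simulate(config_path, seed, n_subjects, out) -> None:
    """Generate a complete synthetic study (behavior + time series)."""
    cfg = _load_cfg(config_path, seed, n_subjects, out)
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)
    log_thresholds(cfg)
    t0 = time.perf_counter()
    bundle = synth.make_coupled_study(cfg.truth, cfg.n_subjects, cfg.t_range, cfg.seed, tr_seconds=cfg.tr_seconds)
    synth.write_study(bundle, out_dir)
    cfg.to_yaml(out_dir / "config.yaml")
    log_stage("simulate", time.perf_counter() - t0, seed=cfg.seed, n_subjects=cfg.n_subjects)
    click.echo(f"wrote study for {cfg.n_subjects} subjects to {out_dir}")


@cli.command()
@click.argument("trials", type=click.Path(exists=True))
@_common_options
def behavior(trials, config_path, seed, n_subjects, out) -> None:
    """Fit the feedback-learning mixed model from a trial-table CSV."""
    cfg = _load_cfg(config_path, seed, n_subjects, out)
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)
    log_thresholds(cfg)
    t0 = time.perf_counter()
    design = behavior_mod.design_from_trials(pd.read_csv(trials), cfg.value_percentile)
    fit = behavior_mod.fit_mixed_model(design)
    indices = behavior_mod.extract_learning_indices(fit)
    out_dir.mkdir(parents=True, exist_ok=True)
    design.to_csv(out_dir / "design.csv", index=False)
    indices.to_csv(out_dir / "learning_indices.csv", index=False, float_format="%.10g")
    log_stage("behavior", time.perf_counter() - t0, n_obs=fit.n_obs, converged=fit.converged)
    click.echo(
        "fixed effects: "
        + ", ".join(f"{k}={v:.4f}" for k, v in fit.gamma_hat.items())
    )


@cli.command()
@click.argument("study_dir", type=click.Path(exists=True))
@_common_options
def glm(study_dir, config_path, seed, n_subjects, out) -> None:
    """Estimate per-ROI deactivation betas for every subject in a study dir."""
    cfg = _load_cfg(config_path, seed, n_subjects, out)
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)
    log_thresholds(cfg)
    t0 = time.perf_counter()
    study = Path(study_dir)
    rows = {}
    for series_path in sorted(study.glob("series_*.csv")):
        sid = series_path.stem.replace("series_", "")
        ts = roiglm.read_series_csv(series_path, cfg.tr_seconds)
        events = roiglm.read_events_tsv(study / f"events_{sid}.tsv")
        design = roiglm.build_glm_design(events, ts.n_volumes, cfg.tr_seconds, cutoff_s=cfg.highpass_cutoff_s)
        censor = None
        motion_path = study / f"motion_{sid}.csv"
        if motion_path.exists():
            trace = pd.read_csv(motion_path).iloc[:, 0].to_numpy(float)
            censor, frac = roiglm.censor_frames(trace, cfg.motion_censor_mm)
            logger.info("subject %s: censored fraction %.3f", sid, frac)
        rows[sid] = roiglm.estimate_deactivation(ts, design, censor_mask=censor).pump_betas
    betas = pd.DataFrame.from_dict(rows, orient="index", columns=list(roiglm.ROI_NAMES))
    out_dir.mkdir(parents=True, exist_ok=True)
    betas.to_csv(out_dir / "deactivation_betas.csv", index_label="subject_id", float_format="%.10g")
    log_stage("glm", time.perf_counter() - t0, n_subjects=len(rows))
    click.echo(f"wrote deactivation betas for {len(rows)} subjects")


@cli.command()
@click.argument("study_dir", type=click.Path(exists=True))
@_common_options
def network(study_dir, config_path, seed, n_subjects, out) -> None:
    """Group + individual uSEM path search; writes AR estimates."""
    cfg = _load_cfg(config_path, seed, n_subjects, out)
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)
    log_thresholds(cfg)
    t0 = time.perf_counter()
    study = Path(study_dir)
    datasets = []
    for series_path in sorted(study.glob("series_*.csv")):
        sid = series_path.stem.replace("series_", "")
        ts = roiglm.read_series_csv(series_path, cfg.tr_seconds)
        datasets.append(usem.SubjectData.from_timeseries(ts, sid))
    group = usem.group_search(datasets, cfg.search_alpha, cfg.group_criterion, cfg.lagged_candidates)
    fits = {}
    for data in datasets:
        if cfg.individual_search:
            fits[data.subject_id] = usem.individual_search(
                data, group.structure, cfg.search_alpha, cfg.lagged_candidates
            ).fit
        else:
            fits[data.subject_id] = usem.fit_structure(data, group.structure)
    ar = usem.extract_ar(fits)
    out_dir.mkdir(parents=True, exist_ok=True)
    ar.to_csv(out_dir / "ar_estimates.csv", index_label="subject_id", float_format="%.10g")
    group.edge_list(fits).to_csv(out_dir / "group_edges.csv", index=False, float_format="%.10g")
    usem.subject_path_table(fits, group.structure).to_csv(
        out_dir / "subject_paths.csv", index=False, float_format="%.10g"
    )
    usem.export_graph(group, out_dir / "group_graph.adjlist")
    log_stage("network", time.perf_counter() - t0, n_subjects=len(datasets), group_paths=len(group.structure.paths()))
    click.echo(f"group model has {len(group.structure.paths())} shared paths")


@cli.command("components")
@click.argument("results_dir", type=click.Path(exists=True))
@_common_options
def components_cmd(results_dir, config_path, seed, n_subjects, out) -> None:
    """PCA scores + regressions from indices/betas/AR tables."""
    cfg = _load_cfg(config_path, seed, n_subjects, out)
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)
    log_thresholds(cfg)
    t0 = time.perf_counter()
    res = Path(results_dir)
    indices = pd.read_csv(res / "learning_indices.csv").set_index("subject_id")
    betas = pd.read_csv(res / "deactivation_betas.csv").set_index("subject_id")
    ar = pd.read_csv(res / "ar_estimates.csv").set_index("subject_id")
    common = indices.index.intersection(betas.index).intersection(ar.index)
    stab = components_mod.first_principal_component(ar.loc[common])
    deact = components_mod.first_principal_component(betas.loc[common])
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for outcome, col in (("valence", "valence_sensitivity"), ("value", "value_sensitivity")):
        reg = components_mod.fit_learning_regression(
            indices.loc[common, col], stab.scores, deact.scores, cfg.regression_p_threshold
        )
        b = reg.coefficients
        lines.append(
            f"{outcome}: stability B={b.loc['stability', 'B']:.4f} p={b.loc['stability', 'p']:.4g}; "
            f"deactivation B={b.loc['deactivation', 'B']:.4f} p={b.loc['deactivation', 'p']:.4g}"
        )
    (out_dir / "component_regressions.txt").write_text("\n".join(lines) + "\n")
    log_stage("components", time.perf_counter() - t0, n_subjects=len(common))
    for line in lines:
        click.echo(line)


@cli.command("run-all")
@_common_options
def run_all(config_path, seed, n_subjects, out) -> None:
    """Run the full pipeline end to end and write the results bundle."""
    cfg = _load_cfg(config_path, seed, n_subjects, out)
    out_dir = Path(cfg.out_dir)
    setup_logging(out_dir)
    log_thresholds(cfg)
    t0 = time.perf_counter()
    result = components_mod.run_full_pipeline(cfg)
    write_results(result, out_dir)
    log_stage("run-all", time.perf_counter() - t0, seed=cfg.seed, n_subjects=cfg.n_subjects)
    for outcome, reg in result.regressions.items():
        b = reg.coefficients
        click.echo(
            f"{outcome}: stability B={b.loc['stability', 'B']:.4f} p={b.loc['stability', 'p']:.4g}; "
            f"deactivation B={b.loc['deactivation', 'B']:.4f} p={b.loc['deactivation', 'p']:.4g}"
        )


@cli.command()
@click.argument("paths", nargs=-1, type=click.Path())
def validate(paths) -> None:
    """Schema-check input files; exit 1 on violations."""
    report = validate_inputs(list(paths))
    click.echo(json.dumps(report.to_dict(), indent=2))
    if not report.ok:
        raise SystemExit(1)


def main(argv: list[str] | None = None) -> int:
    """Programmatic entry point with the 0/1/2 exit-code contract."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except SystemExit as exc:
        return int(exc.code or 0)
    except (click.UsageError, click.BadParameter, FileNotFoundError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        return 1
    except Exception as exc:  # noqa: BLE001 - internal failure
        click.echo(f"internal error: {exc}", err=True)
        return 2


if __name__ == "__main__":
    sys.exit(main())
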