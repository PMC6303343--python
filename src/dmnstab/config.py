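"""Run configuration: study constants, simulation truth, and analysis thresholds.

Every fixed constant of the analysis lives here with its study default:
24 balloons, explosion points 4-10, 0.5-4.0 s event jitter, TR = 2 s,
128 s high-pass cutoff, 2 mm motion censoring, the 75th-percentile value
threshold, the 70% group-path criterion, and the p = 0.025 regression
threshold. All defaults are overridable from a YAML file and the full
configuration is serialized into every results bundle so a run can be
regenerated exactly from its config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: The ten default-mode-network regions, in canonical column order.
ROI_NAMES: tuple[str, ...] = (
    "mPFC",
    "PCC",
    "L_dSFG",
    "R_dSFG",
    "L_TP",
    "R_TP",
    "L_Hipp",
    "R_Hipp",
    "L_AG",
    "R_AG",
)

N_ROIS = 10

#: Repetition time of the scan sequence, seconds.
TR_SECONDS = 2.0

#: Number of balloon trials per subject.
N_BALLOONS = 24

#: Inclusive range of explosion points (pumps at which a balloon can pop).
EXPLOSION_MIN = 4
EXPLOSION_MAX = 10

#: Inter-event jitter bounds, seconds (0.5-4.0 s).
JITTER_MIN_S = 0.5
JITTER_MAX_S = 4.0

#: High-pass filter cutoff for the GLM drift model, seconds.
HIGHPASS_CUTOFF_S = 128.0

#: Frame-displacement censoring threshold, millimetres.
MOTION_CENSOR_MM = 2.0

#: Quantile of a subject's own pump counts defining "high-value" feedback.
VALUE_PERCENTILE = 75.0

#: Fraction of subjects for which a candidate path must be significant to
#: enter (and survive pruning from) the group model.
GROUP_CRITERION = 0.70

#: Per-test alpha used in the path search.
SEARCH_ALPHA = 0.05

#: Two-sided significance threshold for the final regressions (Bonferroni
#: for the two feedback-learning outcomes).
REGRESSION_P_THRESHOLD = 0.025


@dataclass
class TruthConfig:
    """Ground-truth parameters of the synthetic study.

    gamma holds the Level-1 fixed effects (intercept, trial number,
    current outcome, previous-outcome valence, previous-outcome value).
    ``gamma[2]`` is carried for the fitted model's contract but does not
    act generatively: in the mechanical balloon model the current outcome
    is determined by the intended pump count and the explosion point.
    """

    gamma: tuple[float, float, float, float, float] = (5.0, -0.05, -1.0, 1.5, 0.8)
    tau00: float = 1.0  # random-intercept variance
    tau33: float = 0.25  # valence-slope variance
    tau44: float = 0.25  # value-slope variance
    sigma2: float = 1.0  # trial-level residual variance

    # Network truth: AR mean/SD across subjects, per-ROI within-subject
    # scatter, and the shared contemporaneous paths (source, target, weight).
    ar_mean: float = 0.6
    ar_between_sd: float = 0.12
    ar_within_sd: float = 0.05
    group_contemporaneous: tuple[tuple[str, str, float], ...] = (
        ("PCC", "L_AG", 0.3),
        ("PCC", "R_AG", 0.3),
        ("mPFC", "PCC", 0.3),
    )
    zeta_var: float = 1.0

    # Stability -> learning coupling: slope deviations are
    # coupling_b * standardized AR deviation + N(0, slope_noise_sd^2).
    coupling_b: float = 0.5
    slope_noise_sd: float = 0.1

    # Deactivation truth: per-subject pump-response amplitude, drawn
    # independently of the AR process (negative = deactivation).
    deact_amp_mean: float = -0.5
    deact_amp_sd: float = 0.3


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 65
    t_range: tuple[int, int] = (180, 300)  # volumes per subject (self-paced)
    truth: TruthConfig = field(default_factory=TruthConfig)

    tr_seconds: float = TR_SECONDS
    n_balloons: int = N_BALLOONS
    jitter_s: tuple[float, float] = (JITTER_MIN_S, JITTER_MAX_S)
    highpass_cutoff_s: float = HIGHPASS_CUTOFF_S
    motion_censor_mm: float = MOTION_CENSOR_MM
    value_percentile: float = VALUE_PERCENTILE
    group_criterion: float = GROUP_CRITERION
    search_alpha: float = SEARCH_ALPHA
    regression_p_threshold: float = REGRESSION_P_THRESHOLD
    #: include lagged cross-ROI candidates in the path search
    lagged_candidates: bool = True
    #: run the per-subject path search after the group search
    individual_search: bool = True
    out_dir: str = "results"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


_SCHEMA_ERRORS = {
    "seed": lambda v: isinstance(v, int) and 0 <= v < 2**31,
    "n_subjects": lambda v: isinstance(v, int) and v >= 1,
    "group_criterion": lambda v: 0 < v <= 1,
    "search_alpha": lambda v: 0 < v < 1,
    "regression_p_threshold": lambda v: 0 < v < 1,
    "motion_censor_mm": lambda v: v > 0,
    "value_percentile": lambda v: 0 < v < 100,
    "tr_seconds": lambda v: v > 0,
    "highpass_cutoff_s": lambda v: v > 0,
}


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of violation strings (empty when the config is valid)."""
    errors: list[str] = []
    d = cfg.to_dict()
    for key, check in _SCHEMA_ERRORS.items():
        try:
            ok = check(d[key])
        except Exception:  # noqa: BLE001 - any failure is a violation
            ok = False
        if not ok:
            errors.append(f"config.{key}: invalid value {d[key]!r}")
    lo, hi = cfg.t_range
    if not (isinstance(lo, int) and isinstance(hi, int) and 0 < lo <= hi):
        errors.append(f"config.t_range: invalid range {cfg.t_range!r}")
    t = cfg.truth
    for name in ("tau00", "tau33", "tau44", "sigma2", "zeta_var"):
        if getattr(t, name) < 0:
            errors.append(f"truth.{name}: variance must be >= 0")
    if not (0 <= t.ar_mean < 1):
        errors.append("truth.ar_mean: must lie in [0, 1) for stationarity")
    for src, dst, _w in t.group_contemporaneous:
        for roi in (src, dst):
            if roi not in ROI_NAMES:
                errors.append(f"truth.group_contemporaneous: unknown ROI {roi!r}")
    return errors


def _merge(base: dict[str, Any], override: dict[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load a RunConfig from YAML, applying keyword overrides on top."""
    data = RunConfig().to_dict()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = _merge(data, loaded)
    data = _merge(data, overrides)
    truth_d = data.pop("truth", {})
    if "gamma" in truth_d:
        truth_d["gamma"] = tuple(truth_d["gamma"])
    if "group_contemporaneous" in truth_d:
        truth_d["group_contemporaneous"] = tuple(
            tuple(e) for e in truth_d["group_contemporaneous"]
        )
    truth = TruthConfig(**truth_d)
    for key in ("t_range", "jitter_s"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = RunConfig(truth=truth, **data)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    return cfg
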