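"""Readers, writers, configuration and the end-to-end pipeline.

Study data travel as long-format (tidy) CSV with the header
``subject_id,arm,time,outcome,value`` — one observed score per row.  A shim
accepts one-row-per-subject "wide" files with named pre/post columns, since
practitioner spreadsheets usually arrive that way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decision, intervals, measurement, response
from .decision import Direction, Threshold, ThresholdSource
from .exceptions import ConfigurationError, InvalidInputError
from .measurement import Arm, STUDY_COLUMNS, TEMethod, TypicalError

logger = logging.getLogger(__name__)

VALID_ARMS = {a.value for a in Arm}


def read_study_csv(path) -> pd.DataFrame:
    """Read and validate a long-format study table.

    Rejects missing/extra header fields, unknown arm labels and non-numeric
    values, naming the offending rows (1-based, counting the header as
    row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"{path}: file is empty") from None
    if list(df.columns) != list(STUDY_COLUMNS):
        raise InvalidInputError(
            f"{path}: expected header {','.join(STUDY_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    if df.empty:
        raise InvalidInputError(f"{path}: no data rows")
    problems = []
    rows = df.index + 2  # 1-based file rows, after the header
    values = pd.to_numeric(df["value"], errors="coerce")
    for idx in df.index[values.isna() | ~np.isfinite(values.fillna(np.inf))]:
        problems.append(f"row {rows[idx]}: non-numeric value {df.at[idx, 'value']!r}")
    for idx in df.index[~df["arm"].isin(VALID_ARMS)]:
        problems.append(
            f"row {rows[idx]}: unknown arm {df.at[idx, 'arm']!r} "
            f"(expected one of {sorted(VALID_ARMS)})"
        )
    blank = df[["subject_id", "time", "outcome"]].isna().any(axis=1)
    for idx in df.index[blank]:
        problems.append(f"row {rows[idx]}: missing subject_id/time/outcome")
    if problems:
        raise InvalidInputError(f"{path}: malformed rows:\n  " + "\n  ".join(problems))
    out = df.copy()
    out["value"] = values.astype(float)
    dup = out.duplicated(subset=["subject_id", "arm", "time", "outcome"])
    if dup.any():
        raise InvalidInputError(
            f"{path}: duplicate (subject_id, arm, time, outcome) at file "
            f"row(s) {[int(r) for r in rows[out.index[dup]]]}"
        )
    return out.reset_index(drop=True)


def write_study_csv(study: pd.DataFrame, path) -> None:
    """Write a long-format study table; full float precision preserved."""
    study.to_csv(path, index=False, columns=list(STUDY_COLUMNS))


def read_wide_csv(path, outcome: str, *, subject_col: str = "subject_id",
                  arm_col: str = "arm", pre_col: str = "pre",
                  post_col: str = "post") -> pd.DataFrame:
    """Import a one-row-per-subject file with named pre/post columns and
    return the equivalent long-format table."""
    df = pd.read_csv(path)
    for col in (subject_col, arm_col, pre_col, post_col):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    rows = []
    for _, r in df.iterrows():
        for time, col in (("pre", pre_col), ("post", post_col)):
            rows.append((str(r[subject_col]), str(r[arm_col]), time, outcome,
                         float(r[col])))
    long = pd.DataFrame(rows, columns=list(STUDY_COLUMNS))
    bad_arms = set(long["arm"]) - VALID_ARMS
    if bad_arms:
        raise InvalidInputError(f"{path}: unknown arm label(s) {sorted(bad_arms)}")
    return long


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = response.DEFAULT_N_BOOT
    seed: int | None = None
    level: float = 0.95


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run the full pipeline on one outcome.

    ``te_source`` selects where the typical error comes from:

    * ``"data"`` — group test--retest rows in the study at ``te_times``;
    * ``"literature_te"`` — a published TE (``te_value``, optional ``te_n``);
    * ``"literature_cv"`` — a published CV% scaled by a reference score
      (``cv_percent``, ``cv_reference_score``).
    """

    outcome: str
    direction: Direction = Direction.INCREASE_BENEFICIAL
    te_source: str = "data"
    te_value: float | None = None
    te_n: int | None = None
    cv_percent: float | None = None
    cv_reference_score: float | None = None
    te_times: tuple[str, str] = ("test1", "test2")
    units: str = ""
    ci_level: float = 0.95
    adjust: bool = False
    swc_source: str = "cohen_d"
    swc_value: float | None = None
    cohen_d: float = decision.DEFAULT_COHEN_D
    classify_rule: str = "approx_te"
    bootstrap: BootstrapConfig | None = field(default_factory=BootstrapConfig)

    def __post_init__(self) -> None:
        if self.te_source not in ("data", "literature_te", "literature_cv"):
            raise ConfigurationError(f"unknown te_source {self.te_source!r}")
        if self.te_source == "literature_te" and self.te_value is None:
            raise ConfigurationError("te_source 'literature_te' requires te_value")
        if self.te_source == "literature_cv" and (
                self.cv_percent is None or self.cv_reference_score is None):
            raise ConfigurationError(
                "te_source 'literature_cv' requires cv_percent and "
                "cv_reference_score"
            )
        if self.swc_source not in ("user", "cohen_d"):
            raise ConfigurationError(f"unknown swc_source {self.swc_source!r}")
        if self.swc_source == "user" and self.swc_value is None:
            raise ConfigurationError("swc_source 'user' requires swc_value")


def resolve_te(config: AnalysisConfig, study: pd.DataFrame | None) -> TypicalError:
    """Materialise the typical error the configuration points at."""
    if config.te_source == "literature_te":
        return TypicalError(
            estimate=config.te_value, method=TEMethod.LITERATURE_TE,
            n=config.te_n, df=None if config.te_n is None else config.te_n - 1,
            units=config.units,
        )
    if config.te_source == "literature_cv":
        return measurement.te_from_cv(
            config.cv_percent, config.cv_reference_score,
            n=config.te_n, units=config.units,
        )
    if study is None:
        raise ConfigurationError("te_source 'data' requires a study table")
    pairs = measurement.pairs_from_records(
        study, config.outcome, time1=config.te_times[0],
        time2=config.te_times[1], units=config.units,
    )
    return measurement.estimate_te_group(pairs)


def resolve_threshold(config: AnalysisConfig,
                      baseline_scores=None) -> Threshold:
    """Materialise the smallest-worthwhile-change threshold."""
    if config.swc_source == "user":
        return Threshold(swc=config.swc_value, direction=config.direction,
                         source=ThresholdSource.USER)
    if baseline_scores is None:
        raise ConfigurationError(
            "swc_source 'cohen_d' requires baseline scores to compute the "
            "between-individual SD"
        )
    return decision.swc_from_cohen(baseline_scores, d=config.cohen_d,
                                   direction=config.direction)


def run_pipeline(config: AnalysisConfig, study: pd.DataFrame) -> dict:
    """Run the full analysis on one outcome and return a JSON-ready report.

    The report always carries the typical error with provenance and the CI
    multiplier used.  Per-subject baseline CIs cover every subject with a
    ``pre`` observation; change CIs and success verdicts cover subjects with
    complete pre/post pairs; the group-level response section appears when
    both arms have at least two complete subjects.
    """
    te = resolve_te(config, study)
    logger.info("typical error: %.6g (%s, n=%s, df=%s)", te.estimate,
                te.method.value, te.n, te.df)
    sub = study[study["outcome"] == config.outcome]
    if sub.empty:
        raise InvalidInputError(f"study has no records for outcome {config.outcome!r}")
    mult = intervals.ci_multiplier(
        config.ci_level, n=None if not config.adjust else (te.df or 0) + 1
    ) if not (config.adjust and te.df is None) else None
    if config.adjust and te.df is None:
        raise ConfigurationError(
            "adjusted intervals requested but the typical error carries no df"
        )
    logger.info("CI multiplier at level %.3g (adjust=%s): %s",
                config.ci_level, config.adjust, mult)

    report: dict = {
        "outcome": config.outcome,
        "direction": config.direction.value,
        "te": te.to_dict(),
        "ci_level": config.ci_level,
        "adjusted": config.adjust,
        "multiplier": mult,
        "baseline": [],
        "changes": [],
        "threshold": None,
        "response": None,
    }

    pre_rows = sub[sub["time"] == "pre"]
    for _, r in pre_rows.iterrows():
        ci = intervals.true_score_ci(r["value"], te, level=config.ci_level,
                                     adjust=config.adjust)
        report["baseline"].append({
            "subject_id": r["subject_id"], "arm": r["arm"],
            "observed": r["value"], "ci": ci.to_dict(),
        })

    threshold = None
    if not pre_rows.empty:
        try:
            threshold = resolve_threshold(config, pre_rows["value"].to_numpy())
        except InvalidInputError:
            threshold = None
    if config.swc_source == "user":
        threshold = resolve_threshold(config)
    if threshold is not None:
        report["threshold"] = {
            "swc": threshold.swc,
            "direction": threshold.direction.value,
            "source": threshold.source.value,
            "d": threshold.d,
            "baseline_sd": threshold.baseline_sd,
        }

    have_post = "post" in set(sub["time"])
    if have_post and threshold is not None:
        changes = response.change_scores(study, config.outcome)
        for _, r in changes.iterrows():
            assessment = decision.classify_change(
                r["pre"], r["post"], te, threshold,
                rule=config.classify_rule, level=config.ci_level,
                adjust=config.adjust,
            )
            report["changes"].append({
                "subject_id": r["subject_id"], "arm": r["arm"],
                "pre": r["pre"], "post": r["post"],
                "change": assessment.observed_change,
                "ci": assessment.interval.to_dict(),
                "verdict": assessment.verdict.value,
            })
        arms = set(changes["arm"])
        counts_ok = all(
            (changes["arm"] == a).sum() >= 2
            for a in (Arm.INTERVENTION.value, Arm.CONTROL.value)
        )
        if {"intervention", "control"} <= arms and counts_ok:
            boot = config.bootstrap
            if boot is not None and boot.seed is None:
                raise ConfigurationError(
                    "bootstrap requested but no seed configured"
                )
            est = response.estimate_response(
                study, config.outcome, threshold,
                n_boot=None if boot is None else boot.n_boot,
                level=0.95 if boot is None else boot.level,
                seed=None if boot is None else boot.seed,
            )
            report["response"] = est.to_dict()
    return report


#: Minimal structural schema of the pipeline report (field -> type or None).
REPORT_SCHEMA = {
    "outcome": str,
    "direction": str,
    "te": dict,
    "ci_level": float,
    "adjusted": bool,
    "multiplier": (float, type(None)),
    "baseline": list,
    "changes": list,
    "threshold": (dict, type(None)),
    "response": (dict, type(None)),
}


def validate_report(report: dict) -> None:
    """Check a pipeline report against :data:`REPORT_SCHEMA`; raise
    :class:`InvalidInputError` on a violation."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise InvalidInputError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise InvalidInputError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ}"
            )
    json.dumps(report)  # must be serialisable
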