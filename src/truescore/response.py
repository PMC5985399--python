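"""Group-level individual-response analysis.

Over a pre/post intervention both arms accumulate measurement error and
biological variability in their change scores; only the intervention arm
additionally carries heterogeneous intervention effects.  The intervention
response SD is therefore

    sigma_IR = sqrt(SD_Int^2 - SD_Con^2)

where SD_Int and SD_Con are the SDs of observed change scores in the
intervention and control arms.  Modelling intervention-attributable true
change as Normal(mean intervention-arm change, sigma_IR), the *proportion
of response* is the tail area beyond the smallest worthwhile change in the
beneficial direction.  Uncertainty is quantified by a percentile bootstrap
that resamples subjects with replacement within each arm independently.

When SD_Con >= SD_Int the variance difference is negative: sigma_IR is
clamped to 0 with a ``degenerate`` flag, and the proportion collapses to a
step function (1 if the mean change lies strictly beyond the SWC, else 0).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decision import Direction, Threshold
from .exceptions import InvalidInputError
from .intervals import Interval, IntervalKind
from .measurement import Arm

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class ArmChangeSummary:
    """Mean and SD of observed pre-to-post change scores in one arm."""

    arm: Arm
    n: int
    mean_change: float
    sd_change: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"arm {self.arm.value} needs n >= 2, got {self.n}")
        if not np.isfinite(self.sd_change) or self.sd_change < 0:
            raise InvalidInputError(
                f"sd_change must be finite and >= 0, got {self.sd_change!r}"
            )

    @classmethod
    def from_changes(cls, arm: Arm, changes) -> "ArmChangeSummary":
        arr = np.asarray(changes, dtype=float)
        if arr.size < 2:
            raise InvalidInputError(
                f"arm {arm.value} needs at least 2 change scores, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("change scores must all be finite")
        return cls(arm=arm, n=int(arr.size),
                   mean_change=float(arr.mean()),
                   sd_change=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class BootstrapDiagnostics:
    """Point estimate and replicate-level diagnostics of a bootstrap run."""

    interval: Interval
    point_estimate: float
    degenerate_fraction: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class ResponseEstimate:
    """Full result of a proportion-of-response analysis."""

    sigma_ir: float
    degenerate: bool
    mean_change_intervention: float
    sd_change_intervention: float
    sd_change_control: float
    n_intervention: int
    n_control: int
    swc: Threshold
    proportion: float
    bootstrap: BootstrapDiagnostics | None = None

    def to_dict(self) -> dict:
        out = {
            "sigma_ir": self.sigma_ir,
            "degenerate": self.degenerate,
            "mean_change_intervention": self.mean_change_intervention,
            "sd_change_intervention": self.sd_change_intervention,
            "sd_change_control": self.sd_change_control,
            "n_intervention": self.n_intervention,
            "n_control": self.n_control,
            "swc": self.swc.swc,
            "direction": self.swc.direction.value,
            "proportion": self.proportion,
        }
        if self.bootstrap is not None:
            out["bootstrap"] = {
                "interval": self.bootstrap.interval.to_dict(),
                "point_estimate": self.bootstrap.point_estimate,
                "degenerate_fraction": self.bootstrap.degenerate_fraction,
                "n_boot": self.bootstrap.n_boot,
                "seed": self.bootstrap.seed,
            }
        return out


def sigma_ir(intervention: ArmChangeSummary,
             control: ArmChangeSummary) -> tuple[float, bool]:
    """Intervention response SD, sqrt(SD_Int^2 - SD_Con^2).

    Returns ``(sigma, degenerate)``.  A non-positive variance difference is
    clamped to sigma = 0 with ``degenerate=True`` and a logged warning: the
    data show no excess change variability attributable to the intervention.
    """
    var_diff = intervention.sd_change ** 2 - control.sd_change ** 2
    if var_diff <= 0:
        logger.warning(
            "control-arm change variability (SD %.4g) matches or exceeds the "
            "intervention arm's (SD %.4g); variance difference %.4g <= 0, "
            "sigma_IR clamped to 0 — no evidence of individual response "
            "heterogeneity",
            control.sd_change, intervention.sd_change, var_diff,
        )
        return 0.0, True
    return float(np.sqrt(var_diff)), False


def proportion_response(mean_change: float, sigma: float,
                        threshold: Threshold) -> float:
    """Tail area of Normal(mean_change, sigma) beyond the SWC in the
    beneficial direction; a step function when sigma = 0."""
    if not np.isfinite(mean_change):
        raise InvalidInputError(f"mean_change must be finite, got {mean_change!r}")
    if not np.isfinite(sigma) or sigma < 0:
        raise InvalidInputError(f"sigma must be finite and >= 0, got {sigma!r}")
    if threshold.direction is Direction.INCREASE_BENEFICIAL:
        line = threshold.swc
        if sigma == 0.0:
            return 1.0 if mean_change > line else 0.0
        return float(stats.norm.sf(line, loc=mean_change, scale=sigma))
    line = -threshold.swc
    if sigma == 0.0:
        return 1.0 if mean_change < line else 0.0
    return float(stats.norm.cdf(line, loc=mean_change, scale=sigma))


def _proportion_from_changes(int_changes: np.ndarray, con_changes: np.ndarray,
                             threshold: Threshold) -> tuple[float, bool]:
    s_int = ArmChangeSummary.from_changes(Arm.INTERVENTION, int_changes)
    s_con = ArmChangeSummary.from_changes(Arm.CONTROL, con_changes)
    sigma, degenerate = sigma_ir(s_int, s_con)
    return proportion_response(s_int.mean_change, sigma, threshold), degenerate


def bootstrap_proportion_ci(intervention_changes, control_changes,
                            threshold: Threshold, level: float = 0.95,
                            n_boot: int = DEFAULT_N_BOOT, *,
                            seed: int) -> BootstrapDiagnostics:
    """Percentile bootstrap CI for the proportion of response.

    Each replicate resamples subjects with replacement within each arm
    independently (arm sizes fixed) and recomputes mean change, SD_Int,
    SD_Con, sigma_IR (with the degeneracy clamp) and the proportion.
    Degenerate replicates contribute their 0/1 proportion rather than being
    discarded; their frequency is reported.  Bounds are clipped to [0, 1].
    """
    if n_boot < 100:
        raise InvalidInputError(f"n_boot must be >= 100, got {n_boot}")
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level must lie in (0, 1), got {level!r}")
    ints = np.asarray(intervention_changes, dtype=float)
    cons = np.asarray(control_changes, dtype=float)
    for name, arr in (("intervention", ints), ("control", cons)):
        if arr.size < 2:
            raise InvalidInputError(
                f"{name} arm needs at least 2 change scores, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"{name}-arm change scores must all be finite")

    point, _ = _proportion_from_changes(ints, cons, threshold)

    rng = np.random.default_rng(seed)
    boot_int = rng.integers(0, ints.size, size=(n_boot, ints.size))
    boot_con = rng.integers(0, cons.size, size=(n_boot, cons.size))
    res_int = ints[boot_int]
    res_con = cons[boot_con]
    mean_int = res_int.mean(axis=1)
    var_int = res_int.var(axis=1, ddof=1)
    var_con = res_con.var(axis=1, ddof=1)
    var_diff = var_int - var_con
    degenerate = var_diff <= 0
    sigma = np.sqrt(np.where(degenerate, 0.0, var_diff))

    if threshold.direction is Direction.INCREASE_BENEFICIAL:
        line = threshold.swc
        with np.errstate(divide="ignore", invalid="ignore"):
            props = stats.norm.sf((line - mean_int) / np.where(sigma > 0, sigma, 1.0))
        props = np.where(degenerate, (mean_int > line).astype(float), props)
    else:
        line = -threshold.swc
        with np.errstate(divide="ignore", invalid="ignore"):
            props = stats.norm.cdf((line - mean_int) / np.where(sigma > 0, sigma, 1.0))
        props = np.where(degenerate, (mean_int < line).astype(float), props)

    alpha = 1.0 - level
    lower, upper = np.quantile(props, [alpha / 2.0, 1.0 - alpha / 2.0])
    interval = Interval(
        lower=float(np.clip(lower, 0.0, 1.0)),
        upper=float(np.clip(upper, 0.0, 1.0)),
        level=level,
        center=float((lower + upper) / 2.0),
        adjusted=False,
        df=None,
        kind=IntervalKind.TRUE_SCORE_CHANGE,
        note="percentile bootstrap, within-arm resampling",
    )
    return BootstrapDiagnostics(
        interval=interval,
        point_estimate=point,
        degenerate_fraction=float(degenerate.mean()),
        n_boot=n_boot,
        seed=seed,
    )


def change_scores(study: pd.DataFrame, outcome: str, *,
                  pre: str = "pre", post: str = "post") -> pd.DataFrame:
    """Per-subject change scores (post - pre) for one outcome.

    Returns a frame with columns ``subject_id, arm, pre, post, change``.
    A subject present at only one time point is an error naming the subject.
    """
    sub = study[study["outcome"] == outcome]
    if sub.empty:
        raise InvalidInputError(f"no records for outcome {outcome!r}")
    missing_times = {pre, post} - set(sub["time"].unique())
    if missing_times:
        raise InvalidInputError(
            f"outcome {outcome!r} has no records at time point(s) "
            f"{sorted(missing_times)}"
        )
    wide = sub.pivot_table(index=["subject_id", "arm"], columns="time",
                           values="value", aggfunc="first")[[pre, post]]
    incomplete = wide[wide.isna().any(axis=1)]
    if not incomplete.empty:
        subjects = [str(s) for s, _ in incomplete.index]
        raise InvalidInputError(
            f"subject(s) {subjects} lack a complete {pre}/{post} pair for "
            f"outcome {outcome!r}"
        )
    out = wide.reset_index()
    out.columns.name = None
    out = out.rename(columns={pre: "pre", post: "post"})
    out["change"] = out["post"] - out["pre"]
    return out


def estimate_response(study: pd.DataFrame, outcome: str, threshold: Threshold, *,
                      pre: str = "pre", post: str = "post",
                      n_boot: int | None = DEFAULT_N_BOOT,
                      level: float = 0.95,
                      seed: int | None = None) -> ResponseEstimate:
    """End-to-end proportion-of-response analysis of a two-arm study table.

    Computes per-subject change scores, arm summaries, sigma_IR, the
    proportion of response, and (unless ``n_boot`` is None) a percentile
    bootstrap CI, for which ``seed`` is mandatory.
    """
    changes = change_scores(study, outcome, pre=pre, post=post)
    by_arm = {}
    for arm in (Arm.INTERVENTION, Arm.CONTROL):
        arm_changes = changes.loc[changes["arm"] == arm.value, "change"].to_numpy()
        if arm_changes.size < 2:
            raise InvalidInputError(
                f"outcome {outcome!r} has {arm_changes.size} complete subject(s) "
                f"in the {arm.value} arm; need at least 2"
            )
        by_arm[arm] = arm_changes
    s_int = ArmChangeSummary.from_changes(Arm.INTERVENTION, by_arm[Arm.INTERVENTION])
    s_con = ArmChangeSummary.from_changes(Arm.CONTROL, by_arm[Arm.CONTROL])
    sigma, degenerate = sigma_ir(s_int, s_con)
    prop = proportion_response(s_int.mean_change, sigma, threshold)

    boot = None
    if n_boot is not None:
        if seed is None:
            raise InvalidInputError(
                "a seed is required for the bootstrap; pass seed=... or "
                "n_boot=None to skip it"
            )
        boot = bootstrap_proportion_ci(
            by_arm[Arm.INTERVENTION], by_arm[Arm.CONTROL], threshold,
            level=level, n_boot=n_boot, seed=seed,
        )
    return ResponseEstimate(
        sigma_ir=sigma,
        degenerate=degenerate,
        mean_change_intervention=s_int.mean_change,
        sd_change_intervention=s_int.sd_change,
        sd_change_control=s_con.sd_change,
        n_intervention=s_int.n,
        n_control=s_con.n,
        swc=threshold,
        proportion=prop,
        bootstrap=boot,
    )
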