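"""Smallest-worthwhile-change thresholds and per-individual success calls.

The smallest worthwhile change (SWC) is the magnitude of true-score change
a practitioner deems practically meaningful — either chosen directly or as
a Cohen-style small effect, d (default 0.2) times the baseline
between-individual SD.  An intervention is judged *successful* for an
individual when the whole true-score-change CI lies strictly beyond the
SWC on the beneficial side; the interval may be the quick ``+/-TE`` rule or
a proper change CI at any level.

The SWC is stored as a magnitude; the threshold's direction carries the
sign, so a decrease-beneficial outcome (e.g. skinfolds) requires the
interval's upper bound to fall below ``-swc``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .intervals import Interval, approx_change_ci, change_ci
from .measurement import TypicalError

DEFAULT_COHEN_D = 0.2


class Direction(str, enum.Enum):
    INCREASE_BENEFICIAL = "increase_beneficial"
    DECREASE_BENEFICIAL = "decrease_beneficial"


class ThresholdSource(str, enum.Enum):
    USER = "user"
    COHEN_D = "cohen_d"


class Verdict(str, enum.Enum):
    SUCCESSFUL = "successful"
    NOT_SUCCESSFUL = "not_successful"


@dataclass(frozen=True)
class Threshold:
    """A smallest-worthwhile-change magnitude with its beneficial direction."""

    swc: float
    direction: Direction = Direction.INCREASE_BENEFICIAL
    source: ThresholdSource = ThresholdSource.USER
    d: float | None = None
    baseline_sd: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.swc) or self.swc < 0:
            raise InvalidInputError(
                f"SWC must be a finite non-negative magnitude, got {self.swc!r}"
            )
        if self.source is ThresholdSource.COHEN_D:
            if self.d is None or self.baseline_sd is None:
                raise InvalidInputError(
                    "a Cohen-d threshold must carry d and baseline_sd"
                )


@dataclass(frozen=True)
class ChangeAssessment:
    """A classified individual change: the interval, the threshold, the call."""

    observed_change: float
    interval: Interval
    threshold: Threshold
    verdict: Verdict


@dataclass(frozen=True)
class SensitivityReport:
    """Screen of whether a test's TE permits detecting the expected change.

    ``gap`` is expected_change - swc; the test is adequate when TE <= gap,
    i.e. an individual achieving the expected change would typically clear
    the ``swc + TE`` bar the +/-TE success rule imposes.
    """

    swc: float
    te: float
    expected_change: float
    gap: float
    required_observed_change: float
    adequate: bool
    message: str = ""


def swc_from_cohen(baseline_scores, d: float = DEFAULT_COHEN_D,
                   direction: Direction = Direction.INCREASE_BENEFICIAL) -> Threshold:
    """SWC as d times the baseline between-individual sample SD.

    ``baseline_scores`` are one baseline value per individual, conventionally
    pooled across both study arms.
    """
    arr = np.asarray(baseline_scores, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidInputError(
            f"need at least 2 baseline scores to form a between-individual SD, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("baseline scores must all be finite")
    if not np.isfinite(d) or d <= 0:
        raise InvalidInputError(f"effect size d must be > 0, got {d!r}")
    sd = float(np.std(arr, ddof=1))
    return Threshold(
        swc=d * sd,
        direction=direction,
        source=ThresholdSource.COHEN_D,
        d=d,
        baseline_sd=sd,
    )


def _interval_beyond(interval: Interval, threshold: Threshold) -> bool:
    # strict inequality: a bound exactly on the SWC does not "lie beyond" it
    if threshold.direction is Direction.INCREASE_BENEFICIAL:
        return interval.lower > threshold.swc
    return interval.upper < -threshold.swc


def classify_change(pre_score: float, post_score: float, te: TypicalError,
                    threshold: Threshold, rule: str = "approx_te",
                    level: float = 0.5, adjust: bool = False) -> ChangeAssessment:
    """Classify an individual's pre-to-post change as successful or not.

    ``rule="approx_te"`` uses the quick ``change +/- TE`` interval;
    ``rule="ci"`` uses a proper change CI at ``level`` (optionally
    t-adjusted).  Success requires the whole interval to lie strictly
    beyond the SWC in the beneficial direction.
    """
    if rule == "approx_te":
        interval = approx_change_ci(pre_score, post_score, te)
    elif rule == "ci":
        interval = change_ci(pre_score, post_score, te, level=level, adjust=adjust)
    else:
        raise InvalidInputError(f"unknown rule {rule!r}; expected 'approx_te' or 'ci'")
    verdict = (Verdict.SUCCESSFUL if _interval_beyond(interval, threshold)
               else Verdict.NOT_SUCCESSFUL)
    return ChangeAssessment(
        observed_change=post_score - pre_score,
        interval=interval,
        threshold=threshold,
        verdict=verdict,
    )


def required_observed_change(threshold: Threshold, te: TypicalError) -> float:
    """Minimum observed change magnitude (on the beneficial side) at which
    the +/-TE rule declares success: swc + TE."""
    return threshold.swc + te.estimate


def sensitivity_check(threshold: Threshold, te: TypicalError,
                      expected_change: float) -> SensitivityReport:
    """Screen a test's measurement error against the expected improvement.

    ``expected_change`` is the anticipated beneficial change magnitude.  The
    test is adequate when TE does not exceed the gap between expected change
    and SWC; otherwise individuals must improve more than typically expected
    before the +/-TE rule can register success.
    """
    if not np.isfinite(expected_change):
        raise InvalidInputError(f"expected_change must be finite, got {expected_change!r}")
    gap = expected_change - threshold.swc
    required = required_observed_change(threshold, te)
    if gap <= 0:
        return SensitivityReport(
            swc=threshold.swc, te=te.estimate, expected_change=expected_change,
            gap=gap, required_observed_change=required, adequate=False,
            message=(
                "the expected change does not exceed the SWC; no test, however "
                "reliable, can register a worthwhile improvement here"
            ),
        )
    adequate = te.estimate <= gap
    msg = "" if adequate else (
        f"TE {te.estimate:g} exceeds the gap {gap:g} between expected change "
        f"and SWC; success would require an observed change of at least "
        f"{required:g}, larger than typically expected"
    )
    return SensitivityReport(
        swc=threshold.swc, te=te.estimate, expected_change=expected_change,
        gap=gap, required_observed_change=required, adequate=adequate,
        message=msg,
    )
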