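"""Confidence intervals for true scores and true-score change.

A true-score CI is the observed score plus/minus a multiple of the typical
error.  The multiplier is a standard-normal two-sided quantile when TE is
treated as known (large reliability samples), or a Student-t quantile with
df = n - 1 when the uncertainty of a TE estimated from an n-subject
test--retest is to be propagated — the "adjusted" multipliers.

Change scores (post - pre) carry error from two observations, so their SD
is sqrt(2) * TE; change CIs use the same multipliers scaled by sqrt(2).
The practitioner's quick rule "observed change +/- TE" is a close
approximation to a 50% change CI (exact implied coverage
2*Phi(1/sqrt(2)) - 1 ~= 0.5205).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, InvalidInputError
from .measurement import SQRT2, TypicalError

#: Exact coverage of the "observed change +/- TE" rule under Gaussian error:
#: the change-score SD is sqrt(2)*TE, so +/-TE spans +/-1/sqrt(2) SDs.
APPROX_TE_RULE_COVERAGE = 2.0 * stats.norm.cdf(1.0 / math.sqrt(2.0)) - 1.0


class IntervalKind(str, enum.Enum):
    TRUE_SCORE = "true_score"
    TRUE_SCORE_CHANGE = "true_score_change"


@dataclass(frozen=True)
class Interval:
    """A two-sided symmetric confidence interval."""

    lower: float
    upper: float
    level: float
    center: float
    adjusted: bool
    df: int | None
    kind: IntervalKind
    note: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InvalidInputError(
                f"interval lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.adjusted and self.df is None:
            raise ConfigurationError("an adjusted interval must carry its df")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "center": self.center,
            "adjusted": self.adjusted,
            "df": self.df,
            "kind": self.kind.value,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:  # 1-dp display rendering
        return f"({self.lower:.1f}, {self.upper:.1f})"


def _check_level(level: float) -> None:
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"confidence level must lie in (0, 1), got {level!r}")


def ci_multiplier(level: float, n: int | None = None) -> float:
    """TE multiple for a two-sided CI of the given coverage.

    With ``n`` absent the TE is treated as known and the multiplier is the
    standard-normal quantile at (1 + level)/2.  With ``n`` given, the
    uncertainty of a TE estimated from n test--retest subjects (or n
    repeats) is propagated through a Student-t quantile with df = n - 1.
    Returned at full precision; rounding for display is the caller's concern.
    """
    _check_level(level)
    q = (1.0 + level) / 2.0
    if n is None:
        return float(stats.norm.ppf(q))
    if n < 2:
        raise InvalidInputError(f"sample-size adjustment needs n >= 2, got {n}")
    return float(stats.t.ppf(q, df=n - 1))


def _multiplier_for(te: TypicalError, level: float, adjust: bool) -> tuple[float, int | None]:
    if not adjust:
        return ci_multiplier(level), None
    if te.df is None:
        raise ConfigurationError(
            "a sample-size-adjusted interval was requested but the typical "
            f"error (method={te.method.value}) carries no degrees of freedom; "
            "supply the reliability study's n"
        )
    return ci_multiplier(level, n=te.df + 1), te.df


def true_score_ci(observed: float, te: TypicalError, level: float = 0.95,
                  adjust: bool = False) -> Interval:
    """CI for the true score underlying one observed score:
    observed +/- multiplier * TE."""
    if not np.isfinite(observed):
        raise InvalidInputError(f"observed score must be finite, got {observed!r}")
    mult, df = _multiplier_for(te, level, adjust)
    half = mult * te.estimate
    return Interval(
        lower=observed - half,
        upper=observed + half,
        level=level,
        center=observed,
        adjusted=adjust,
        df=df,
        kind=IntervalKind.TRUE_SCORE,
    )


def change_ci(pre_score: float, post_score: float, te: TypicalError,
              level: float = 0.95, adjust: bool = False) -> Interval:
    """CI for the true-score change across an intervention:
    (post - pre) +/- multiplier * sqrt(2) * TE."""
    for name, v in (("pre_score", pre_score), ("post_score", post_score)):
        if not np.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")
    mult, df = _multiplier_for(te, level, adjust)
    change = post_score - pre_score
    half = mult * SQRT2 * te.estimate
    return Interval(
        lower=change - half,
        upper=change + half,
        level=level,
        center=change,
        adjusted=adjust,
        df=df,
        kind=IntervalKind.TRUE_SCORE_CHANGE,
    )


def approx_change_ci(pre_score: float, post_score: float,
                     te: TypicalError) -> Interval:
    """The practitioner's quick change interval, (post - pre) +/- TE.

    Since the change-score SD is sqrt(2)*TE, the implied coverage is
    2*Phi(1/sqrt(2)) - 1 ~= 0.5205 — recorded as the interval's exact level
    rather than the nominal "about 50%".
    """
    for name, v in (("pre_score", pre_score), ("post_score", post_score)):
        if not np.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")
    change = post_score - pre_score
    return Interval(
        lower=change - te.estimate,
        upper=change + te.estimate,
        level=APPROX_TE_RULE_COVERAGE,
        center=change,
        adjusted=False,
        df=None,
        kind=IntervalKind.TRUE_SCORE_CHANGE,
        note="approximate +/-TE rule (close to a 50% change CI)",
    )
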