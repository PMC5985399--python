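"""Classical-test-theory data model and typical-error estimators.

A recorded test value (the *observed score*, ``O_s``) is modelled as a
hypothetical stable *true score* ``T_s`` perturbed by Gaussian measurement
error: ``O_s = T_s + eps``, with ``eps ~ N(0, TE^2)``.  The standard
deviation of repeated observations around a stable true score is the
*typical error* (TE).  This module estimates TE from

* repeated tests on a single individual (sample SD of the scores),
* a group test--retest (sample SD of the difference scores divided by
  sqrt(2), since Var(diff) = TE^2 + TE^2), or
* a published coefficient of variation (CV% = 100 * TE / mean).

TE is assumed homoscedastic across the population; a warning is logged
when the data hint otherwise (see :func:`estimate_te_group`).
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)

#: Column order required of a long-format study table.
STUDY_COLUMNS = ("subject_id", "arm", "time", "outcome", "value")

#: Kendall-tau threshold between |difference| and pair mean above which a
#: heteroscedasticity hint is logged.
HETEROSCEDASTICITY_TAU = 0.5


class Arm(str, enum.Enum):
    """Study arm of a measurement record."""

    INTERVENTION = "intervention"
    CONTROL = "control"
    NONE = "none"


class TEMethod(str, enum.Enum):
    """Provenance of a typical-error estimate."""

    INDIVIDUAL_REPEATS = "individual_repeats"
    GROUP_TEST_RETEST = "group_test_retest"
    LITERATURE_TE = "literature_te"
    LITERATURE_CV = "literature_cv"


@dataclass(frozen=True)
class MeasurementRecord:
    """One observed score: subject, arm, time point, outcome, value."""

    subject_id: str
    arm: Arm
    time: str
    outcome: str
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise InvalidInputError(
                f"non-finite value {self.value!r} for subject {self.subject_id!r}"
            )


@dataclass(frozen=True)
class TestRetestPairs:
    """Paired scores from a group test--retest over a period in which true
    scores are assumed stable."""

    __test__ = False  # domain type, not a pytest class

    subject_ids: tuple[str, ...]
    score_test1: tuple[float, ...]
    score_test2: tuple[float, ...]
    outcome: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(self.score_test1) != n or len(self.score_test2) != n:
            raise InvalidInputError(
                "subject_ids, score_test1 and score_test2 must have equal length "
                f"(got {n}, {len(self.score_test1)}, {len(self.score_test2)})"
            )
        if n < 2:
            raise InvalidInputError(f"need at least 2 test-retest pairs, got {n}")
        for scores in (self.score_test1, self.score_test2):
            arr = np.asarray(scores, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError("test-retest scores must all be finite")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def differences(self) -> np.ndarray:
        """Per-subject difference scores, test2 - test1."""
        return np.asarray(self.score_test2, float) - np.asarray(self.score_test1, float)


@dataclass(frozen=True)
class TypicalError:
    """A typical-error estimate together with its provenance.

    ``df`` (degrees of freedom, n - 1 for data-derived estimates) drives the
    small-sample adjustment of confidence-interval multipliers; literature
    values carry ``df=None`` unless the source's sample size is known.
    """

    estimate: float
    method: TEMethod
    n: int | None = None
    df: int | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate) or self.estimate < 0:
            raise InvalidInputError(
                f"typical error must be a finite non-negative number, got {self.estimate!r}"
            )
        if self.df is not None and self.df < 1:
            raise InvalidInputError(f"degrees of freedom must be >= 1, got {self.df}")

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "method": self.method.value,
            "n": self.n,
            "df": self.df,
            "units": self.units,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def estimate_te_individual(scores, *, units: str = "") -> TypicalError:
    """Estimate TE from repeated tests on a single individual.

    The estimate is the sample standard deviation (denominator k - 1) of the
    ``k >= 2`` observed scores, valid over a time frame in which the
    individual's true score is assumed stable.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidInputError(
            f"need at least 2 repeated scores, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("repeated scores must all be finite")
    k = int(arr.size)
    return TypicalError(
        estimate=float(np.std(arr, ddof=1)),
        method=TEMethod.INDIVIDUAL_REPEATS,
        n=k,
        df=k - 1,
        units=units,
    )


def estimate_te_group(pairs: TestRetestPairs) -> TypicalError:
    """Estimate TE from a group test--retest.

    Difference scores have variance TE^2 + TE^2 = 2 TE^2, so the estimate is
    the sample SD of the differences divided by sqrt(2); df = n - 1.

    The single-TE model assumes homoscedasticity across the group.  When the
    absolute differences correlate strongly with the pair means (Kendall
    tau > 0.5) a warning is logged — the error likely scales with the score
    and a single TE misrepresents it.
    """
    diffs = pairs.differences()
    sd_diff = float(np.std(diffs, ddof=1))
    means = (np.asarray(pairs.score_test1, float) + np.asarray(pairs.score_test2, float)) / 2.0
    abs_diffs = np.abs(diffs)
    if pairs.n >= 3 and np.ptp(abs_diffs) > 0 and np.ptp(means) > 0:
        tau = stats.kendalltau(means, abs_diffs).statistic
        if np.isfinite(tau) and tau > HETEROSCEDASTICITY_TAU:
            logger.warning(
                "absolute test-retest differences correlate with pair means "
                "(Kendall tau = %.2f > %.1f); the single-TE model may be "
                "inappropriate (heteroscedastic error)",
                tau,
                HETEROSCEDASTICITY_TAU,
            )
    return TypicalError(
        estimate=sd_diff / SQRT2,
        method=TEMethod.GROUP_TEST_RETEST,
        n=pairs.n,
        df=pairs.n - 1,
        units=pairs.units,
    )


def te_from_cv(cv_percent: float, observed_score: float, *,
               n: int | None = None, units: str = "") -> TypicalError:
    """Reconstruct a TE from a published coefficient of variation.

    ``TE = CV% * O_s / 100``.  CV is a ratio-scale statistic, so the
    observed score must be strictly positive.  Pass the source study's
    sample size via ``n`` to enable small-sample CI adjustment.
    """
    if not np.isfinite(cv_percent) or cv_percent < 0:
        raise InvalidInputError(f"cv_percent must be >= 0, got {cv_percent!r}")
    if not np.isfinite(observed_score) or observed_score <= 0:
        raise InvalidInputError(
            "CV is defined relative to the mean on a ratio scale; the observed "
            f"score must be > 0 (got {observed_score!r})"
        )
    return TypicalError(
        estimate=cv_percent * observed_score / 100.0,
        method=TEMethod.LITERATURE_CV,
        n=n,
        df=None if n is None else n - 1,
        units=units,
    )


def cv_from_te(te: TypicalError, mean_score: float) -> float:
    """Express a TE as a coefficient of variation, 100 * TE / mean."""
    if not np.isfinite(mean_score) or mean_score <= 0:
        raise InvalidInputError(f"mean_score must be > 0, got {mean_score!r}")
    return 100.0 * te.estimate / mean_score


def pairs_from_records(study: pd.DataFrame, outcome: str, *,
                       time1: str = "test1", time2: str = "test2",
                       units: str = "") -> TestRetestPairs:
    """Assemble :class:`TestRetestPairs` from a long-format study table.

    Subjects missing either time point are dropped with a logged count; the
    resulting ``n`` reflects complete pairs only.
    """
    sub = study[study["outcome"] == outcome]
    if sub.empty:
        raise InvalidInputError(f"no records for outcome {outcome!r}")
    wide = sub.pivot_table(index="subject_id", columns="time", values="value",
                           aggfunc="first")
    for t in (time1, time2):
        if t not in wide.columns:
            raise InvalidInputError(
                f"no records at time {t!r} for outcome {outcome!r}"
            )
    complete = wide[[time1, time2]].dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("dropped %d subject(s) with an incomplete test-retest pair",
                       dropped)
    if len(complete) < 2:
        raise InvalidInputError(
            f"need at least 2 complete pairs, got {len(complete)}"
        )
    return TestRetestPairs(
        subject_ids=tuple(str(s) for s in complete.index),
        score_test1=tuple(float(v) for v in complete[time1]),
        score_test2=tuple(float(v) for v in complete[time2]),
        outcome=outcome,
        units=units,
    )
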