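import numpy as np
import pytest

from truescore import Arm, StudyDesign, TEMethod, TypicalError, simulate_study


@pytest.fixture
def carnosine_te() -> TypicalError:
    """Muscle-carnosine typical error, 0.52 mmol/kg dm, from an n=20
    test-retest."""
    return TypicalError(estimate=0.52, method=TEMethod.GROUP_TEST_RETEST,
                        n=20, df=19, units="mmol/kg dm")


@pytest.fixture
def literature_te():
    def make(estimate: float, n: int | None = None) -> TypicalError:
        return TypicalError(estimate=estimate, method=TEMethod.LITERATURE_TE,
                            n=n, df=None if n is None else n - 1)
    return make


@pytest.fixture
def small_study():
    """A tiny deterministic two-arm pre/post study table."""
    study, truth = simulate_study(StudyDesign(n_per_arm=6, seed=7))
    return study, truth


def sample_sd(values) -> float:
    """Independent two-pass sample SD (denominator n-1), used as the oracle
    against library variance routines."""
    values = list(float(v) for v in values)
    n = len(values)
    mean = sum(values) / n
    return (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
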