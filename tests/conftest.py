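import numpy as np
import pytest

from ntpet.kinetics import (FrameSchedule, TracerKineticParams,
                            simulate_reference_tac)
from ntpet.lpntpet import build_basis_library


@pytest.fixture(scope="session")
def sched():
    return FrameSchedule.uniform()


@pytest.fixture(scope="session")
def tracer():
    return TracerKineticParams()


@pytest.fixture(scope="session")
def tracer_ode():
    return TracerKineticParams(mode="full-ode")


@pytest.fixture(scope="session")
def ref(tracer, sched):
    return simulate_reference_tac(tracer, sched)


@pytest.fixture(scope="session")
def lib(sched):
    return build_basis_library(sched=sched)
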