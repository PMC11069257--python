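import numpy as np
import pytest

from affinichrom import (
    Chromatogram,
    InjectionContext,
    ReducedPeak,
    ThomasParams,
    simulate_peak,
    thomas_profile,
)

# Retention times (minutes) of the reference drugs on the two receptor
# columns, with the void marker at 1.9 min; ground truth for the
# classification logic.
DRUG_RETENTION = {
    # analyte: (tR two-point, tR single-point, expected label)
    "atropine": (10.0, 7.4, "antagonist-like"),
    "pirenzepine": (6.0, 5.1, "antagonist-like"),
    "cevimeline": (2.2, 5.8, "agonist-like"),
    "pilocarpine": (3.2, 4.2, "agonist-like"),
}
T0_MIN = 1.9


@pytest.fixture(scope="session")
def moderate_params() -> ThomasParams:
    """A well-conditioned overloaded peak used across fitting tests."""
    return ThomasParams(1.0, 4.0, 0.05, 0.2)


@pytest.fixture(scope="session")
def moderate_peak(moderate_params) -> ReducedPeak:
    x = np.arange(0.005, 12.0, 0.005)
    return ReducedPeak(x, thomas_profile(x, moderate_params))


@pytest.fixture(scope="session")
def simulated_chromatogram(moderate_params) -> Chromatogram:
    return simulate_peak(moderate_params, t0_min=T0_MIN)


@pytest.fixture()
def atropine_context() -> InjectionContext:
    """Injection conditions of the reference experiments: 10 uL at
    0.2 mL/min on a 1.9-min-void system."""
    return InjectionContext(concentration=4e-4, injection_volume=10e-6,
                            flow_rate=0.2, t0=T0_MIN)
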