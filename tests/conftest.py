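import numpy as np
import pytest

from gobysurv.survival import Centering, HaulObservation, SurvivalParams


@pytest.fixture
def reference_params() -> SurvivalParams:
    """Fleet-level posterior medians used for prediction examples."""
    from gobysurv.survival import REFERENCE_ESTIMATES

    return REFERENCE_ESTIMATES


@pytest.fixture
def reference_centering() -> Centering:
    from gobysurv.survival import REFERENCE_CENTERING

    return REFERENCE_CENTERING


@pytest.fixture
def three_hauls() -> list[HaulObservation]:
    """Tiny two-trip fixture for likelihood oracles."""
    return [
        HaulObservation("tA", "tA-h0", 200, 190, 90, 4.0, 22.0, 15.2, 17.0, 6.0),
        HaulObservation("tA", "tA-h1", 150, 140, 80, 3.0, 28.0, 15.9, 18.0, 7.0),
        HaulObservation("tB", "tB-h0", 180, 160, 50, 6.0, 31.0, 16.1, 18.5, 5.5),
    ]


@pytest.fixture
def small_params() -> SurvivalParams:
    return SurvivalParams(
        alpha0=0.3, alpha1=0.01, alpha2=0.09,
        beta0=3.0, beta1=0.05, beta2=-0.5,
        tau=2.5, sigma1=0.2, sigma2=1.0,
        rnd1={"tA": 0.05, "tB": -0.1},
        rnd2={"tA": 0.3, "tB": -0.2},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
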