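import numpy as np
import pytest

from sepeffects import DGPParams, PointDataset

# base coefficients of the simulation study: (pL, pU, th0..th3) fixed,
# U-terms off unless a test turns them on
BASE_THETA = (-1.0, -2.0, 1.0, 3.0, 0.0, 0.0, 0.0)


@pytest.fixture
def base_params() -> DGPParams:
    return DGPParams(pL=0.1, pU=0.5, theta=BASE_THETA, beta=(-1, 0.5, 0.5, 0, 0, 0, 0))


@pytest.fixture
def u_dependent_params() -> DGPParams:
    """Both processes depend on the unmeasured U: non-identification error present."""
    return DGPParams(
        pL=0.5, pU=0.5,
        theta=(-1, -2, 1, 3, 1.0, -0.5, 0.5),
        beta=(-1, 0.5, 0.5, 0, 0.8, -0.4, 0.3),
    )


@pytest.fixture
def toy_t1() -> PointDataset:
    """8-record toy with no covariate, hand-traceable weighted estimates.

    Arm A=1 records (D,Y): (0,1),(0,0),(0,0),(1,0);
    arm A=0 records (D,Y): (0,1),(0,1),(1,0),(1,0).
    Saturated nuisance: pi~(1,.)=1/4, pi~(0,.)=1/2.
    """
    a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    d = np.array([0, 0, 0, 1, 0, 0, 1, 1])
    y = np.array([1, 0, 0, 0, 1, 1, 0, 0])
    z = np.zeros(8, dtype=int)
    return PointDataset(u=z, l=z, a=a, d=d, y=y)


def random_params(rng: np.random.Generator, pU: float | None = None,
                  coef_scale: float = 1.5) -> DGPParams:
    """A random full parameterization for property tests."""
    return DGPParams(
        pL=rng.uniform(0.05, 0.95),
        pU=rng.uniform(0.05, 0.95) if pU is None else pU,
        theta=tuple(rng.uniform(-coef_scale, coef_scale, 7)),
        beta=tuple(rng.uniform(-coef_scale, coef_scale, 7)),
        pA=0.5,
    )
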