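import numpy as np
import pytest

from nanorapids.features import DetectionParams
from nanorapids.plate import PlateLayout
from nanorapids.simulate import SyntheticRunSpec
from nanorapids.spectra import Scan


@pytest.fixture
def layout() -> PlateLayout:
    return PlateLayout()


@pytest.fixture
def params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def short_spec() -> SyntheticRunSpec:
    """A 10-minute run spec used to keep simulation-backed tests quick."""
    return SyntheticRunSpec(run_length=10.0, seed=11,
                            layout=PlateLayout(wells_per_sample=100))


def gaussian_scans(
    mz: float,
    rt: float,
    apex: float,
    sigma: float = 0.06,
    n_scans: int = 120,
    dt: float = 1.25 / 60.0,
    n_carbons: int = 0,
) -> list[Scan]:
    """A noise-free MS1 scan series holding one Gaussian elution peak."""
    scans = []
    for k in range(n_scans):
        t = k * dt
        h = apex * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
        mzs, ints = [], []
        if h >= 1.0:
            mzs.append(mz)
            ints.append(h)
            if n_carbons:
                mzs.append(mz + 1.00335)
                ints.append(h * 0.011 * n_carbons)
        scans.append(Scan(1, t, np.array(mzs), np.array(ints)))
    return scans
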