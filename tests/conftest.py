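import numpy as np
import pytest

from dwimotion.motion_descriptors import MotionSummary
from dwimotion.pipelines import ScanRecord
from dwimotion.rigid_kinematics import BrainMask, make_spherical_mask


@pytest.fixture(scope="session")
def small_mask() -> BrainMask:
    """Brain-scale but cheap spherical mask for kinematics tests."""
    return make_spherical_mask(radius=80.0, spacing=16.0)


@pytest.fixture(scope="session")
def random_mask() -> BrainMask:
    """500 random voxel coordinates inside a 90 mm box."""
    rng = np.random.default_rng(20240117)
    return BrainMask(rng.uniform(-90.0, 90.0, size=(500, 3)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def record_factory():
    """Factory for ScanRecords with a minimal consistent MotionSummary."""

    def make(subject="s1", session="ses1", scan_index=1, mean=0.1, median=None,
             tr=3.0, cohort="SYN", age=50.0, sex="F", dx="CN"):
        median = mean * 0.9 if median is None else median
        summary = MotionSummary(
            mean_rel_mm_per_vol=mean,
            median_rel_mm_per_vol=median,
            mean_rel_mm_per_min=mean * 60.0 / tr,
            trans_rate_per_vol=np.zeros(3),
            trans_rate_per_min=np.zeros(3),
            rot_rate_per_vol=np.zeros(3),
            rot_rate_per_min=np.zeros(3),
            cumulative_mm=np.linspace(0.0, 9.0 * mean, 10),
            tr_seconds=tr,
        )
        return ScanRecord(subject=subject, session=session, scan_index=scan_index,
                          cohort=cohort, age=age, sex=sex, dx=dx, summary=summary)

    return make
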