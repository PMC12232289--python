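import numpy as np
import pytest

from ogttkit import (
    OGTTSeries,
    SubjectRecord,
    standardize_params,
)

OBS_GRID = np.array([0, 10, 20, 30, 60, 90, 120, 150, 180], dtype=float)


@pytest.fixture(scope="session")
def ref_subject():
    return SubjectRecord("ref", age=12.0, sex="M", weight=80.0, height=155.0, ahi=3.0)


@pytest.fixture(scope="session")
def obese_params(ref_subject):
    return standardize_params(ref_subject, "obese")


@pytest.fixture()
def flat_series():
    """Flat glucose/insulin/C-peptide curves on the canonical grid."""
    n = OBS_GRID.size
    return OGTTSeries(
        subject_id="flat",
        times=OBS_GRID,
        glucose=np.full(n, 90.0),
        insulin=np.full(n, 60.0),  # 10 uU/mL
        cpeptide=np.full(n, 700.0),
    )


def make_series(glucose, insulin, cpeptide, times=OBS_GRID, subject_id="toy"):
    return OGTTSeries(
        subject_id=subject_id,
        times=np.asarray(times, float),
        glucose=np.asarray(glucose, float),
        insulin=np.asarray(insulin, float),
        cpeptide=np.asarray(cpeptide, float),
    )
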