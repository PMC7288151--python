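import numpy as np
import pytest

import sheettopo as st

#: printed 5th-order calibration polynomial of the instrument (dn(dz), px)
EQ8_COEFFS = [-0.74, 0.29, 4.52e-5, -5.33e-7, 1.06e-9, -6.26e-13]


@pytest.fixture(scope="session")
def eq8_model() -> st.CalibrationModel:
    """Calibration model with the instrument's published coefficients."""
    return st.CalibrationModel(
        coefficients=np.asarray(EQ8_COEFFS),
        r_squared=0.9996,
        valid_z_range=(0.0, 750.0),
    )


@pytest.fixture(scope="session")
def linear_model() -> st.CalibrationModel:
    """Pure linear model matching the synthetic renderer's forward map."""
    return st.CalibrationModel.from_linear_slope(0.29, 0.0, (0.0, 750.0))


@pytest.fixture
def small_flat_scene() -> st.SceneSpec:
    return st.preset_scene("flat", seed=42, speckle_contrast=0.15)


def small_field(rows: int) -> float:
    """Physical field height (um) of a reduced image at the default scale."""
    return rows * 5000.0 / 896.0
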