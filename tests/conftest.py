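import numpy as np
import pytest

from adchist import MixtureSpec, make_subject_volume


@pytest.fixture(scope="session")
def reference_spec() -> MixtureSpec:
    """A well-separated two-component mixture used throughout the suite."""
    return MixtureSpec(f=0.6, mu_L=1.0, sigma_L=0.15, mu_H=1.9, sigma_H=0.25)


@pytest.fixture(scope="session")
def subject(reference_spec):
    """One deterministic synthetic subject (32³ grid, radius-8 lesion)."""
    return make_subject_volume(reference_spec, seed=42, subject_id="fixture")


@pytest.fixture(scope="session")
def whole_brain(subject) -> np.ndarray:
    return np.ones(subject.roi_mask.shape, dtype=bool)
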