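import numpy as np
import pytest

from pseudotract.phantom import PhantomSpec, generate_subject
from pseudotract.pipeline import derive_subject


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, unposed default-geometry phantom subject."""
    spec = PhantomSpec(noise_sigma=0.0, pose_jitter_deg=0.0, pose_jitter_mm=0.0)
    return generate_subject(spec, subject_seed=1)


@pytest.fixture(scope="session")
def clean_derived(clean_subject):
    """Fitted maps + whole-brain tractogram for the clean subject."""
    return derive_subject(clean_subject)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
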