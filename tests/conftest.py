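import numpy as np
import pytest
from hypothesis import settings

from fedusim.synthdata import DatasetSpec, ImageSample, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

_SHARED_PIXELS = np.full((16, 16), 0.5)


def make_fake_samples(n_normal, n_benign, n_malignant):
    """Lightweight samples sharing one pixel buffer, for label-level tests."""
    out = []
    for label, n in (("normal", n_normal), ("benign", n_benign),
                     ("malignant", n_malignant)):
        out.extend(ImageSample(f"{label}-{i:05d}", _SHARED_PIXELS, label)
                   for i in range(n))
    return out


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 real generated images (10 per class) at 32x32."""
    spec = DatasetSpec(10, 10, 10, image_size=32, seed=1)
    return spec, generate_dataset(spec)
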