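import numpy as np
import pytest

from cortseg.network import UNetMinusSpec
from cortseg.phantom import PhantomConfig, generate_phantom

#: phantom sized for desk-scale training: big, well-separated lesions.
TRAINABLE_CONFIG = dict(
    dims=(48, 48, 48),
    n_wml=6,
    n_cl=2,
    size_distribution={"WML": (60.0, 0.7), "CL": (40.0, 0.6)},
)


def make_trainable_phantom(seed, subject_id=None, site="site1"):
    cfg = PhantomConfig(seed=seed, **TRAINABLE_CONFIG)
    return generate_phantom(cfg, subject_id or f"p{seed}", site=site)


@pytest.fixture(scope="session")
def tiny_spec():
    """Filter counts divided by 8; geometry identical to the full network."""
    return UNetMinusSpec().scaled(8)


@pytest.fixture(scope="session")
def micro_spec():
    """Near-minimal channel widths, for gradient and equivariance checks."""
    return UNetMinusSpec(encoder_filters=(2, 2, 2, 2, 2), bottleneck_expand=3,
                         decoder_filters=(2, 2, 2, 2))


@pytest.fixture(scope="session")
def small_truth():
    """One light 40^3 phantom shared by read-only tests."""
    cfg = PhantomConfig(dims=(40, 40, 40), n_wml=3, n_cl=1, seed=5)
    return generate_phantom(cfg, "small", site="siteA")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
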