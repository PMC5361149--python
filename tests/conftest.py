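import numpy as np
import pytest

from octatten import (
    ALineProfile,
    NormalizedSignal,
    ReferenceProfile,
    forward_model,
)

#: Axial pixel size of a 1.8 mm depth range sampled at 2048 px.
DZ = 1.8 / 2048


def exponential_signal(mu_rel: float, window_mm: float, dz: float = DZ,
                       amplitude: float = 1.0) -> NormalizedSignal:
    """Noiseless normalized signal decaying at the round-trip rate 2*mu_rel."""
    n = int(np.floor(window_mm / dz))
    z = np.arange(n) * dz
    return NormalizedSignal(amplitude * np.exp(-2.0 * mu_rel * z), dz, n * dz)


@pytest.fixture
def dz() -> float:
    return DZ


@pytest.fixture
def reference(dz) -> ReferenceProfile:
    """Noiseless reference phantom profile, mu_ref = 1/mm, surface at 0."""
    profile = forward_model(
        z0=0.0, A=2.0, mu_bs=1.0, mu_ext=1.0, psf=None, dz=dz, n=1400
    )
    return ReferenceProfile(profile=profile, mu_ref=1.0, surface_index=0)
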