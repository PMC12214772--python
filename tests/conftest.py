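import numpy as np
import pytest

from pongscope.phantom import BoutSpec, PhantomConfig, build_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def still_phantom():
    """Motionless phantom (no bouts, no rotation/deformation)."""
    return build_phantom(
        PhantomConfig(bouts=(), start_pause=4.0, z_bob_amplitude=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def crawling_phantom():
    """One forward bout of 8 strides at the default 0.8 mm/s peak speed."""
    return build_phantom(
        PhantomConfig(
            bouts=(BoutSpec("forward", n_strides=8),), start_pause=1.0, seed=3
        )
    )


def mixture_photons(phantom, n, rng, channel="red"):
    """Draw photon locations from the phantom's emitter mixture at rest.

    Stand-in for a fully covered scan of the motionless phantom: photon
    density is the fluorophore mixture convolved with the PSF.
    """
    amp = phantom.rate_red if channel == "red" else phantom.rate_green
    p = amp / amp.sum()
    e = rng.choice(len(phantom.positions), n, p=p)
    s_lat = np.sqrt(phantom.sigma[e] ** 2 + phantom.cfg.psf_sigma_lateral**2)
    s_ax = np.sqrt(phantom.sigma[e] ** 2 + phantom.cfg.psf_sigma_axial**2)
    jitter = np.stack(
        [rng.normal(0, s_lat), rng.normal(0, s_lat), rng.normal(0, s_ax)], axis=1
    )
    return phantom.positions[e] + jitter
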