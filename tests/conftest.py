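import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import duospect as ds
from duospect.phantom import default_organs

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    return ds.build_phantom(ds.PhantomSpec())


@pytest.fixture(scope="session")
def default_protocol():
    return ds.AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_setup():
    """Half-resolution phantom (same anatomy in mm) for fast tests."""
    spec = ds.PhantomSpec(grid_shape=(32, 32, 24), spacing=(9.6, 9.6, 9.6))
    protocol = ds.AcquisitionProtocol(
        n_angles=60, detector_shape=(32, 24), pixel_spacing_mm=9.6
    )
    return {"spec": spec, "phantom": ds.build_phantom(spec), "protocol": protocol}


@pytest.fixture(scope="session")
def tiny_setup():
    """Very coarse phantom for statistical (many-replicate) checks."""
    spec = ds.PhantomSpec(grid_shape=(16, 16, 12), spacing=(19.2, 19.2, 19.2))
    protocol = ds.AcquisitionProtocol(
        n_angles=12, detector_shape=(16, 12), pixel_spacing_mm=19.2
    )
    return {"spec": spec, "phantom": ds.build_phantom(spec), "protocol": protocol}


@pytest.fixture(scope="session")
def standard_noiseless(default_phantom, default_protocol):
    """Noiseless acquisition + both reconstructions on the standard phantom."""
    proj = ds.simulate_acquisition(default_phantom, default_protocol, seed=1, noise=False)
    recon_ho = ds.reconstruct_ho(proj, default_phantom.mu_81, default_protocol, ds.ReconConfig())
    recon_tc = ds.reconstruct_tc(proj, default_phantom.mu_140, default_protocol, ds.ReconConfig())
    return {
        "phantom": default_phantom,
        "protocol": default_protocol,
        "proj": proj,
        "recon_ho": recon_ho,
        "recon_tc": recon_tc,
    }
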