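import numpy as np
import pytest

from cordscan.image_model import GrayImage
from cordscan.intensity_em import GaussianComponent, GmmFit
from cordscan.phantom import PhantomSpec, generate
from cordscan.pipeline import run_pipeline


def make_fit(iso_band=(55, 130), air_mean=5.0, hypo_mean=31.0,
             iso_mean=80.0, hyper_mean=180.0) -> GmmFit:
    """A hand-built classification table for tests that need pixel classes
    without running EM: iso inside ``iso_band``, air below the air mean,
    hyper above the band, hypo in between."""
    comps = [GaussianComponent(air_mean, 4.0, 0.4, "air"),
             GaussianComponent(hypo_mean, 16.0, 0.1, "hypo"),
             GaussianComponent(iso_mean, 36.0, 0.3, "iso"),
             GaussianComponent(hyper_mean, 100.0, 0.2, "hyper")]
    g = np.arange(256)
    cls = np.full(256, "hypo", dtype="<U5")
    cls[g < air_mean] = "air"
    cls[(g >= iso_band[0]) & (g <= iso_band[1])] = "iso"
    cls[g > iso_band[1]] = "hyper"
    fit = GmmFit(comps)
    fit.class_of_gray = cls
    fit.iso_lower, fit.iso_upper = iso_band
    return fit


def gray(arr) -> GrayImage:
    return GrayImage(np.asarray(arr))


@pytest.fixture(scope="session")
def default_phantom():
    return generate(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_result(default_phantom):
    series, _ = default_phantom
    return run_pipeline(series)


@pytest.fixture(scope="session")
def shallow_phantom():
    """Bodies shallow enough (22 px) that the f6 window spans them, so the
    truncated-ALL path hugs the anterior edge and regions stay whole."""
    return generate(PhantomSpec(seed=2, vb_depth=22))


@pytest.fixture(scope="session")
def shallow_result(shallow_phantom):
    series, _ = shallow_phantom
    return run_pipeline(series)
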