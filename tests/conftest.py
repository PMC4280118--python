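import numpy as np
import pytest

from petidif.curves import FrameSchedule, TimeActivityCurve
from petidif.phantom import PhantomSpec, generate_phantom


def gamma_bolus(t, amplitude=80.0, t_peak=30.0, alpha=3.0):
    """Smooth (C^2 at onset) gamma-variate bolus with a slow washout tail."""
    t = np.asarray(t, dtype=float)
    main = np.where(t > 0,
                    amplitude * (t / t_peak) ** alpha
                    * np.exp(alpha * (1.0 - t / t_peak)), 0.0)
    tail = np.where(t > 0, 6.0 * (1.0 - np.exp(-0.02 * t)), 0.0)
    return main + tail * np.exp(-2e-4 * t)


@pytest.fixture(scope="session")
def smooth_bolus_tac():
    t = np.arange(0.0, 300.0, 0.5)
    return TimeActivityCurve(t, gamma_bolus(t))


@pytest.fixture(scope="session")
def ideal_phantom():
    """Uniform vascular voxels, no PSF, no noise: the exactness limit."""
    spec = PhantomSpec(noise_scale=0.0, psf_fwhm=0.0,
                       vessel_profile="uniform", seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def realistic_phantom():
    """Graded vessels + PSF blur + count-scaled noise (default conditions)."""
    spec = PhantomSpec(seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def short_schedule():
    return FrameSchedule.hrrt_osem(max_time_s=3600.0)
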