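import numpy as np
import pytest

from enzkin import (
    KineticParameters,
    OpticalConstants,
    ProgressCurve,
    TraceSetSpec,
    generate_trace_set,
)

# Wild-type enzyme / preferred-nucleoside parameter regime used throughout:
# micromolar Km, fast turnover, product inhibition of the same order as Km.
WT_PARAMS = KineticParameters(km=6.2e-5, kcat=157.0, ki=1.3e-4)

# Slow-turnover regime (a poorly hydrolysed prodrug substrate): no
# detectable product inhibition, kcat three orders of magnitude down.
SLOW_PARAMS = KineticParameters(km=7.0e-4, kcat=0.016)


@pytest.fixture(scope="session")
def wt_params():
    return WT_PARAMS


@pytest.fixture(scope="session")
def slow_params():
    return SLOW_PARAMS


@pytest.fixture(scope="session")
def noiseless_wt_traces():
    spec = TraceSetSpec(params=WT_PARAMS, seed=11, noise_sd_au=0.0, n_points=200)
    return list(generate_trace_set(spec))


@pytest.fixture()
def concentration_curve():
    """A clean concentration-unit curve for unit-level fitting checks."""
    params = KineticParameters(km=1e-4, kcat=10.0)
    s0, e0 = 2e-4, 1e-8
    times = np.linspace(0.0, 5 * (params.km + s0) / (params.kcat * e0), 150)
    from enzkin import substrate_timecourse

    s = substrate_timecourse(params, s0, e0, times)
    return ProgressCurve(
        curve_id="unit__c0", times=times, signal=s, s0=s0, e0=e0, signal_units="M"
    )


@pytest.fixture(scope="session")
def default_optics():
    return OpticalConstants(eps_s=1e4, eps_p=1e3)
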