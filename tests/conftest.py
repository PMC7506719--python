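import numpy as np
import pytest

from ppgox import (ExtractionConfig, SiteParams, SubjectParams, make_protocol,
                   moving_average, simulate_subject)
from ppgox.extraction import SpO2Series


@pytest.fixture(scope="session")
def default_timeline():
    return make_protocol()


def noiseless_params(resting_spo2=97.0, desat_depth=0.0, **kwargs) -> SubjectParams:
    """Subject with all stochastic components switched off."""
    site_kwargs_ear = dict(ac_amplitude=300.0, transit_delay=4.35, desat_depth=desat_depth)
    site_kwargs_fin = dict(ac_amplitude=705.0, transit_delay=16.75, desat_depth=desat_depth)
    return SubjectParams(
        resting_spo2=resting_spo2,
        noise_sd=0.0,
        drift_amplitude=0.0,
        respiration_mod_depth=0.0,
        site_params={"ear": SiteParams(**site_kwargs_ear),
                     "finger": SiteParams(**site_kwargs_fin)},
        **kwargs,
    )


@pytest.fixture(scope="session")
def noiseless_subject(default_timeline):
    """One noiseless constant-SpO2 subject (both sites) plus ground truth."""
    return simulate_subject(noiseless_params(), default_timeline)


@pytest.fixture(scope="session")
def breathhold_subject(default_timeline):
    """Noiseless subject with real desaturation dips."""
    return simulate_subject(noiseless_params(desat_depth=6.0), default_timeline)


def make_spo2_series(t: np.ndarray, spo2: np.ndarray, fs: float,
                     smooth_window_s: float = 3.0) -> SpO2Series:
    """Wrap a bare SpO2 trace in an SpO2Series for delay-stage tests."""
    cfg = ExtractionConfig(smooth_window_s=smooth_window_s)
    zeros = np.zeros_like(spo2)
    return SpO2Series(
        t=t, spo2=spo2,
        spo2_smooth=moving_average(spo2, fs, smooth_window_s),
        R=zeros, dc_red=zeros, dc_ir=zeros, envelopes={}, fs=fs, config=cfg,
    )
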