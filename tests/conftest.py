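import math

import numpy as np
import pytest

from renaldosim.cohort import CohortConfig
from renaldosim.curves import ACTIVITY, DOSE_RATE, TimeSample
from renaldosim.methods import KidneyCycleRecord

LAM_REF = 0.0134331  # h^-1, effective half-time 51.6 h


@pytest.fixture
def rng():
    return np.random.default_rng(20180705)


@pytest.fixture
def small_cohort_config():
    """A small cohort for fast end-to-end tests."""
    return CohortConfig(n_patients=8, seed=11)


def monoexp_planar_series(a24, lam, times=(1.0, 24.0, 48.0, 168.0), first_ratio=None):
    """Planar activity samples lying exactly on the piecewise model: the tail
    is mono-exponential from 24 h; the first sample is ``first_ratio`` times
    the 24-h value (default: on the backward mono-exponential)."""
    out = []
    for t in times:
        if t < 24.0:
            v = a24 * (first_ratio if first_ratio is not None else math.exp(-lam * (t - 24.0)))
        else:
            v = a24 * math.exp(-lam * (t - 24.0))
        out.append(TimeSample(t, v, ACTIVITY))
    return tuple(out)


def make_record(
    patient_id="pt001",
    cycle=1,
    side="left",
    a24=100.0,
    lam=LAM_REF,
    r24=0.04,
    t_s=24.0,
    times=(1.0, 24.0, 48.0, 168.0),
    first_ratio=None,
    a_inj=7400.0,
    mass=150.0,
    lambda_borrowed=False,
):
    """A noise-free kidney-cycle record on an exact piecewise curve."""
    spect = TimeSample(t_s, r24 * math.exp(-lam * (t_s - 24.0)), DOSE_RATE)
    return KidneyCycleRecord(
        patient_id=patient_id,
        cycle_index=cycle,
        side=side,
        planar_series=monoexp_planar_series(a24, lam, times, first_ratio),
        spect_sample=spect,
        injected_activity=a_inj,
        kidney_mass=mass,
        lambda_borrowed=lambda_borrowed,
    )


def make_pair(**kw):
    left = make_record(side="left", **kw)
    right = make_record(side="right", **kw)
    return left, right
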