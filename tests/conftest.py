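"""Shared fixtures: compact session templates and quick builders.

Simulated sessions used across the suite keep the two-puff structure but
shorten the habituation and inter-stimulus interval so hundreds of cohorts
fit in a normal test run; tests of recovery accuracy use the full-length
template explicitly.
"""

import numpy as np
import pytest

import photom as ph

# compact two-puff template: 20 s habituation, 25 s ISI
SHORT_EVENTS, SHORT_DURATION = ph.air_puff_events(
    habituation_s=20.0, isi_s=25.0, first_offset_s=10.0, tail_s=15.0
)
TIMEPOINTS = list(ph.AIR_PUFF_TIMEPOINTS)


@pytest.fixture(scope="session")
def short_events():
    return list(SHORT_EVENTS)


@pytest.fixture()
def short_params():
    return ph.SignalParams(fs=100.0, duration_s=SHORT_DURATION, seed=0)


@pytest.fixture(scope="session")
def fast_preprocess():
    # sessions are generated at 100 Hz already; skip decimation
    return ph.PreprocessParams(downsample_factor=1)


def make_raw(
    signal_465,
    signal_405=None,
    fs=20.0,
    events=(),
    stimulus_kind="auditory_only",
    **labels,
):
    """Minimal valid RawSession around explicit sample arrays."""
    signal_465 = np.asarray(signal_465, dtype=float)
    if signal_405 is None:
        signal_405 = signal_465.copy()
    defaults = dict(
        subject_id="s1", sex="female", treatment="vehicle", timepoint="baseline"
    )
    defaults.update(labels)
    return ph.RawSession(
        stimulus_kind=stimulus_kind,
        sampling_rate=fs,
        t0=0.0,
        signal_465=signal_465,
        signal_405=np.asarray(signal_405, dtype=float),
        event_times=np.asarray(events, dtype=float),
        enforce_event_count=False,
        **defaults,
    )


def make_dff(dff, fs=100.0, events=(), t0=0.0, **labels):
    defaults = dict(subject_id="s1", timepoint="baseline")
    defaults.update(labels)
    return ph.DffTrace(
        sampling_rate=fs,
        t0=t0,
        dff=np.asarray(dff, dtype=float),
        event_times=np.asarray(events, dtype=float),
        fit=(1.0, 0.0),
        qc=0.0,
        **defaults,
    )


def make_binned(bins, n_pre=10, normalized=False, **labels):
    defaults = dict(subject_id="s1", timepoint="baseline")
    defaults.update(labels)
    return ph.BinnedTrace(
        bins=np.asarray(bins, dtype=float), n_pre=n_pre, normalized=normalized,
        **defaults,
    )
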