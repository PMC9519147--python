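import numpy as np
import pytest

from cctype.core import ContinuousRecording
from cctype import synth


def tone_recording(freq, fs=1000.0, duration=20.0, amplitude=1.0, channel="c0"):
    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return ContinuousRecording(x[None, :], fs, [channel], {channel: "P0"})


@pytest.fixture(scope="session")
def default_session():
    """One full default synthetic session: trials, clean units, injected artifacts.

    Shared across tests that exercise the paper-scale population (91 clean
    units, 3 planted outliers, 1 duplicate).
    """
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(1234).spawn(3)]
    trials = synth.generate_trial_table(seed=seeds[0])
    duration = trials.end_time()
    clean, gt = synth.generate_units(trials, seed=seeds[1])
    units, gt = synth.inject_unit_artifacts(clean, duration, ground_truth=gt, seed=seeds[2])
    return {"trials": trials, "duration": duration, "clean": clean, "units": units, "gt": gt}
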