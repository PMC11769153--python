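import warnings

import numpy as np
import pytest

import restmdd as rm

warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def short_protocol():
    """Desk-scale protocol: five 10 s resting periods, brief photic/HV."""
    return rm.make_default_protocol(total_resting_seconds=50.0,
                                    photic_seconds=2.0,
                                    hyperventilation_seconds=5.0)


@pytest.fixture(scope="session")
def subject():
    return rm.SubjectProfile("s1", "MDD", 40, "F", seed=7)


@pytest.fixture(scope="session")
def recording(subject, short_protocol):
    """One clean synthetic recording under the short protocol."""
    return rm.synth_recording(subject, protocol=short_protocol)


@pytest.fixture(scope="session")
def segments(recording):
    return rm.extract_resting_periods(recording)


def periodogram_band_fraction(x, fs, lo, hi):
    """Fraction of periodogram power inside [lo, hi] Hz (test oracle)."""
    spec = np.abs(np.fft.rfft(np.asarray(x, float))) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return spec[(freqs >= lo) & (freqs <= hi)].sum() / spec.sum()
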