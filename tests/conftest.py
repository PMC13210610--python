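import numpy as np
import pytest

from rowstab import AngularVelocitySeries


@pytest.fixture
def sine_series():
    """sin(2*pi*(t - 0.25)/2) on [0, 10] at 1 kHz: period 2 s, upward zero
    crossings at 0.25, 2.25, ..., 8.25 s."""
    t = np.arange(0, 10.0, 0.001)
    return AngularVelocitySeries(np.sin(2 * np.pi * (t - 0.25) / 2), dt=0.001)


@pytest.fixture
def ten_second_grid():
    """10 s at 1 kHz: integer frequencies are bin-aligned (0.1 Hz bins)."""
    return np.arange(0, 10.0, 0.001)


def write_csv(path, header, rows, sep=","):
    with open(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for row in rows:
            fh.write(sep.join(str(x) for x in row) + "\n")
    return path
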