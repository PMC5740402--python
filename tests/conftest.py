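import numpy as np
import pytest

from karyodraw.measure_core import (
    ChromosomeMeasurement,
    Metaphase,
    Polyline,
    place_centromere,
)


def straight_measurement(name, length_px, ci_percent=None, y=0.0):
    """A 2-vertex horizontal trace: cheap, exact arc length."""
    m = ChromosomeMeasurement(
        name=name, fragments=[Polyline([(0.0, y), (length_px, y)])])
    if ci_percent is not None:
        m = place_centromere(m, ci_percent / 100.0 * length_px)
    return m


def straight_metaphase(lengths_px, cis=None, mp_id="mp", calibration=None):
    """Metaphase of straight traces; lengths in px, optional CIs in percent."""
    cis = cis if cis is not None else [None] * len(lengths_px)
    ms = [
        straight_measurement(str(i + 1), L, ci, y=50.0 * i)
        for i, (L, ci) in enumerate(zip(lengths_px, cis))
    ]
    return Metaphase(id=mp_id, measurements=ms, calibration=calibration)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
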