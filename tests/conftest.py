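import numpy as np
import pytest
from hypothesis import settings

from vmatconv import builtin_geometry

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def m120():
    return builtin_geometry("M120")


@pytest.fixture(scope="session")
def hdmlc():
    return builtin_geometry("HDMLC")


def rasterized_open_area(bank_b, bank_a, boundaries, y_window,
                         x_window=None, dy=0.1):
    """Independent aperture-area oracle: sample the open width on a fine
    y grid clipped to the jaw window."""
    ys = np.arange(y_window[0] + dy / 2, y_window[1], dy)
    idx = np.searchsorted(boundaries, ys, side="right") - 1
    ok = (idx >= 0) & (idx < len(boundaries) - 1)
    b = np.asarray(bank_b)[idx[ok]]
    a = np.asarray(bank_a)[idx[ok]]
    if x_window is not None:
        b = np.clip(b, *x_window)
        a = np.clip(a, *x_window)
    return float(np.sum(np.maximum(a - b, 0.0)) * dy)
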