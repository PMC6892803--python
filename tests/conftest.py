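import numpy as np
import pytest

import thermoloc as tl


@pytest.fixture
def beam22():
    return tl.beam_22um()


@pytest.fixture
def beam56():
    return tl.beam_56um()


@pytest.fixture
def ink_sample():
    return tl.SampleModel(emissivity=0.8, D=1.0e5, T0=20.0, A=2.9e4, tau_d=0.2)


@pytest.fixture
def small_camera():
    """Small camera format keeping simulations light; physics as default."""
    return tl.CameraModel(format=(16, 12))


@pytest.fixture
def uniform_square():
    """Large uniform absorber; centre at (2000, 2000) μm."""
    return tl.make_uniform_square(2000, 10)


@pytest.fixture
def single_pulse(uniform_square, ink_sample, beam22, small_camera):
    """One clean pulse on the uniform absorber: (stack, event, peak frame)."""
    ev = tl.IlluminationEvent(0, 0, 2137.0, 1918.0, 0.0, 0.3)
    stack = tl.render_stack(uniform_square, ink_sample, beam22, [ev],
                            small_camera, noise_mode="none")
    return stack, ev, stack.frames[9]
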