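import numpy as np
import pytest

from smstoich import (
    CameraModel,
    ComplexStoichiometry,
    FluorophorePhotophysics,
    render_two_color_movie,
)


@pytest.fixture(scope="session")
def small_movie():
    """A small rendered two-channel movie with ground truth, shared across
    imaging tests (10 complexes, bright well-separated foci)."""
    rng = np.random.default_rng(42)
    complexes = [
        ComplexStoichiometry(int(rng.integers(1, 5)), int(rng.integers(1, 5)))
        for _ in range(10)
    ]
    pp = FluorophorePhotophysics(300.0, 20.0, 1 / 200)
    cam = CameraModel(offset=100.0, read_noise_sd=5.0, psf_sigma=1.2,
                      shape=(96, 96))
    stack_a, stack_b, gt = render_two_color_movie(
        complexes, pp, pp, cam, n_frames=60, seed=7
    )
    return {"a": stack_a, "b": stack_b, "gt": gt, "camera": cam,
            "photophysics": pp, "complexes": complexes}
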