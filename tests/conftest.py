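import math

import numpy as np
import pytest

from spot.optics_sim import DipoleEmitter, OpticalConfig


@pytest.fixture
def default_config():
    return OpticalConfig(image_shape=(64, 64))


def crest_lattice_scene(n_emitters=20, seed=7, image_shape=(192, 192),
                        pixel_size=65.0, period=230.0):
    """Random-property emitters on the pattern-crest lattice.

    Lattice points satisfy k_dir . x = 0 mod 2pi simultaneously for all three
    pattern directions (the 0/60/120-degree wavevectors close under
    subtraction), so every emitter sits at a crest of the phase-0 pattern of
    every direction.  Spacing is chosen to keep emitters isolated.
    """
    rng = np.random.default_rng(seed)
    config = OpticalConfig(image_shape=image_shape, pixel_size=pixel_size,
                           pattern_period=period)
    emitters = []
    cols = math.ceil(math.sqrt(n_emitters))
    placed = 0
    for a_i in range(cols + 2):
        for b_i in range(cols + 2):
            if placed >= n_emitters:
                break
            a = 8 + 7 * a_i
            b = 6 * b_i + round(a / 2) + 4
            x = a * period
            y = period * (2 * b - a) / math.sqrt(3)
            if not (5 * pixel_size < x < (image_shape[1] - 6) * pixel_size
                    and 5 * pixel_size < y < (image_shape[0] - 6) * pixel_size):
                continue
            emitters.append(
                DipoleEmitter(
                    x=x, y=y, z=0.0, brightness=1000.0,
                    emission_ratio=float(rng.uniform(0.3, 1.5)),
                    orientation=float(rng.uniform(0.0, math.pi)),
                    wobble=float(rng.uniform(0.0, 1.0)),
                )
            )
            placed += 1
    assert len(emitters) >= n_emitters
    return config, emitters
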