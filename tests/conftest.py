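import numpy as np
import pytest

from adhesiometry import synthetic as syn


@pytest.fixture
def disc_mask():
    """Boolean disc of radius 20 centred in a 64x64 field."""
    yy, xx = np.indices((64, 64), dtype=float)
    return np.hypot(yy - 31.5, xx - 31.5) <= 20


@pytest.fixture
def two_disc_mask():
    """Two radius-20 discs with centres 30 px apart (overlapping union)."""
    yy, xx = np.indices((100, 120), dtype=float)
    d1 = np.hypot(yy - 50, xx - 45) <= 20
    d2 = np.hypot(yy - 50, xx - 75) <= 20
    return d1, d2, d1 | d2


def make_class_spread_scene(seed: int, n_per_class: int = 10):
    """Aggregate scene with objects in all four size classes, areas kept
    well away from the class boundaries so discretization cannot flip a
    class between truth and recovery."""
    rng = np.random.default_rng(seed)
    areas = np.concatenate(
        [
            rng.uniform(0.0004, 0.0008, n_per_class),  # class I
            rng.uniform(0.002, 0.008, n_per_class),    # class II
            rng.uniform(0.02, 0.08, n_per_class),      # class III
            rng.uniform(0.12, 0.4, n_per_class),       # class IV
        ]
    )
    objects = tuple((float(a), "disc") for a in areas)
    return syn.AggregateSceneSpec(
        field_size_px=(1200, 1200),
        pixel_size_mm=0.005,
        objects=objects,
        overlap_pairs=0,
        background_gradient_amplitude=0.1,
        noise_sd=0.01,
        seed=seed,
    )
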