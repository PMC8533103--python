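"""Shared fixtures: small ground-truthed synthetic clips.

Session-scoped so the (cheap but not free) frame rendering happens once per
clip per run.  Boxes cover the generator's default chamber ellipses.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cardiovid import RunConfig, SyntheticHeartSpec, generate_clip

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

#: Bounding boxes enclosing the default chamber ellipses (x,y,w,h).
ATRIUM_BOX = "18,38,28,20"
VENTRICLE_BOX = "74,35,36,26"


def default_config(**overrides) -> RunConfig:
    cfg = RunConfig(roi_atrium=ATRIUM_BOX, roi_ventricle=VENTRICLE_BOX)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def regular_spec() -> SyntheticHeartSpec:
    """Reference acquisition regime: 10 s at 200 fps, 150 bpm, no jitter,
    0.1 s A-V delay, pixel noise sd 5; dark pulses so signal troughs mark
    the beats."""
    return SyntheticHeartSpec(pulse_sign="dark", seed=11)


@pytest.fixture(scope="session")
def regular_clip(regular_spec):
    return generate_clip(regular_spec)


@pytest.fixture(scope="session")
def jittered_clip():
    """40 s at 60 fps with 0.01 s beat-time jitter: ~100 beats for
    regularity-recovery checks."""
    spec = SyntheticHeartSpec(
        fps=60.0, duration_s=40.0, mean_bpm=150.0, beat_jitter_sd_s=0.01,
        pixel_noise_sd=3.0, pulse_sign="dark", seed=23,
    )
    return generate_clip(spec)


@pytest.fixture(scope="session")
def daphnia_clip():
    """Ultrafast regime: 600 bpm at 300 fps."""
    spec = SyntheticHeartSpec(
        fps=300.0, duration_s=6.0, mean_bpm=600.0, av_delay_s=0.03,
        pulse_width_s=0.05, pixel_noise_sd=5.0, pulse_sign="dark", seed=31,
    )
    return generate_clip(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
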