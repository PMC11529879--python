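"""Shared fixtures: synthetic scenes and the masking configuration that
optimizes them (combined-channel threshold + pixel compression, the
workflow for membranes whose phases differ in per-channel brightness)."""
import warnings

import numpy as np
import pytest

from spectromap import masking, synth
from spectromap.model import BetaConfig, MaskingParams, SegmentationParams


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Pipeline warnings (empty masks etc.) are expected in many tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def optimized_params() -> MaskingParams:
    """Masking parameters that segment two-phase rings cleanly: threshold on
    the channel sum (uniform across phases) after gamma compression."""
    return MaskingParams(
        snr_k=3.0,
        threshold_channels={"0": 1.0, "1": 1.0},
        compress_enabled=True,
        gamma=0.5,
    )


@pytest.fixture
def ring_scene():
    """Noise-free 50/50 two-phase ring: GP exactly +1/3 and -1/3."""
    spec = synth.two_phase_ring_spec()
    stack, gt = synth.make_vesicle_scene(spec)
    return spec, stack, gt


@pytest.fixture
def ring_mask(ring_scene, optimized_params):
    _, stack, _ = ring_scene
    return masking.build_masks(stack, optimized_params)


@pytest.fixture
def gp_config() -> BetaConfig:
    return BetaConfig(expression="(C1-C2)/(C1+C2)", channel_binding={"C1": 0, "C2": 1})


def annulus(shape=(64, 64), center=None, r_in=8.0, r_out=12.0) -> np.ndarray:
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    return (d >= r_in) & (d <= r_out)
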