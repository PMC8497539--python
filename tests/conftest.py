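"""Shared fixtures: small synthetic sessions rendered once per run."""

from __future__ import annotations

import numpy as np
import pytest

from swallowtrack.synth import (
    SessionSpec,
    SwallowWaveform,
    generate_session,
)


def small_spec(seed: int = 0, peaks=(6.0, 6.0, 6.0), **overrides) -> SessionSpec:
    """A 12 s / 10 fps / 480x360 session whose swallow peaks land on frames.

    Onsets 2 / 5.5 / 9 s with 2 s swallows put the waveform maxima at
    t = 3, 6.5, 10 s, all exact frame times at 10 fps.
    """
    kwargs = dict(
        image_size_px=(480, 360),
        scale_mm_per_px=0.2,
        fps=10.0,
        duration_s=12.0,
        waveforms=tuple(SwallowWaveform(p, o, 2.0)
                        for p, o in zip(peaks, (2.0, 5.5, 9.0))),
        seed=seed,
    )
    kwargs.update(overrides)
    return SessionSpec(**kwargs)


def tiny_spec(seed: int = 0, **overrides) -> SessionSpec:
    """An even smaller 240x180 session for fast rendering tests."""
    kwargs = dict(
        image_size_px=(240, 180),
        scale_mm_per_px=0.4,
        fps=5.0,
        duration_s=12.0,
        waveforms=tuple(SwallowWaveform(6.0, o, 2.0)
                        for o in (2.0, 5.5, 9.0)),
        seed=seed,
    )
    kwargs.update(overrides)
    return SessionSpec(**kwargs)


@pytest.fixture(scope="session")
def noiseless_session():
    """Clean session: no noise, drift or dropout (detection oracle)."""
    spec = small_spec(seed=11)
    seq, truth = generate_session(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def noisy_session():
    """Session with noise, illumination drift and 5% dropout."""
    spec = small_spec(seed=12, noise_sd=0.02, illumination_drift=0.1,
                      dropout_prob=0.05)
    seq, truth = generate_session(spec)
    return spec, seq, truth


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(2024)
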