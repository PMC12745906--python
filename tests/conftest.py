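"""Shared fixtures: scaled-down phantom specs and a cached demo workflow run.

All fixture data is generated programmatically; the grid sizes here are
deliberately small so the whole suite runs on one CPU in minutes.
"""

import numpy as np
import pytest

from sctforge.phantoms import PhantomSpec
from sctforge.pipeline import demo_config, run_workflow


@pytest.fixture()
def tiny_spec():
    """A minimal head phantom grid for fast geometry tests."""
    return PhantomSpec(
        shape=(12, 24, 20),
        spacing=(6.0, 6.0, 6.0),
        semi_axes=(26.0, 36.0, 34.0),
        skull_thickness_mm=9.0,
        mask_offset_mm=7.0,
        mask_shell_thickness_mm=6.0,
        seed=11,
    )


@pytest.fixture()
def small_spec():
    """The grid used for scaled-down learning experiments."""
    return PhantomSpec(
        shape=(16, 32, 32),
        spacing=(5.0, 5.0, 5.0),
        semi_axes=(32.0, 48.0, 40.0),
        skull_thickness_mm=8.0,
        mask_offset_mm=8.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One demo workflow run (5 train / 2 test subjects, 10 epochs), shared
    across tests that inspect its outputs."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = demo_config(seed=0)
    manifest = run_workflow(cfg, out)
    return cfg, manifest, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
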