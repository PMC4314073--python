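import numpy as np
import pytest

from pulsemap import BeatTimes, FrameStack, generate, preset_scenes
from pulsemap.synth import SceneSpec, Vessel


@pytest.fixture(scope="session")
def scenes():
    return preset_scenes(seed=1)


@pytest.fixture(scope="session")
def clean_run(scenes):
    """Rendered clean preset: (stack, beats, truth)."""
    return generate(scenes["clean"])


@pytest.fixture(scope="session")
def separable_run(scenes):
    return generate(scenes["separable"])


@pytest.fixture(scope="session")
def jitter_run():
    """Small jittered scene with known per-frame transforms."""
    vessels = (
        Vessel(points=tuple((float(r), float(75 + 25 * np.sin(np.pi * r / 140)))
                            for r in range(10, 141, 10)), width=7.0),
        Vessel(points=tuple((float(50 + 18 * np.sin(np.pi * c / 110)), float(c))
                            for c in range(12, 139, 10)), width=5.0),
    )
    spec = SceneSpec(height=150, width=150, fps=10 / 3, vessels=vessels,
                     jitter_translation=3.0, jitter_rotation=2.0, seed=3)
    return generate(spec)


@pytest.fixture
def flat_stack():
    """Four identical mid-grey frames."""
    frames = np.full((4, 40, 40, 3), 120, dtype=np.uint8)
    return FrameStack(frames=frames, fps=25.0)


@pytest.fixture
def unit_beats():
    return BeatTimes(onsets=[0.0, 1.0, 2.0, 3.0])
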