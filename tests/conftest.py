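import numpy as np
import pytest

from elastoselect import synthetic as synth
from elastoselect.video_io import Frame, ROIMask, VideoSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_frame(rgb, index=0, h=8, w=8, source="video1"):
    px = np.zeros((h, w, 3), dtype=np.uint8)
    px[:] = rgb
    return Frame(index=index, source_video=source, pixels=px)


@pytest.fixture
def full_mask():
    return ROIMask(mask=np.ones((8, 8), dtype=bool), lesion_id="L")


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size cohort configuration for fast unit/integration tests."""
    return synth.SynthConfig(
        n_lesions=8, frames_per_video=40, height=64, width=64, seed=11
    )


@pytest.fixture(scope="session")
def small_lesion(small_config):
    videos, mask, truth = synth.generate_lesion(small_config, 0)
    return videos, mask, truth


def make_video(frames_rgb, lesion_id="L0"):
    """Build a VideoSequence from a list of uniform RGB colors."""
    frames = [uniform_frame(rgb, index=i) for i, rgb in enumerate(frames_rgb)]
    return VideoSequence(lesion_id=lesion_id, frames=frames)
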