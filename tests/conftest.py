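import numpy as np
import pytest

from gaitfatigue.pipeline import RunConfig, build_segments
from gaitfatigue.synthetic_gait import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def tiny_params():
    """Three-subject cohort at the default (moderate) fatigue effects."""
    return SimulationParams(n_subjects=3, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return simulate_cohort(tiny_params)


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort, tiny_params):
    cfg = RunConfig(simulation=tiny_params, seed=tiny_params.seed)
    return build_segments(cfg, tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_segment_set(n_subjects=3, windows=9, frames=16, channels=2, seed=0):
    """A structurally valid SegmentSet with random data, for split/metric tests."""
    from gaitfatigue.segmentation import SegmentSet

    rng = np.random.default_rng(seed)
    data, labels, subjects, wins = [], [], [], []
    for k in range(n_subjects):
        for lab in (0, 1):
            for w in range(windows):
                data.append(rng.standard_normal((frames, channels)))
                labels.append(lab)
                subjects.append(f"S{k + 1:03d}")
                wins.append(w)
    return SegmentSet(
        data=np.stack(data), labels=np.array(labels),
        subject_ids=np.array(subjects), window_ids=np.array(wins),
        channel_names=[f"ch{i}" for i in range(channels)],
        window_frames=frames, hop_frames=frames // 2,
    )
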