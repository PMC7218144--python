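import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ecogfm.signal_io import AnnotatedRecording, BlockAnnotation
from ecogfm.synthetic import SyntheticConfig, generate_cohort


def make_recording(
    n_blocks=4,
    block_len=200,
    fs=100.0,
    channel_id="ch",
    label=None,
    lead_in=0,
    tail=0,
    seed=0,
):
    """A labeled noise recording with alternating control/active blocks."""
    rng = np.random.default_rng(seed)
    total = lead_in + n_blocks * block_len + tail
    samples = rng.standard_normal(total)
    anns = []
    story = 0
    for b in range(n_blocks):
        start = lead_in + b * block_len
        if b % 2 == 1:
            story += 1
            anns.append(BlockAnnotation("active", start, start + block_len, story_id=story))
        else:
            anns.append(BlockAnnotation("control", start, start + block_len))
    return AnnotatedRecording(
        channel_id=channel_id, samples=samples, fs=fs, annotations=anns, truth_label=label
    )


#: a fast, small-scale paradigm for exercising the full loop in unit tests
TINY = dict(fs=200.0, block_duration_s=2.0, effect_band=(30.0, 70.0))


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 channels (3 PRC + 9 NRC) at reduced rate/duration, strong effect."""
    cfg = SyntheticConfig(n_prc=3, n_nrc=9, effect_gain=6.0, seed=42, **TINY)
    recs, manifest = generate_cohort(cfg)
    return recs, manifest, cfg


@pytest.fixture(scope="session")
def tiny_experiment_kwargs():
    """Windowing/model settings matched to the tiny cohort's 400-sample blocks."""
    return dict(
        window_width=40,
        window_stride=20,
        subblock_windows=8,
        subblock_stride=3,
        ar_order=8,
        small_model=True,
        epochs=8,
        patience=3,
        test_fraction=0.34,
    )
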