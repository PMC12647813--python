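import numpy as np
import pytest

from narrecall.data_model import (
    DetailAnnotation,
    EventAnnotation,
    RecallSegment,
    RecallTranscript,
    VideoAnnotation,
)
from narrecall.synthetic import SyntheticConfig, generate_study


def make_video(video_id="vid1", n_events=3, event_len=10.0, words=None):
    """Small hand-built video with simple descriptions."""
    words = words or ["the fox jumps", "the dog sleeps", "a bird sings loudly"]
    events = tuple(
        EventAnnotation(
            video_id=video_id,
            event_index=i + 1,
            onset_s=i * event_len,
            offset_s=(i + 1) * event_len,
            description=words[i % len(words)],
            sub_event_descriptions=("closer look",) if i == 0 else (),
        )
        for i in range(n_events)
    )
    return VideoAnnotation(
        video_id=video_id,
        title=f"Title {video_id}",
        duration_s=n_events * event_len,
        events=events,
    )


def make_transcript(pid="p01", vid="vid1", session="day1", segments=(), **kw):
    return RecallTranscript(
        participant_id=pid,
        video_id=vid,
        session=session,
        recall_type=kw.pop("recall_type", "multiple"),
        segments=tuple(segments),
        **kw,
    )


def event_segment(event_index, text="some recall text", n_central=0, n_peripheral=0):
    details = tuple(
        DetailAnnotation("central", f"c{i}") for i in range(n_central)
    ) + tuple(DetailAnnotation("peripheral", f"p{i}") for i in range(n_peripheral))
    return RecallSegment(
        text=text, category="event", event_index=event_index, details=details
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small but complete design: quick to generate, exercises everything."""
    return SyntheticConfig(
        seed=20240917,
        n_per_group=4,
        n_videos=4,
        events_min=5,
        events_max=8,
        rho=0.8,
        noise_words_rate=1.0,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg):
    return generate_study(tiny_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
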