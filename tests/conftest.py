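import numpy as np
import pandas as pd
import pytest

from ethonet import EventTable, Ethogram, aerial_ethogram


def make_events(rows):
    """rows: (subject, video, element, t) tuples -> minimal EventTable."""
    return EventTable(
        pd.DataFrame(
            [
                ("ganga", s, v, "M1", "aerial", t, el, "", "")
                for (s, v, el, t) in rows
            ],
            columns=[
                "community", "subject", "video_id", "mound_id", "mound_type",
                "start_time_s", "element", "body_position", "hand",
            ],
        )
    )


@pytest.fixture(scope="session")
def ethogram() -> Ethogram:
    return aerial_ethogram()


@pytest.fixture
def toy_events() -> EventTable:
    # two subjects, two videos each; A fishes classically, B wiggles more
    return make_events(
        [
            ("A", "v1", "Sit", 0.0),
            ("A", "v1", "Probe 1h", 2.0),
            ("A", "v1", "Extract 1h", 4.5),
            ("A", "v1", "Probe 1h", 6.0),
            ("A", "v1", "Extract 1h", 8.25),
            ("A", "v2", "Probe 1h", 0.0),
            ("A", "v2", "Oscillate", 1.75),
            ("A", "v2", "Extract 1h", 3.0),
            ("B", "v3", "Lean", 0.0),
            ("B", "v3", "Probe 2h", 1.0),
            ("B", "v3", "Shake side", 3.25),
            ("B", "v3", "Extract 2h", 5.0),
            ("B", "v4", "Probe 2h", 0.25),
            ("B", "v4", "Extract 2h", 2.0),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987)
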