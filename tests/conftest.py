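import numpy as np
import pandas as pd
import pytest

from chamberpref.streams import DETECTION_COLUMNS, ExperimentDesign


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign.default()


def make_stream(records, fps=15.0):
    """Build a canonical detection DataFrame from simple tuples.

    Each record: (compartment, frame_index, boxes) where boxes is a list of
    (x_min, y_min, x_max, y_max) tuples; an empty list makes an empty-frame
    row.  Metadata defaults to experiment 1, replicate 1, day 1, morning.
    """
    rows = []
    for comp, fidx, boxes in records:
        base = {
            "experiment_id": 1,
            "replicate": 1,
            "day": 1,
            "session": "morning",
            "compartment": comp,
            "frame_index": fidx,
            "timestamp_s": fidx / fps,
        }
        if not boxes:
            rows.append({**base, "x_min": np.nan, "y_min": np.nan,
                         "x_max": np.nan, "y_max": np.nan})
        else:
            for b in boxes:
                rows.append({**base, "x_min": b[0], "y_min": b[1],
                             "x_max": b[2], "y_max": b[3]})
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    df.attrs["fps"] = fps
    df.attrs["frame_step"] = 1
    return df


def box_around(x, y, w=40.0, h=30.0):
    """A w x h box centred on (x, y)."""
    return (x - w / 2, y - h / 2, x + w / 2, y + h / 2)
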