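import math

import numpy as np
import pytest
from hypothesis import settings

from casatrack.core import Track

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

# Table of per-sample (experimental, estimated) viability percentages from
# the ten clinically evaluated video segments used as the worked example.
VIABILITY_PAIRS = [
    (85, 87), (96, 84), (75, 72), (85, 85), (91, 87),
    (85, 83), (86, 88), (97, 88), (81, 87), (85, 72),
]


def greedy_match_oracle(existing, incoming, gate_px):
    """Independent greedy-matching oracle: full-matrix argmin scan per round.

    Repeatedly selects the globally smallest still-available (track, point)
    distance not exceeding the gate, breaking ties on (track_id, index).
    """
    remaining_r = list(range(len(existing)))
    remaining_c = list(range(len(incoming)))
    matches = []
    while True:
        best_key, best_rc = None, None
        for r in remaining_r:
            tid, p = existing[r]
            for c in remaining_c:
                q = incoming[c]
                d = math.dist((p[0], p[1]), (q[0], q[1]))
                if d > gate_px:
                    continue
                key = (d, tid, c)
                if best_key is None or key < best_key:
                    best_key, best_rc = key, (r, c)
        if best_rc is None:
            break
        r, c = best_rc
        matches.append((existing[r][0], c))
        remaining_r.remove(r)
        remaining_c.remove(c)
    return matches


def make_track(track_id, points, start_frame=0, stride=1):
    """Build a Track from a plain list of (x, y) points."""
    t = Track(track_id=track_id)
    for i, (x, y) in enumerate(points):
        t.append(start_frame + i * stride, (float(x), float(y)))
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
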