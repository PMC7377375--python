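import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dreamgraph.corpus import ReportMeta, TokenizedReport


@pytest.fixture
def make_report():
    """Factory for small TokenizedReports with sensible default metadata."""

    def _make(tokens, breaks=(), stage="REM", report_id="r1", participant_id="p1",
              night_id="n1", minutes=120.0, pirs=None, trc=None):
        meta = ReportMeta(
            report_id=report_id,
            participant_id=participant_id,
            night_id=night_id,
            stage=stage,
            minutes_since_lights_off=minutes,
            pirs=pirs,
            trc=trc,
        )
        return TokenizedReport(meta=meta, tokens=tuple(tokens), break_positions=tuple(breaks))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_token_report(rng, make, n_min=30, n_max=80, vocab=12, max_breaks=3, **kw):
    """A random report drawn from a small vocabulary, with random breaks."""
    n = int(rng.integers(n_min, n_max + 1))
    tokens = [f"w{int(v)}" for v in rng.integers(0, vocab, n)]
    nb = int(rng.integers(0, max_breaks + 1))
    breaks = sorted(set(int(b) for b in rng.integers(0, max(n - 1, 1), nb))) if n > 1 else []
    return make(tokens, breaks, **kw)
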