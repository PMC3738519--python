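import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from twindow.datasets import (
    AUDITORY,
    CATCH,
    SOA_GRID,
    VISUAL,
    ConditionRTs,
    ParticipantData,
    TOJTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_participant(
    pid="P1",
    aud=(240.0, 260.0, 280.0, 300.0),
    vis=(280.0, 300.0, 320.0, 340.0),
    catch=(),
    av=None,
    toj=None,
):
    """Participant with every RT condition present; unspecified bisensory
    conditions reuse the visual sample shifted to be race-compatible."""
    av = av or {}
    rt = {
        CATCH: ConditionRTs(CATCH, None, np.asarray(catch, dtype=float)),
        AUDITORY: ConditionRTs(AUDITORY, None, np.asarray(aud, dtype=float)),
        VISUAL: ConditionRTs(VISUAL, None, np.asarray(vis, dtype=float)),
    }
    for soa in SOA_GRID:
        if soa in av:
            lat = np.asarray(av[soa], dtype=float)
        else:
            lat = np.asarray(aud, dtype=float) + 50.0
        rt[soa] = ConditionRTs("av", soa, lat)
    if toj is None:
        soas = np.array(SOA_GRID)
        counts = np.where(soas > 0, 9, 1)
        counts[soas == 0] = 5
        toj = TOJTable(soas, counts, np.full(soas.size, 10))
    return ParticipantData(pid, rt, toj)


@pytest.fixture
def participant():
    return make_participant()
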