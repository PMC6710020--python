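import numpy as np
import pytest

from netcoevolve.effects import ModelSpec
from netcoevolve.panels import SchoolPanel, WaveObservation


@pytest.fixture
def tiny_panel():
    """4 actors, 2 waves, fully observed, hand-checkable."""
    n = 4
    adj1 = np.zeros((n, n), dtype=np.int8)
    adj1[0, 1] = adj1[1, 2] = adj1[0, 2] = 1
    adj2 = adj1.copy()
    adj2[3, 0] = 1          # one added tie
    def wave(adj, alc, con, sec):
        return WaveObservation(
            adjacency=adj,
            present=np.ones(n, dtype=bool),
            alcohol=np.array(alc, dtype=float),
            control=np.array(con, dtype=float),
            secrecy=np.array(sec, dtype=float),
        )
    return SchoolPanel(
        school_id="t1", school_type="coed",
        actor_ids=[f"p{k}" for k in range(n)],
        waves=[wave(adj1, [1, 2, 3, 4], [1, 2, 3, 1], [2, 2, 1, 3]),
               wave(adj2, [1, 3, 3, 4], [1, 2, 2, 1], [2, 3, 1, 3])],
        gender=np.array([0.0, 1.0, 0.0, 1.0]),
        fsm=np.array([0.0, 0.0, 1.0, 1.0]),
        year3_weekly_prevalence=0.25,
    ).validate()


@pytest.fixture
def tiny_spec(tiny_panel):
    return ModelSpec.from_panel(tiny_panel)
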