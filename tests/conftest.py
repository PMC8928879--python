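from datetime import time

import pytest

from stablewatch.core import BehaviorLabel, LabelSequence, Task

S = BehaviorLabel.STANDING
U = BehaviorLabel.LHU
D = BehaviorLabel.LHD
L = BehaviorLabel.LYING
O = BehaviorLabel.OUT


def make_seq(labels, task=Task.TOTAL, night_id="n1", individual_id="a",
             interval_seconds=7, night_start=time(17, 0)):
    return LabelSequence(night_id=night_id, individual_id=individual_id,
                         task=task, labels=tuple(labels),
                         interval_seconds=interval_seconds,
                         night_start=night_start)


@pytest.fixture
def binary_seq_factory():
    return lambda labels, **kw: make_seq(labels, task=Task.BINARY, **kw)


@pytest.fixture
def total_seq_factory():
    return lambda labels, **kw: make_seq(labels, task=Task.TOTAL, **kw)
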