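import numpy as np
import pytest

import quadgait as qg


@pytest.fixture
def meta():
    return qg.TrialMeta(belt_speed=0.4, frame_rate=0.0)


@pytest.fixture(scope="session")
def intact_trial():
    """A medium synthetic intact trial shared across read-only tests."""
    cfg = qg.SyntheticGaitConfig(n_hind_cycles=200, seed=101)
    table, truth = qg.generate_event_schedule_with_truth(cfg)
    return cfg, table, truth


def make_table(contacts, liftoffs, belt_speed=0.4, frame_rate=0.0,
               state="intact"):
    """Build a GaitEventTable from per-limb time dicts.

    Limbs absent from ``liftoffs`` get liftoffs at contact midpoints so
    the alternation invariant holds; timing-sensitive tests pass liftoffs
    explicitly.
    """
    m = qg.TrialMeta(belt_speed=belt_speed, frame_rate=frame_rate, state=state)
    contacts = {k: np.asarray(v, dtype=float) for k, v in contacts.items()}
    liftoffs = {k: np.asarray(v, dtype=float) for k, v in liftoffs.items()}
    for limb, c in contacts.items():
        if limb not in liftoffs and len(c) > 1:
            liftoffs[limb] = (c[:-1] + c[1:]) / 2
    return qg.from_times(contacts, liftoffs, m)
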