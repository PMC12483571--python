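import numpy as np
import pandas as pd
import pytest

import socmap as sm


@pytest.fixture(scope="session")
def lexicon():
    return sm.default_lexicon()


@pytest.fixture(scope="session")
def ring_net(lexicon):
    net = sm.build_network("ring8", seed=1)
    return sm.assign_attributes(net, lexicon, "correlated", seed=2)


@pytest.fixture(scope="session")
def bridge_net(lexicon):
    net = sm.build_network("two_clique_bridge9", seed=1)
    return sm.assign_attributes(net, lexicon, "uncorrelated", seed=2)


class SimplePlacement:
    """Bare coordinates + node ids, standing in for a PlacementMap."""

    def __init__(self, coords, node_ids):
        self.coords = np.asarray(coords, dtype=float)
        self.node_ids = list(node_ids)


@pytest.fixture(scope="session")
def octagon_placement():
    th = np.arange(8) * 2 * np.pi / 8
    coords = np.column_stack([np.cos(th), np.sin(th)]) * 0.4 + 0.5
    return SimplePlacement(coords, [f"s{i}" for i in range(1, 9)])


def per_participant_records(topology, gen, n_participants, seed0, lexicon,
                            regime="uncorrelated"):
    """Trial-level recall outcomes where every participant sees their own
    seeded attribute assignment (as in the online experiments)."""
    base = sm.build_network(topology, seed=0)
    dfs = []
    for p in range(n_participants):
        net = sm.assign_attributes(base, lexicon, regime, seed=seed0 + p)
        sched = sm.generate_schedule(net, "recall", 2, seed=seed0 + p)
        df = sm.simulate_recall(sched, net, gen, 1, seed=seed0 + 100_000 + p)
        df["participant_id"] = f"p{p:03d}"
        dfs.append(df)
    return pd.concat(dfs, ignore_index=True)
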