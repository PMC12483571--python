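"""Experiment networks, attribute assignment and trial schedules.

Two network topologies are supported:

``ring8``
    Eight students arranged in a single cycle; every student has exactly two
    friends, and shares one personality trait and one university-club context
    with each friend (one trait/context pair per friendship edge).

``two_clique_bridge9``
    Two four-student cyclic cliques joined through a ninth *bridge* student.
    The two clique members adjacent to the bridge have three friends and are
    the *central* nodes of the network; the bridge belongs to neither clique.

Attributes are assigned to friendship edges from a scored lexicon, either so
that semantic similarity of attributes correlates positively with graph
proximity (``correlated`` regime) or as a seeded random permutation that
breaks any such relationship (``uncorrelated`` regime).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from socmap.exceptions import ConfigurationError, StateError, StructuralError

Topology = Literal["ring8", "two_clique_bridge9"]
Regime = Literal["correlated", "uncorrelated"]
Phase = Literal["encoding", "dragdrop", "recall"]

CONDITIONS = ("friendship", "trait", "context")

#: Candidate display names for network members.
NAME_POOL = (
    "Alice", "Ben", "Clara", "Daniel", "Emma", "Felix", "Grace", "Henry",
    "Isla", "Jack", "Katie", "Liam", "Mia", "Noah", "Olivia", "Peter",
)


@dataclass(frozen=True)
class Edge:
    """An unordered friendship edge carrying one shared trait and context."""

    u: str
    v: str
    trait: Optional[str] = None
    context: Optional[str] = None

    def pair(self) -> frozenset:
        return frozenset((self.u, self.v))

    def other(self, node: str) -> str:
        if node == self.u:
            return self.v
        if node == self.v:
            return self.u
        raise ValueError(f"{node!r} not an endpoint of {self}")


@dataclass(frozen=True)
class AttributeLexicon:
    """Scored trait and context words.

    Trait scores are valence in [-1, 1] relative to the reference word
    "Smiley" (score 1.0); context scores are club athleticism in [-1, 1]
    relative to "Running" (score 1.0).  The table stands in for a word
    embedding: any mapping word -> scalar score with the same references can
    be supplied by the user.
    """

    traits: dict
    contexts: dict

    def __post_init__(self) -> None:
        for table, ref in ((self.traits, "Smiley"), (self.contexts, "Running")):
            if ref in table and table[ref] != 1.0:
                raise ConfigurationError(f"reference word {ref!r} must score 1.0")
            for w, s in table.items():
                if not np.isfinite(s):
                    raise ConfigurationError(f"non-finite score for {w!r}")


def default_lexicon() -> AttributeLexicon:
    """The packaged lexicon of 14 traits and 14 university clubs.

    Scores are hand-set scalars on the two reference axes (trait valence
    anchored at "Smiley", club athleticism anchored at "Running"); they play
    the role of one-dimensional embedding coordinates.
    """
    traits = {
        "Smiley": 1.0, "Friendly": 0.85, "Cheerful": 0.7, "Generous": 0.55,
        "Honest": 0.4, "Calm": 0.25, "Quiet": 0.1, "Shy": -0.1,
        "Moody": -0.25, "Lazy": -0.4, "Arrogant": -0.55, "Rude": -0.7,
        "Obnoxious": -0.85, "Cruel": -1.0,
    }
    contexts = {
        "Running": 1.0, "Swimming": 0.85, "Climbing": 0.7, "Rowing": 0.55,
        "Tennis": 0.4, "Hiking": 0.25, "Dance": 0.1, "Yoga": -0.1,
        "Drama": -0.25, "Music": -0.4, "Photography": -0.55, "Debate": -0.7,
        "Chess": -0.85, "Math": -1.0,
    }
    return AttributeLexicon(traits=traits, contexts=contexts)


@dataclass
class SocialNetwork:
    """A small friendship network with per-edge shared attributes."""

    nodes: list
    edges: list
    topology: Topology
    central_nodes: frozenset = frozenset()
    bridge_node: Optional[str] = None
    display_names: dict = field(default_factory=dict)
    lexicon: Optional[AttributeLexicon] = None
    regime: Optional[Regime] = None
    seed: Optional[int] = None

    # -- structure ---------------------------------------------------------
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.u, e.v) for e in self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def incident_edges(self, node: str) -> list:
        return [e for e in self.edges if node in (e.u, e.v)]

    def friends(self, node: str) -> list:
        return [e.other(node) for e in self.incident_edges(node)]

    def has_attributes(self) -> bool:
        return all(e.trait is not None and e.context is not None for e in self.edges)

    # -- attribute summaries ----------------------------------------------
    def _scores(self, node: str, kind: str) -> list:
        if not self.has_attributes() or self.lexicon is None:
            raise StateError("attributes have not been assigned")
        table = self.lexicon.traits if kind == "trait" else self.lexicon.contexts
        words = [getattr(e, kind) for e in self.incident_edges(node)]
        return [table[w] for w in words]

    def node_trait_score(self, node: str) -> float:
        """Mean valence of the node's edge traits (traits live on friendships)."""
        return float(np.mean(self._scores(node, "trait")))

    def node_context_score(self, node: str) -> float:
        return float(np.mean(self._scores(node, "context")))

    def valence_class(self, node: str) -> str:
        """Three-level trait-valence class of a node: positive / negative / both."""
        s = self._scores(node, "trait")
        if all(x > 0 for x in s):
            return "positive"
        if all(x <= 0 for x in s):
            return "negative"
        return "both"


@dataclass(frozen=True)
class TrialRecord:
    """One encoding, drag-and-drop or 3AFC trial."""

    participant_id: str
    phase: Phase
    block: int
    trial_index: int
    condition: str
    cue: str
    options: tuple = ()
    correct_option: str = ""


@dataclass
class TrialSchedule:
    """Ordered trials for one phase of the experiment."""

    trials: list
    phase: Phase
    blocks: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            opts = list(t.options) + [""] * (3 - len(t.options))
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "phase": t.phase,
                    "block": t.block,
                    "trial_index": t.trial_index,
                    "condition": t.condition,
                    "cue": t.cue,
                    "option_1": opts[0],
                    "option_2": opts[1],
                    "option_3": opts[2],
                    "correct_option": t.correct_option,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _ring8_edges() -> list:
    ids = [f"s{i}" for i in range(1, 9)]
    return ids, [Edge(ids[i], ids[(i + 1) % 8]) for i in range(8)]


def _bridge9_edges() -> list:
    # cliques (s1..s4) and (s6..s9); s5 bridges between s4 and s6
    ids = [f"s{i}" for i in range(1, 10)]
    a = ["s1", "s2", "s3", "s4"]
    b = ["s6", "s7", "s8", "s9"]
    edges = [Edge(a[i], a[(i + 1) % 4]) for i in range(4)]
    edges += [Edge(b[i], b[(i + 1) % 4]) for i in range(4)]
    edges += [Edge("s4", "s5"), Edge("s5", "s6")]
    return ids, edges


def build_network(topology: Topology, seed: int = 0) -> SocialNetwork:
    """Construct one of the two experiment topologies.

    Node ids are fixed (``s1``...); display names are a seeded draw from the
    name pool, so different participants see different name-to-position
    assignments.
    """
    rng = np.random.default_rng(seed)
    if topology == "ring8":
        ids, edges = _ring8_edges()
        central: frozenset = frozenset()
        bridge = None
    elif topology == "two_clique_bridge9":
        ids, edges = _bridge9_edges()
        central = frozenset({"s4", "s6"})
        bridge = "s5"
    else:
        raise ConfigurationError(f"unknown topology {topology!r}")
    names = list(NAME_POOL)
    rng.shuffle(names)
    display = {nid: names[i] for i, nid in enumerate(ids)}
    return SocialNetwork(
        nodes=ids,
        edges=edges,
        topology=topology,
        central_nodes=central,
        bridge_node=bridge,
        display_names=display,
        seed=seed,
    )


def graph_distances(net: SocialNetwork) -> np.ndarray:
    """Symmetric shortest-path (geodesic) distance matrix, zero diagonal."""
    g = net.graph()
    if not nx.is_connected(g):
        raise StructuralError("network is disconnected")
    n = net.n_nodes
    idx = {v: i for i, v in enumerate(net.nodes)}
    d = np.zeros((n, n), dtype=int)
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, l in lengths.items():
            d[idx[u], idx[v]] = l
    return d


# ---------------------------------------------------------------------------
# attribute assignment
# ---------------------------------------------------------------------------

def _word_subset(table: dict, n: int) -> list:
    """Pick n words evenly spread across the lexicon's score range."""
    words = sorted(table, key=table.__getitem__)
    if len(words) < n:
        raise ConfigurationError(f"lexicon has {len(words)} words, need {n}")
    pick = np.unique(np.round(np.linspace(0, len(words) - 1, n)).astype(int))
    if len(pick) < n:  # lexicon barely large enough: take the first n
        pick = np.arange(n)
    return [words[i] for i in pick]


def _tent(n: int) -> list:
    """Rank layout around a cycle: scores rise then fall, so rank distance
    approximates cyclic distance (no sharp wrap-around discontinuity)."""
    up = list(range(0, n, 2))
    down = list(range(1, n, 2))[::-1]
    return up + down


def _edge_order(net: SocialNetwork) -> list:
    """Edges in a traversal order along which attribute scores are laid out."""
    by_pair = {e.pair(): e for e in net.edges}
    if net.topology == "ring8":
        ids = [f"s{i}" for i in range(1, 9)]
        return [by_pair[frozenset((ids[i], ids[(i + 1) % 8]))] for i in range(8)]
    a = ["s1", "s2", "s3", "s4"]
    b = ["s6", "s7", "s8", "s9"]
    order = [by_pair[frozenset((a[i], a[(i + 1) % 4]))] for i in range(4)]
    order += [by_pair[frozenset(("s4", "s5"))], by_pair[frozenset(("s5", "s6"))]]
    order += [by_pair[frozenset((b[i], b[(i + 1) % 4]))] for i in range(4)]
    return order


def _correlated_ranks(net: SocialNetwork, rng: np.random.Generator) -> list:
    """Rank (into the sorted word list) for each edge of `_edge_order`.

    ring8: a tent pattern around the cycle, rotated by a seeded offset.
    two_clique_bridge9: lowest four scores tented around one clique, middle
    two on the bridge edges, highest four tented around the other clique
    (clique sides swapped at random per seed).
    """
    if net.topology == "ring8":
        tent = _tent(8)
        k = int(rng.integers(8))
        return [tent[(i + k) % 8] for i in range(8)]
    low = [_tent(4)[i] for i in range(4)]           # 0..3 tented
    high = [_tent(4)[i] + 6 for i in range(4)]      # 6..9 tented
    mid = [4, 5]
    if rng.integers(2):
        low, high = [h for h in high], [l for l in low]
        mid = mid[::-1]
    return low + mid + high


def assign_attributes(
    net: SocialNetwork,
    lexicon: AttributeLexicon,
    regime: Regime,
    seed: int = 0,
) -> SocialNetwork:
    """Return a copy of `net` with one trait and one context per edge.

    Under the ``correlated`` regime words are laid out along the network so
    that attribute-score similarity tracks graph proximity; under
    ``uncorrelated`` the same word multiset is randomly permuted over edges.
    """
    if regime not in ("correlated", "uncorrelated"):
        raise ConfigurationError(f"unknown regime {regime!r}")
    n_edges = len(net.edges)
    rng = np.random.default_rng(seed)
    trait_rng, ctx_rng = rng.spawn(2)

    ordered = _edge_order(net)
    assignment: dict = {e.pair(): {} for e in net.edges}
    for kind, table, sub_rng in (
        ("trait", lexicon.traits, trait_rng),
        ("context", lexicon.contexts, ctx_rng),
    ):
        words = _word_subset(table, n_edges)  # sorted by score ascending
        if regime == "correlated":
            ranks = _correlated_ranks(net, sub_rng)
            chosen = [words[r] for r in ranks]
        else:
            chosen = list(words)
            sub_rng.shuffle(chosen)
        for e, w in zip(ordered, chosen):
            assignment[e.pair()][kind] = w

    new_edges = [
        dataclasses.replace(
            e, trait=assignment[e.pair()]["trait"], context=assignment[e.pair()]["context"]
        )
        for e in net.edges
    ]
    return dataclasses.replace(net, edges=new_edges, lexicon=lexicon, regime=regime)


def attribute_distance_correlation(net: SocialNetwork) -> float:
    """Spearman correlation of attribute-score dissimilarity with graph distance.

    Each node's trait/context score is the mean of its incident edge scores;
    pairwise dissimilarity is the Euclidean norm of the (trait, context)
    score difference.  Returns NaN when scores are constant (rank correlation
    undefined).
    """
    if not net.has_attributes():
        raise StateError("attributes have not been assigned")
    d = graph_distances(net)
    t = np.array([net.node_trait_score(v) for v in net.nodes])
    c = np.array([net.node_context_score(v) for v in net.nodes])
    iu = np.triu_indices(net.n_nodes, k=1)
    dissim = np.sqrt(
        (t[:, None] - t[None, :]) ** 2 + (c[:, None] - c[None, :]) ** 2
    )[iu]
    if np.ptp(dissim) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(dissim, d[iu])
    return float(rho)


# ---------------------------------------------------------------------------
# trial schedules
# ---------------------------------------------------------------------------

def _tested_edges(net: SocialNetwork, node: str) -> list:
    """The two associations cued for `node` in each recall condition.

    Clique members are tested on their within-clique friendships; the bridge
    student is tested on both bridge friendships.  In the ring every node
    simply has two edges.  This reproduces the published per-block counts:
    48 trials for the ring, 54 for the bridged network (the bridge student
    contributes two extra trials per condition).
    """
    inc = net.incident_edges(node)
    if net.bridge_node is None or node == net.bridge_node:
        return inc
    bridge = net.bridge_node
    return [e for e in inc if bridge not in (e.u, e.v)]


def _recall_trial(
    net: SocialNetwork,
    node: str,
    edge: Edge,
    condition: str,
    rng: np.random.Generator,
) -> tuple:
    if condition == "friendship":
        correct = edge.other(node)
        candidates = [
            v for v in net.nodes if v != node and v not in net.friends(node)
        ]
    else:
        kind = condition
        correct = getattr(edge, kind)
        own = {getattr(e, kind) for e in net.incident_edges(node)}
        candidates = sorted(
            {getattr(e, kind) for e in net.edges} - own
        )
    foils = list(rng.choice(candidates, size=2, replace=False))
    options = [correct] + foils
    rng.shuffle(options)
    return tuple(options), correct


def generate_schedule(
    net: SocialNetwork,
    phase: Phase,
    blocks: int,
    seed: int = 0,
    participant_id: str = "",
) -> TrialSchedule:
    """Generate the trial schedule for one phase.

    encoding: one trial per friendship edge per block, order shuffled within
    block.  recall: each node cued twice per condition per block (3AFC with
    one correct option and two foils), conditions counterbalanced by a seeded
    shuffle within block.  dragdrop: a single placement prompt.
    """
    rng = np.random.default_rng(seed)
    trials: list = []
    if phase == "dragdrop":
        trials.append(
            TrialRecord(participant_id, "dragdrop", 1, 0, "dragdrop", "all")
        )
        return TrialSchedule(trials=trials, phase=phase, blocks=1)

    if phase == "encoding":
        idx = 0
        for b in range(1, blocks + 1):
            order = list(net.edges)
            rng.shuffle(order)
            for e in order:
                trials.append(
                    TrialRecord(
                        participant_id,
                        "encoding",
                        b,
                        idx,
                        "encoding",
                        f"{e.u}|{e.v}",
                        (e.trait or "", e.context or "", ""),
                        "",
                    )
                )
                idx += 1
        return TrialSchedule(trials=trials, phase=phase, blocks=blocks)

    if phase == "recall":
        if not net.has_attributes():
            raise StateError("recall schedule requires assigned attributes")
        idx = 0
        for b in range(1, blocks + 1):
            block_trials = []
            for node in net.nodes:
                for edge in _tested_edges(net, node):
                    for condition in CONDITIONS:
                        options, correct = _recall_trial(
                            net, node, edge, condition, rng
                        )
                        block_trials.append(
                            (condition, node, options, correct)
                        )
            order = np.arange(len(block_trials))
            rng.shuffle(order)
            for j in order:
                condition, node, options, correct = block_trials[j]
                trials.append(
                    TrialRecord(
                        participant_id, "recall", b, idx, condition, node,
                        options, correct,
                    )
                )
                idx += 1
        return TrialSchedule(trials=trials, phase=phase, blocks=blocks)

    raise ConfigurationError(f"unknown phase {phase!r}")
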