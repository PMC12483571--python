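"""Stepwise (chained) placement accuracy and exact chance levels.

A participant's 2D layout is scored against the ground-truth graph one
geodesic step at a time.  For a node v, rank all other nodes by Euclidean
distance from v's placement.  A k-step chain -- a geodesic path
v -> u_1 -> ... -> u_k -- is *reproduced* when every chain node at depth j
is ranked closer to v than every node whose geodesic depth from v exceeds j.
Reproducing a k-step chain therefore implies correct placement of all the
intermediate nodes, and accuracy at step k is the fraction of (node, chain)
units reproduced.  Each geodesic direction counts as its own chain unit by
default.

Chance levels follow from a uniformly random ordering of the N-1 other
nodes.  Conditioning from the shallowest constraint outward gives the exact
closed form per chain

    P(chain reproduced) = prod_{j=1..k} 1 / (1 + m_j),

where m_j is the number of nodes at geodesic depth greater than j from v
(u_1 must be first among itself and all deeper nodes; given that, the
remaining relative order is again uniform, and so on).  The group chance at
step k is the chain-count-weighted mean over all (node, chain) units.  An
exhaustive enumeration over all (N-1)! orderings reproduces these values
exactly and is available as an oracle for N <= 9.

Chance decreases with step length and is constant across the final step
whenever the deepest level holds a single node (reproducing the (k-1)-chain
then already pins down the last node, so no new constraint is added).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import spatial, stats

from socmap.design import SocialNetwork, graph_distances
from socmap.exceptions import ConfigurationError, StructuralError

#: tolerance below which two placement distances count as tied
TIE_EPS = 1e-9


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def _depths(net: SocialNetwork) -> Dict[str, Dict[str, int]]:
    g = net.graph()
    if not nx.is_connected(g):
        raise StructuralError("network is disconnected")
    return {v: dict(nx.single_source_shortest_path_length(g, v)) for v in net.nodes}


def geodesic_chains(net: SocialNetwork, k: int) -> List[tuple]:
    """All geodesic paths of length k, as tuples (v, u_1, ..., u_k).

    Paths are enumerated from every source node; the two ring directions
    yield distinct chains.
    """
    g = net.graph()
    depths = _depths(net)
    chains = []
    for v in net.nodes:
        for t, d in depths[v].items():
            if d == k:
                for p in nx.all_shortest_paths(g, v, t):
                    chains.append(tuple(p))
    return chains


def _rank_from(coords: np.ndarray, node_index: Dict[str, int], v: str) -> Dict[str, int]:
    """Rank of every other node by distance from v (ties broken by node id)."""
    i = node_index[v]
    d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
    others = [u for u in node_index if u != v]
    # epsilon comparison first, then id order for reproducible tie-breaks
    others.sort(key=lambda u: (round(d[node_index[u]] / TIE_EPS), u))
    return {u: r for r, u in enumerate(others)}


def _chain_ok(chain: tuple, depth_v: Dict[str, int], rank: Dict[str, int]) -> bool:
    v = chain[0]
    for j in range(1, len(chain)):
        rj = rank[chain[j]]
        for w, d in depth_v.items():
            if w != v and d > j and rank[w] < rj:
                return False
    return True


def chained_accuracy(
    pm,
    net: SocialNetwork,
    per_direction: bool = True,
) -> np.ndarray:
    """Per-step chained placement accuracy for one participant.

    Returns accuracy at steps 1..diameter.  With ``per_direction`` (default)
    every geodesic path counts as its own unit; otherwise the unit is the
    (source, target) pair and all its geodesics must be reproduced.
    """
    coords = pm.coords if hasattr(pm, "coords") else np.asarray(pm, dtype=float)
    node_ids = pm.node_ids if hasattr(pm, "node_ids") else list(net.nodes)
    if set(node_ids) != set(net.nodes):
        raise StructuralError("placement and network node ids differ")
    node_index = {v: i for i, v in enumerate(node_ids)}
    depths = _depths(net)
    ranks = {v: _rank_from(coords, node_index, v) for v in net.nodes}
    diam = int(graph_distances(net).max())
    acc = np.zeros(diam)
    for k in range(1, diam + 1):
        if per_direction:
            units = [(c, (_chain_ok(c, depths[c[0]], ranks[c[0]]),))
                     for c in geodesic_chains(net, k)]
            oks = [all(u[1]) for u in units]
        else:
            by_pair: Dict[tuple, list] = {}
            for c in geodesic_chains(net, k):
                by_pair.setdefault((c[0], c[-1]), []).append(c)
            oks = [
                all(_chain_ok(c, depths[v], ranks[v]) for c in cs)
                for (v, _), cs in by_pair.items()
            ]
        acc[k - 1] = float(np.mean(oks))
    return acc


# ---------------------------------------------------------------------------
# chance levels
# ---------------------------------------------------------------------------

def _chain_chance(chain: tuple, depth_v: Dict[str, int]) -> Fraction:
    v = chain[0]
    p = Fraction(1)
    for j in range(1, len(chain)):
        m = sum(1 for w, d in depth_v.items() if w != v and d > j)
        p *= Fraction(1, 1 + m)
    return p


def chance_levels(
    net: SocialNetwork,
    method: str = "analytic",
) -> np.ndarray:
    """Per-step chance of reproducing a chain under random placement.

    ``method='analytic'`` uses the exact product formula per chain;
    ``method='enumerate'`` averages over all (N-1)! orderings of the other
    nodes (exact, oracle-grade; refuses N > 9).  Both return the
    chain-count-weighted mean chance at steps 1..diameter and agree exactly.
    """
    depths = _depths(net)
    diam = int(graph_distances(net).max())
    n = net.n_nodes
    if method == "enumerate" and n > 9:
        warnings.warn("enumeration oracle disabled for N > 9; using analytic")
        method = "analytic"
    out = np.zeros(diam)
    for k in range(1, diam + 1):
        chains = geodesic_chains(net, k)
        if method == "analytic":
            vals = [_chain_chance(c, depths[c[0]]) for c in chains]
            out[k - 1] = float(sum(vals) / len(vals))
        else:
            total = Fraction(0)
            by_source: Dict[str, list] = {}
            for c in chains:
                by_source.setdefault(c[0], []).append(c)
            count = 0
            for v, cs in by_source.items():
                others = [u for u in net.nodes if u != v]
                ok = [0] * len(cs)
                n_perm = 0
                for perm in itertools.permutations(others):
                    rank = {u: r for r, u in enumerate(perm)}
                    n_perm += 1
                    for ci, c in enumerate(cs):
                        if _chain_ok(c, depths[v], rank):
                            ok[ci] += 1
                total += Fraction(sum(ok), n_perm)
                count += len(cs)
            out[k - 1] = float(total / count)
    return out


def chance_levels_exact(net: SocialNetwork) -> List[Fraction]:
    """Analytic chance levels as exact rationals (steps 1..diameter)."""
    depths = _depths(net)
    diam = int(graph_distances(net).max())
    out = []
    for k in range(1, diam + 1):
        chains = geodesic_chains(net, k)
        vals = [_chain_chance(c, depths[c[0]]) for c in chains]
        out.append(sum(vals) / len(vals))
    return out


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

@dataclass
class StepAccuracyReport:
    steps: np.ndarray
    mean_accuracy: np.ndarray
    chance: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    n_participants: int
    flagged_steps: list

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "mean_accuracy": self.mean_accuracy,
                "chance": self.chance,
                "t": self.t_stats,
                "p": self.p_values,
                "n_participants": self.n_participants,
            }
        )


def step_ttests(
    cohort: Sequence[np.ndarray],
    chance: np.ndarray,
) -> StepAccuracyReport:
    """One-sample t-tests of cohort accuracy against chance, per step.

    One-sided (above chance), following the directional hypothesis.  Steps
    with zero across-participant variance are flagged: t is +/- inf when the
    tied value differs from chance and NaN when it equals chance exactly.
    """
    A = np.asarray(cohort, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ConfigurationError("need accuracies for at least 2 participants")
    chance = np.asarray(chance, dtype=float)
    n_steps = A.shape[1]
    t = np.zeros(n_steps)
    p = np.zeros(n_steps)
    flagged = []
    for k in range(n_steps):
        x = A[:, k]
        if np.ptp(x) == 0:
            flagged.append(k + 1)
            if x[0] == chance[k]:
                t[k], p[k] = np.nan, np.nan
            else:
                t[k] = np.inf if x[0] > chance[k] else -np.inf
                p[k] = 0.0 if x[0] > chance[k] else 1.0
            continue
        t[k], p[k] = stats.ttest_1samp(x, chance[k], alternative="greater")
    return StepAccuracyReport(
        steps=np.arange(1, n_steps + 1),
        mean_accuracy=A.mean(axis=0),
        chance=chance,
        t_stats=t,
        p_values=p,
        n_participants=A.shape[0],
        flagged_steps=flagged,
    )
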