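"""Synthetic participants: 2D placements and 3AFC recall outcomes.

Real participants arrange student names in a rectangular box so that
proximity encodes friendship likelihood, and answer cued three-alternative
forced-choice (3AFC) recall trials.  This module generates both kinds of
data from explicit generative models so that every downstream analysis can
be exercised and calibrated without human data.

Placements are produced by inverting the clustering model: symmetrized
assignment probabilities define target dissimilarities (delta proportional
to the inverse probability), which are embedded in 2D by deterministic
stress minimization (classical-scaling initialization followed by
quasi-Newton descent on the squared stress), then perturbed with seeded
Gaussian jitter.  No claim is made that humans compute such an embedding;
this is the minimal mechanism that makes the inverse-distance read-out
approximately recover the generating probabilities.

Recall outcomes are Bernoulli draws from a logistic model with a
per-condition base log-odds, fixed effects of the cue's trait-valence class,
centrality and bridge status (applied to friendship trials, where those
effects are hypothesized), and a participant random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, spatial

from socmap.bias_model import (
    BiasParams,
    assignment_probs,
    attribute_matrix,
    condition_tensor,
)
from socmap.design import SocialNetwork, TrialSchedule
from socmap.exceptions import ConfigurationError, StructuralError

#: default rectangular box (width, height) in box units
DEFAULT_BOX = (1.6, 1.0)


@dataclass
class PlacementMap:
    """One participant's 2D coordinates for every network node."""

    participant_id: str
    node_ids: list
    coords: np.ndarray            # (N, 2), box units
    box: tuple = DEFAULT_BOX
    confidence: float = 4.0       # 1 (not confident) .. 7 (very confident)
    placement_time_s: float = 60.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.node_ids), 2):
            raise StructuralError("coords must be (n_nodes, 2)")
        w, h = self.box
        if np.any(self.coords[:, 0] < -1e-9) or np.any(self.coords[:, 0] > w + 1e-9):
            raise StructuralError("x coordinates outside box")
        if np.any(self.coords[:, 1] < -1e-9) or np.any(self.coords[:, 1] > h + 1e-9):
            raise StructuralError("y coordinates outside box")
        d = spatial.distance_matrix(self.coords, self.coords)
        if np.any(d[~np.eye(len(d), dtype=bool)] == 0):
            raise StructuralError("coincident placements")


@dataclass
class RecallGenModel:
    """Generative logistic model for 3AFC outcomes.

    Log-odds scale.  ``base`` maps condition -> intercept; the remaining
    coefficients act on friendship trials through cue features derived from
    the network: trait-valence class (reference level: positive),
    centrality, their interaction, and bridge status.  ``intercept_sd`` is
    the between-participant random-intercept standard deviation.
    """

    base: dict = field(
        default_factory=lambda: {"friendship": 0.1, "trait": 0.0, "context": 0.2}
    )
    b_negative: float = 0.0
    b_both: float = 0.0
    b_central: float = 0.0
    b_central_x_negative: float = 0.0
    b_bridge: float = 0.0
    intercept_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.intercept_sd < 0:
            raise ConfigurationError("intercept_sd must be >= 0")


# ---------------------------------------------------------------------------
# placements
# ---------------------------------------------------------------------------

def _classical_scaling(delta: np.ndarray) -> np.ndarray:
    """Deterministic 2D classical (Torgerson) scaling of a dissimilarity matrix."""
    n = len(delta)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (delta ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    lam = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(lam)
    # canonical orientation so the layout is seed-independent
    for k in range(2):
        if X[np.argmax(np.abs(X[:, k])), k] < 0:
            X[:, k] = -X[:, k]
    return X


def _stress_embed(delta: np.ndarray) -> np.ndarray:
    """Minimize squared stress sum_{i<j} (||x_i - x_j|| - delta_ij)^2."""
    n = len(delta)
    iu = np.triu_indices(n, k=1)
    target = delta[iu]

    def stress(flat: np.ndarray):
        X = flat.reshape(n, 2)
        diff = X[iu[0]] - X[iu[1]]
        d = np.sqrt((diff ** 2).sum(axis=1)) + 1e-12
        r = d - target
        val = float((r ** 2).sum())
        g = np.zeros((n, 2))
        coef = (2 * r / d)[:, None] * diff
        np.add.at(g, iu[0], coef)
        np.add.at(g, iu[1], -coef)
        return val, g.ravel()

    x0 = _classical_scaling(delta).ravel()
    res = optimize.minimize(stress, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    return res.x.reshape(n, 2)


def _fit_to_box(X: np.ndarray, box: tuple, margin: float = 0.05) -> np.ndarray:
    """Translate and uniformly scale a layout into the box (shape-preserving)."""
    w, h = box
    X = X - X.mean(axis=0)
    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0
    scale = min((1 - 2 * margin) * w / span[0], (1 - 2 * margin) * h / span[1])
    X = X * scale
    X = X - X.min(axis=0)
    # center inside the box
    pad = (np.array(box) - np.ptp(X, axis=0)) / 2
    return X + pad


def target_dissimilarities(net: SocialNetwork, params: BiasParams) -> np.ndarray:
    """Model-implied dissimilarities: delta_ij proportional to 1 / p_bar_ij,
    with p_bar the symmetrized assignment probabilities."""
    D = attribute_matrix(net)
    C = condition_tensor(net)
    P = assignment_probs(D, C, params).P
    pbar = (P + P.T) / 2.0
    n = len(P)
    off = ~np.eye(n, dtype=bool)
    delta = np.zeros_like(pbar)
    delta[off] = 1.0 / pbar[off]
    delta[off] /= delta[off].mean()  # scale-free: embedding is rescaled to the box
    return delta


def simulate_placements(
    net: SocialNetwork,
    params: BiasParams,
    n_participants: int,
    noise_sd: float,
    seed: int = 0,
    box: tuple = DEFAULT_BOX,
) -> list:
    """Simulate drag-and-drop placements for a cohort.

    All participants share the deterministic stress-minimizing layout of the
    model-implied dissimilarities; individual variation enters through
    seeded Gaussian jitter with standard deviation ``noise_sd`` (box units),
    clipped to the box.  Confidence and placement time are uninformative
    noise carried only so file formats round-trip.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    delta = target_dissimilarities(net, params)
    layout = _fit_to_box(_stress_embed(delta), box)
    rng = np.random.default_rng(seed)
    w, h = box
    out = []
    for p in range(n_participants):
        coords = layout + rng.normal(scale=noise_sd, size=layout.shape)
        coords[:, 0] = np.clip(coords[:, 0], 0, w)
        coords[:, 1] = np.clip(coords[:, 1], 0, h)
        # jitter guarantees no exact overlap even at noise_sd = 0
        coords += rng.normal(scale=1e-9, size=coords.shape)
        coords[:, 0] = np.clip(coords[:, 0], 0, w)
        coords[:, 1] = np.clip(coords[:, 1], 0, h)
        out.append(
            PlacementMap(
                participant_id=f"p{p:03d}",
                node_ids=list(net.nodes),
                coords=coords,
                box=box,
                confidence=float(rng.uniform(1, 7)),
                placement_time_s=float(rng.lognormal(mean=4.0, sigma=0.3)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# recall outcomes
# ---------------------------------------------------------------------------

def _cue_features(net: SocialNetwork, node: str) -> dict:
    cls = net.valence_class(node)
    return {
        "valence_class": cls,
        "central": node in net.central_nodes,
        "bridge": node == net.bridge_node,
    }


def simulate_recall(
    schedule: TrialSchedule,
    net: SocialNetwork,
    gen: RecallGenModel,
    n_participants: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate trial-level 3AFC outcomes for a cohort.

    Returns a tidy DataFrame with the schedule columns plus ``response``,
    ``correct`` (0/1) and ``rt_s``.  The logit of a correct response is
    base(condition) + fixed effects of the cue's features (friendship
    trials) + the participant's random intercept.
    """
    if schedule.phase != "recall":
        raise StructuralError("schedule must be a recall schedule")
    node_set = set(net.nodes)
    for t in schedule.trials:
        if t.cue not in node_set:
            raise StructuralError(f"cue {t.cue!r} is not a node of the network")
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")

    feats = {v: _cue_features(net, v) for v in net.nodes}
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(scale=gen.intercept_sd)
        pid = f"p{p:03d}"
        for t in schedule.trials:
            fe = feats[t.cue]
            logit = gen.base[t.condition] + u
            if t.condition == "friendship":
                neg = fe["valence_class"] == "negative"
                both = fe["valence_class"] == "both"
                logit += gen.b_negative * neg + gen.b_both * both
                logit += gen.b_central * fe["central"]
                logit += gen.b_central_x_negative * fe["central"] * neg
                logit += gen.b_bridge * fe["bridge"]
            p_correct = 1.0 / (1.0 + np.exp(-logit))
            ok = rng.random() < p_correct
            if ok:
                response = t.correct_option
            else:
                foils = [o for o in t.options if o != t.correct_option]
                response = foils[int(rng.integers(len(foils)))]
            rows.append(
                {
                    "participant_id": pid,
                    "phase": t.phase,
                    "block": t.block,
                    "trial_index": t.trial_index,
                    "condition": t.condition,
                    "cue": t.cue,
                    "option_1": t.options[0],
                    "option_2": t.options[1],
                    "option_3": t.options[2],
                    "correct_option": t.correct_option,
                    "response": response,
                    "correct": int(ok),
                    "rt_s": float(rng.lognormal(mean=0.5, sigma=0.3)),
                    "valence_class": fe["valence_class"],
                    "central": int(fe["central"]),
                    "bridge": int(fe["bridge"]),
                }
            )
    return pd.DataFrame(rows)
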