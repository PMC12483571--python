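"""Serialization of pipeline artifacts (JSON for structures, CSV for tables).

All JSON artifacts carry a ``schema_version`` field; CSV files are UTF-8,
comma-separated with a header row and '.' decimals.  ``parse(serialize(x))``
round-trips every artifact the pipeline produces.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from socmap.bias_model import BiasParams, FitResult
from socmap.design import (
    AttributeLexicon,
    Edge,
    SocialNetwork,
    TrialRecord,
    TrialSchedule,
)
from socmap.exceptions import ConfigurationError
from socmap.simulate import PlacementMap

SCHEMA_VERSION = 1


def _check_version(obj: dict, what: str) -> None:
    v = obj.get("schema_version")
    if v != SCHEMA_VERSION:
        raise ConfigurationError(
            f"{what}: schema_version {v!r} not supported (expected {SCHEMA_VERSION})"
        )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def network_to_json(net: SocialNetwork, path: Union[str, Path, None] = None) -> dict:
    obj = {
        "schema_version": SCHEMA_VERSION,
        "topology": net.topology,
        "nodes": list(net.nodes),
        "display_names": dict(net.display_names),
        "edges": [
            {"u": e.u, "v": e.v, "trait": e.trait, "context": e.context}
            for e in net.edges
        ],
        "central_nodes": sorted(net.central_nodes),
        "bridge_node": net.bridge_node,
        "regime": net.regime,
        "seed": net.seed,
        "lexicon": (
            {"traits": net.lexicon.traits, "contexts": net.lexicon.contexts}
            if net.lexicon is not None
            else None
        ),
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2, ensure_ascii=False))
    return obj


def network_from_json(src: Union[str, Path, dict]) -> SocialNetwork:
    obj = src if isinstance(src, dict) else json.loads(Path(src).read_text())
    _check_version(obj, "network")
    lex = None
    if obj.get("lexicon"):
        lex = AttributeLexicon(
            traits=obj["lexicon"]["traits"], contexts=obj["lexicon"]["contexts"]
        )
    return SocialNetwork(
        nodes=list(obj["nodes"]),
        edges=[
            Edge(e["u"], e["v"], e.get("trait"), e.get("context"))
            for e in obj["edges"]
        ],
        topology=obj["topology"],
        central_nodes=frozenset(obj.get("central_nodes", [])),
        bridge_node=obj.get("bridge_node"),
        display_names=dict(obj.get("display_names", {})),
        lexicon=lex,
        regime=obj.get("regime"),
        seed=obj.get("seed"),
    )


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def schedule_to_csv(sched: TrialSchedule, path: Union[str, Path]) -> None:
    sched.to_dataframe().to_csv(path, index=False)


def schedule_from_csv(path: Union[str, Path]) -> TrialSchedule:
    df = pd.read_csv(path, keep_default_na=False)
    trials = [
        TrialRecord(
            participant_id=str(r.participant_id),
            phase=r.phase,
            block=int(r.block),
            trial_index=int(r.trial_index),
            condition=r.condition,
            cue=str(r.cue),
            options=tuple(
                o for o in (str(r.option_1), str(r.option_2), str(r.option_3))
            ),
            correct_option=str(r.correct_option),
        )
        for r in df.itertuples()
    ]
    phase = trials[0].phase if trials else "recall"
    blocks = max((t.block for t in trials), default=0)
    return TrialSchedule(trials=trials, phase=phase, blocks=blocks)


# ---------------------------------------------------------------------------
# placements
# ---------------------------------------------------------------------------

def placements_to_csv(pms: List[PlacementMap], path: Union[str, Path]) -> None:
    rows = []
    for pm in pms:
        for nid, (x, y) in zip(pm.node_ids, pm.coords):
            rows.append(
                {
                    "participant_id": pm.participant_id,
                    "node_id": nid,
                    "x": x,
                    "y": y,
                    "box_w": pm.box[0],
                    "box_h": pm.box[1],
                    "confidence": pm.confidence,
                    "placement_time_s": pm.placement_time_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def placements_from_csv(path: Union[str, Path]) -> List[PlacementMap]:
    df = pd.read_csv(path)
    out = []
    for pid, g in df.groupby("participant_id", sort=False):
        out.append(
            PlacementMap(
                participant_id=str(pid),
                node_ids=[str(n) for n in g["node_id"]],
                coords=g[["x", "y"]].to_numpy(dtype=float),
                box=(float(g["box_w"].iloc[0]), float(g["box_h"].iloc[0])),
                confidence=float(g["confidence"].iloc[0]),
                placement_time_s=float(g["placement_time_s"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fits_to_json(fits: List[FitResult], path: Union[str, Path, None] = None) -> dict:
    obj = {
        "schema_version": SCHEMA_VERSION,
        "fits": [
            {
                "participant_id": f.participant_id,
                "variant": f.variant,
                "beta": f.params.beta.tolist(),
                "beta_hat": f.params.beta_hat.tolist(),
                "alpha": f.params.alpha,
                "active_mask": f.params.active_mask.astype(int).tolist(),
                "final_kl": f.final_kl,
                "init_kl": f.init_kl,
                "n_iter": f.n_iter,
                "converged": f.converged,
            }
            for f in fits
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2))
    return obj


def fits_from_json(src: Union[str, Path, dict]) -> List[FitResult]:
    obj = src if isinstance(src, dict) else json.loads(Path(src).read_text())
    _check_version(obj, "fits")
    out = []
    for f in obj["fits"]:
        params = BiasParams(
            beta=np.array(f["beta"]),
            beta_hat=np.array(f["beta_hat"]),
            alpha=f["alpha"],
            active_mask=np.array(f["active_mask"], dtype=bool),
        )
        out.append(
            FitResult(
                params=params,
                variant=f["variant"],
                final_kl=f["final_kl"],
                init_kl=f["init_kl"],
                n_iter=f["n_iter"],
                converged=f["converged"],
                participant_id=f.get("participant_id", ""),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated configuration for an end-to-end pipeline run."""

    experiment: str = "exp1"                # exp1 (ring) or exp2 (bridged)
    regime: str = "uncorrelated"
    n_participants: int = 20
    seed: int = 0
    noise_sd: float = 0.05
    variant: str = "biased"
    beta: Optional[list] = None
    beta_hat: Optional[list] = None
    alpha: float = 1.0
    gen_base: Optional[dict] = None
    gen_b_negative: float = 0.0
    gen_b_both: float = 0.0
    gen_b_central: float = 0.0
    gen_b_central_x_negative: float = 0.0
    gen_b_bridge: float = 0.0
    gen_intercept_sd: float = 0.5
    out_dir: str = "socmap_out"

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ConfigurationError(f"experiment must be exp1/exp2, got {self.experiment!r}")
        if self.regime not in ("correlated", "uncorrelated"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.variant not in ("biased", "unbiased"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")

    @property
    def topology(self) -> str:
        return "ring8" if self.experiment == "exp1" else "two_clique_bridge9"

    def to_json(self, path: Union[str, Path, None] = None) -> dict:
        obj = {"schema_version": SCHEMA_VERSION, **dataclasses.asdict(self)}
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj

    @classmethod
    def from_json(cls, src: Union[str, Path, dict]) -> "RunConfig":
        obj = src if isinstance(src, dict) else json.loads(Path(src).read_text())
        obj = dict(obj)
        _check_version(obj, "config")
        obj.pop("schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)
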