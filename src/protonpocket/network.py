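"""Directed proton-transfer network inferred from ensemble pKa correlations.

A proton transfer between two pocket carboxylates is hypothesised when, in a
given trajectory, (1) exactly one of the pair is protonated, (2) their pKa
series are strongly anti-correlated (r < -0.5 by default), (3) the residues
are spatially proximal, and (4, annotation only) the residues' depth from the
luminal K+ access pathway bears on release to bulk. The donor is the
protonated member. Aggregating accepted pairs over all (state, replicate)
trajectories yields a directed graph whose edge weights (instance counts)
rank transfer likelihood.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .errors import StructuralDataError
from .pka import PocketFrame
from .states import POCKET, ProtonationState

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = -0.5
DEFAULT_PROXIMITY_CUTOFF_NM = 0.6

_POCKET_INDEX = {r.name: i for i, r in enumerate(POCKET)}


@dataclass
class TransferPair:
    """A donor->acceptor transfer hypothesis from one trajectory."""

    donor: str  # the protonated member
    acceptor: str  # the deprotonated member
    r: float
    state: ProtonationState
    replicate: int = 0
    threshold: float = DEFAULT_R_THRESHOLD
    mean_pka_donor: float | None = None
    mean_pka_acceptor: float | None = None
    min_oo_distance_nm: float | None = None

    @property
    def low_pka_consistent(self) -> bool | None:
        """Whether the donor also has the lower windowed mean pKa.

        Transfer is expected from the low-pKa residue to the high-pKa one;
        a protonated donor with the *higher* mean pKa is flagged (False),
        not dropped.
        """
        if self.mean_pka_donor is None or self.mean_pka_acceptor is None:
            return None
        return self.mean_pka_donor <= self.mean_pka_acceptor


def candidate_pairs(
    matrix: CorrelationMatrix, threshold: float = DEFAULT_R_THRESHOLD
) -> list[TransferPair]:
    """Pairs with r strictly below ``threshold`` and exactly one protonated member.

    Both-protonated and both-deprotonated pairs are excluded even at strong
    negative r (no proton to move, or no vacancy to accept it).
    """
    if matrix.state is None:
        raise ValueError("correlation matrix must carry its protonation state")
    state = matrix.state
    out: list[TransferPair] = []
    for a, b, rv in matrix.pairs():
        if not rv < threshold:
            continue
        pa, pb = state.is_protonated(a), state.is_protonated(b)
        if pa == pb:
            continue
        donor, acceptor = (a, b) if pa else (b, a)
        out.append(
            TransferPair(
                donor, acceptor, rv, state, matrix.replicate, threshold,
                mean_pka_donor=matrix.means.get(donor),
                mean_pka_acceptor=matrix.means.get(acceptor),
            )
        )
    return out


def pair_min_oo_distance(
    residue_a: str, residue_b: str, frames: Sequence[PocketFrame]
) -> float:
    """Time-averaged minimum carboxyl O-O distance between two residues (nm)."""
    dists = []
    for f in frames:
        if residue_a not in f.oxygens or residue_b not in f.oxygens:
            raise StructuralDataError(
                f"frame t={f.time_ns} ns lacks oxygens for {residue_a}/{residue_b}"
            )
        oa = np.asarray(f.oxygens[residue_a], dtype=float)
        ob = np.asarray(f.oxygens[residue_b], dtype=float)
        d = np.linalg.norm(oa[:, None, :] - ob[None, :, :], axis=2)
        dists.append(d.min())
    return float(np.mean(dists))


def proximity_filter(
    pairs: Sequence[TransferPair],
    frames: Sequence[PocketFrame],
    cutoff_nm: float = DEFAULT_PROXIMITY_CUTOFF_NM,
) -> list[TransferPair]:
    """Keep pairs whose time-averaged minimum O-O distance is within ``cutoff_nm``.

    Each surviving pair is annotated with that distance.
    """
    kept = []
    for p in pairs:
        d = pair_min_oo_distance(p.donor, p.acceptor, frames)
        p.min_oo_distance_nm = d
        if d <= cutoff_nm:
            kept.append(p)
        else:
            logger.info("pair %s->%s rejected: mean min O-O %.3f nm > %.3f nm",
                        p.donor, p.acceptor, d, cutoff_nm)
    return kept


@dataclass
class TransferNetwork:
    """Directed donor->acceptor graph weighted by ensemble instance counts."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def edges(self) -> list[tuple[str, str, int]]:
        """(donor, acceptor, instance_count) sorted by descending count then canonical order."""
        items = [
            (u, v, int(d["instance_count"])) for u, v, d in self.graph.edges(data=True)
        ]
        items.sort(key=lambda e: (-e[2], _POCKET_INDEX.get(e[0], 99), _POCKET_INDEX.get(e[1], 99)))
        return items

    def instance_count(self, donor: str, acceptor: str) -> int:
        if self.graph.has_edge(donor, acceptor):
            return int(self.graph[donor][acceptor]["instance_count"])
        return 0

    @property
    def total_instances(self) -> int:
        return sum(c for _, _, c in self.edges())


def aggregate_network(pairs: Sequence[TransferPair]) -> TransferNetwork:
    """One directed edge per (donor, acceptor); count = contributing trajectories.

    An "instance" is one (state, replicate) trajectory in which the directed
    pair passed all filters; duplicates of the same (state, replicate, donor,
    acceptor) are deduplicated with a warning.
    """
    g = nx.DiGraph()
    for r in POCKET:
        g.add_node(r.name)
    seen: set[tuple[str, int, str, str]] = set()
    for p in pairs:
        key = (p.state.label, p.replicate, p.donor, p.acceptor)
        if key in seen:
            warnings.warn(f"duplicate transfer pair entry {key}; deduplicated")
            continue
        seen.add(key)
        if p.donor == p.acceptor:
            raise ValueError("self-edge in transfer pairs")
        if g.has_edge(p.donor, p.acceptor):
            g[p.donor][p.acceptor]["instance_count"] += 1
            g[p.donor][p.acceptor]["contributors"].append([p.state.label, p.replicate])
        else:
            g.add_edge(p.donor, p.acceptor, instance_count=1,
                       contributors=[[p.state.label, p.replicate]])
    return TransferNetwork(g)


def rank_transfer_likelihood(network: TransferNetwork) -> list[dict]:
    """Edges ranked by instance count (transfer-likelihood proxy), descending."""
    return [
        {"donor": u, "acceptor": v, "instances": c, "rank": i + 1}
        for i, (u, v, c) in enumerate(network.edges())
    ]


def residue_depths(
    frames: Sequence[PocketFrame], access_point: np.ndarray
) -> dict[str, float]:
    """Mean distance of each residue's carboxylate centroid from the luminal
    access point (nm); annotation supporting the release-to-bulk criterion."""
    access_point = np.asarray(access_point, dtype=float)
    names = sorted({n for f in frames for n in f.oxygens}, key=lambda n: _POCKET_INDEX.get(n, 99))
    return {
        name: float(np.mean([
            np.linalg.norm(f.carboxylate_centroid(name) - access_point)
            for f in frames if name in f.oxygens
        ]))
        for name in names
    }


def network_to_table(network: TransferNetwork) -> pd.DataFrame:
    """Donor/acceptor/instances table (donors shown with their '+' suffix)."""
    rows = [
        {"donor": f"{u}+", "acceptor": v, "instances": c}
        for u, v, c in network.edges()
    ]
    return pd.DataFrame(rows, columns=["donor", "acceptor", "instances"])


def export_network(
    network: TransferNetwork,
    path: str | Path,
    fmt: str = "json",
    depths: dict[str, float] | None = None,
) -> None:
    """Write the network as JSON, DOT (edge weight = count) or CSV."""
    path = Path(path)
    if fmt == "json":
        payload = {
            "nodes": [
                {"id": n, "depth_nm": depths.get(n) if depths else None}
                for n in network.graph.nodes
            ],
            "edges": [
                {
                    "donor": u, "acceptor": v,
                    "instances": int(d["instance_count"]),
                    "contributors": d["contributors"],
                }
                for u, v, d in network.graph.edges(data=True)
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "dot":
        lines = ["digraph proton_transfer {"]
        for n in network.graph.nodes:
            extra = f' [depth="{depths[n]:.3f}"]' if depths and n in depths else ""
            lines.append(f'  "{n}"{extra};')
        for u, v, c in network.edges():
            lines.append(f'  "{u}" -> "{v}" [weight={c}, penwidth={c}, label="{c}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        network_to_table(network).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected json, dot or csv)")
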