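"""Networks of regime shifts and smooth transitions between stable states.

Nodes are uninvadable dynamically stable states. A *red* edge (regime
shift) joins two states whose feasible supply ranges overlap: at least one
sampled supply vector where both are feasible. A *blue* edge (smooth
transition) joins states whose feasible ranges share a boundary: crossing
it makes one species' abundance pass through zero continuously. Boundary
pairs are found by sampling points just outside a state's feasible range —
random positive X entries with one species' abundance set slightly
negative, mapped through the conservation law to a supply vector — and
testing which other stable states are feasible there.

Feasibility of a state depends only on the direction of the supply vector
(the sign pattern of R^-1 phi is invariant under scaling), so boundary
sample vectors need not be rescaled into any sampling box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .feasibility import (
    FeasibilityReport,
    POSITIVITY_TOL,
    build_resource_matrix,
)
from .species_pool import ModelConfig, SpeciesPool
from .state_enumeration import CommunityState

__all__ = [
    "TransitionNetwork",
    "build_overlap_edges",
    "detect_boundary_pairs",
    "partition_modules",
    "build_transition_network",
]


@dataclass
class TransitionNetwork:
    """Stable states as nodes, regime-shift and boundary edges, modules."""

    state_ids: list[int]
    red_edges: dict[tuple[int, int], int]  # pair -> shared-sample count
    blue_edges: set[tuple[int, int]]
    fractions: dict[int, float] = field(default_factory=dict)
    modules: dict[int, int] = field(default_factory=dict)

    def to_graph(self, include_isolated: bool = True) -> nx.Graph:
        g = nx.Graph()
        for sid in self.state_ids:
            if include_isolated or self.degree(sid) > 0:
                g.add_node(
                    sid,
                    feasible_fraction=self.fractions.get(sid, 0.0),
                    module=self.modules.get(sid, -1),
                )
        for (a, b), w in self.red_edges.items():
            g.add_edge(a, b, kind="red", weight=int(w))
        for a, b in self.blue_edges:
            g.add_edge(a, b, kind="blue", weight=1)
        return g

    def degree(self, sid: int) -> int:
        return sum(sid in e for e in self.red_edges) + sum(
            sid in e for e in self.blue_edges
        )

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, "red", w) for (a, b), w in sorted(self.red_edges.items())
        ] + [(a, b, "blue", 0) for a, b in sorted(self.blue_edges)]
        return pd.DataFrame(rows, columns=["source", "target", "type", "weight"])


def build_overlap_edges(
    report: FeasibilityReport, stable_ids: np.ndarray | list[int]
) -> dict[tuple[int, int], int]:
    """Pairs of stable states co-feasible at >= 1 sample, with counts.

    Computed as the co-occurrence matrix F F^T of the sparse feasibility
    indicator restricted to stable states; every edge is therefore
    witnessed by stored sample columns.
    """
    stable_ids = np.asarray(list(stable_ids), dtype=int)
    F = report.feasible[stable_ids].astype(np.int64)
    co = (F @ F.T).tocoo()
    edges: dict[tuple[int, int], int] = {}
    for r, c, v in zip(co.row, co.col, co.data):
        if r < c and v > 0:
            edges[(int(stable_ids[r]), int(stable_ids[c]))] = int(v)
    return edges


def detect_boundary_pairs(
    pool: SpeciesPool,
    states: list[CommunityState],
    stable_ids: list[int],
    config: ModelConfig | None = None,
    n_boundary: int = 1000,
    exclude: set[tuple[int, int]] | None = None,
) -> set[tuple[int, int]]:
    """Blue (shared-boundary) pairs among stable states.

    For each stable state and each entry of its X vector: draw the other
    entries uniformly on (0, 1], set the chosen entry to -0.01, map X
    through phi = delta R X, and record every *other* stable state
    feasible at that supply vector. Pushing an abundance negative probes
    extinction boundaries; pushing a non-limiting concentration negative
    probes limitation-switch boundaries (e.g. the C-limited and N-limited
    states of a single species meeting on the phi_n/phi_c = Yc/Yn
    hyperplane). Pairs already connected by a red edge can be excluded via
    ``exclude``.
    """
    config = config or ModelConfig()
    rng = config.rng()
    exclude = exclude or set()
    lus = {}
    mats = {}
    for sid in stable_ids:
        R, cols = build_resource_matrix(pool, states[sid])
        mats[sid] = (R, cols)
        lus[sid] = scipy.linalg.lu_factor(R)
    pairs: set[tuple[int, int]] = set()
    for sid in stable_ids:
        R, cols = mats[sid]
        n = R.shape[0]
        for k in range(n):
            X = rng.uniform(
                np.nextafter(0.0, 1.0), 1.0, size=(n, n_boundary)
            )
            X[k] = -0.01
            phi = config.delta * (R @ X)
            for other in stable_ids:
                if other == sid:
                    continue
                pair = (min(sid, other), max(sid, other))
                if pair in pairs or pair in exclude:
                    continue
                Xo = scipy.linalg.lu_solve(lus[other], phi / config.delta)
                if np.any(np.all(Xo > POSITIVITY_TOL, axis=0)):
                    pairs.add(pair)
    return pairs


def partition_modules(
    graph: nx.Graph, resolution: float = 1.5, seed: int = 0
) -> dict[int, int]:
    """Louvain modularity partition of the transition network.

    Deterministic for a given seed; greedy modularity maximisation is not
    unique, so the module count should be read as approximate. An empty
    graph puts every node in its own module.
    """
    if graph.number_of_edges() == 0:
        return {node: k for k, node in enumerate(graph.nodes)}
    communities = nx.community.louvain_communities(
        graph, resolution=resolution, seed=seed
    )
    return {
        node: k for k, comm in enumerate(communities) for node in comm
    }


def build_transition_network(
    pool: SpeciesPool,
    states: list[CommunityState],
    report: FeasibilityReport,
    stable_mask: np.ndarray,
    config: ModelConfig | None = None,
    n_boundary: int = 1000,
    detect_boundaries: bool = True,
    resolution: float = 1.5,
) -> TransitionNetwork:
    """Convenience wrapper: overlap edges, boundary edges, modules."""
    stable_ids = list(np.nonzero(stable_mask)[0].astype(int))
    red = build_overlap_edges(report, stable_ids)
    blue: set[tuple[int, int]] = set()
    if detect_boundaries:
        blue = detect_boundary_pairs(
            pool, states, stable_ids, config, n_boundary, exclude=set(red)
        )
    net = TransitionNetwork(
        state_ids=stable_ids,
        red_edges=red,
        blue_edges=blue,
        fractions={sid: float(report.fractions[sid]) for sid in stable_ids},
    )
    graph = net.to_graph(include_isolated=False)
    seed = (config or ModelConfig()).rng_seed
    net.modules = partition_modules(graph, resolution=resolution, seed=seed)
    return net
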